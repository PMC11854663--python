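"""The convergence statistic and PCA geometry.

The headline statistic works on a cluster x group matrix of mean z-scores,
quantized onto the 11-level palette grid running from -1.5 to +1.5 in steps
of 0.3 (the numeric values assigned to the heatmap's 11 colors). Each
cluster-group cell is snapped to its nearest grid level; a group column's
*net change* is the sum of its quantized values, and the *net difference in
units* between two group columns measures how far apart the two groups'
quantized expression profiles are. Two readings of the between-group
comparison are supported and always reported together:

- ``per_cluster_L1`` (default): sum over clusters of |q_A - q_B| — sensitive
  to compensating shifts in opposite directions across clusters;
- ``column_sum``: |net_change(A) - net_change(B)| — the difference of the
  column totals.

A shrinking female-male net difference under the grape diet, relative to the
standard diet, is the quantized-cluster signature of sex convergence. The
PCA half of the module provides the complementary geometric readout: group
centroids in PC1-PC2 and the flag d(SDGF, SDGM) < d(SDF, SDM).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cluster import ClusterAssignment
from .io import GROUPS
from .normalize import ExpressionMatrix

_MIDPOINT_TOL = 1e-9


@dataclass
class PaletteGrid:
    """Uniformly spaced quantization levels, v_min..v_max inclusive."""

    v_min: float
    v_max: float
    step: float
    levels: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if not self.v_min < self.v_max:
            raise ValueError(f"v_min must be < v_max, got [{self.v_min}, {self.v_max}]")
        if self.step <= 0:
            raise ValueError(f"step must be positive, got {self.step}")
        span = (self.v_max - self.v_min) / self.step
        if abs(span - round(span)) > 1e-9:
            raise ValueError(
                f"span {self.v_max - self.v_min} is not an integral multiple of step {self.step}"
            )
        n = int(round(span)) + 1
        self.levels = self.v_min + self.step * np.arange(n)

    def __len__(self) -> int:
        return len(self.levels)


def make_grid(v_min: float = -1.5, v_max: float = 1.5, step: float = 0.3) -> PaletteGrid:
    """The palette grid; defaults give the 11-color scale -1.5..+1.5 by 0.3."""
    return PaletteGrid(v_min, v_max, step)


def quantize(v, grid: PaletteGrid):
    """Snap value(s) to the nearest grid level.

    Values beyond the grid ends clamp to the end levels; exact midpoints
    between two levels round toward zero (the level of smaller magnitude).
    Scalar in, scalar out; array in, array out.
    """
    arr = np.asarray(v, dtype=float)
    if np.isnan(arr).any():
        raise ValueError("cannot quantize NaN")
    t = np.clip((arr - grid.v_min) / grid.step, 0, len(grid) - 1)
    lo = np.floor(t).astype(int)
    hi = np.clip(lo + 1, 0, len(grid) - 1)
    frac = t - lo
    midpoint = np.abs(frac - 0.5) <= _MIDPOINT_TOL
    take_hi = frac > 0.5
    lev_lo = grid.levels[lo]
    lev_hi = grid.levels[hi]
    # midpoints: pick the level nearer zero (ties: the lower level)
    hi_toward_zero = np.abs(lev_hi) < np.abs(lev_lo)
    take_hi = np.where(midpoint, hi_toward_zero, take_hi)
    out = np.clip(np.where(take_hi, lev_hi, lev_lo), grid.v_min, grid.v_max)
    if np.isscalar(v) or arr.ndim == 0:
        return float(out)
    return out


@dataclass
class ClusterProfile:
    """Cluster x group matrix of palette-quantized mean z-scores."""

    values: pd.DataFrame  # index cluster id 1..k, columns GROUPS
    grid: PaletteGrid
    k: int

    def column(self, group: str) -> pd.Series:
        if group not in self.values.columns:
            raise ValueError(f"unknown group {group!r}")
        return self.values[group]


def cluster_profile(
    gm: pd.DataFrame, assign: ClusterAssignment, grid: PaletteGrid
) -> ClusterProfile:
    """Quantized per-cluster mean of the group-mean z matrix.

    Entry (c, G) = quantize(mean over genes of cluster c of gm[gene, G]).
    """
    missing = [g for g in gm.index if g not in assign.labels.index]
    if missing:
        raise ValueError(f"assignment missing {len(missing)} genes, e.g. {missing[:5]}")
    rows = {}
    for c in range(1, assign.k + 1):
        genes = [g for g in assign.genes_in(c) if g in gm.index]
        if not genes:
            raise ValueError(f"cluster {c} has no genes in the matrix")
        rows[c] = quantize(gm.loc[genes].mean(axis=0).to_numpy(), grid)
    values = pd.DataFrame.from_dict(rows, orient="index", columns=list(gm.columns))
    values.index.name = "cluster"
    return ClusterProfile(values=values, grid=grid, k=assign.k)


def net_change(profile: ClusterProfile, group: str) -> float:
    """Sum of a group column's quantized cluster values, in palette units."""
    return float(profile.column(group).sum())


NET_DIFFERENCE_MODES = ("per_cluster_L1", "column_sum")


def net_difference(
    profile: ClusterProfile, group_a: str, group_b: str, mode: str = "per_cluster_L1"
) -> float:
    """Net difference in units between two group columns (symmetric, >= 0)."""
    if mode not in NET_DIFFERENCE_MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {NET_DIFFERENCE_MODES}")
    qa = profile.column(group_a).to_numpy()
    qb = profile.column(group_b).to_numpy()
    if mode == "per_cluster_L1":
        return float(np.abs(qa - qb).sum())
    return float(abs(qa.sum() - qb.sum()))


@dataclass
class PCAResult:
    """Sample scores, gene loadings, and variance fractions from centered SVD."""

    scores: pd.DataFrame  # samples x PC1..PCm
    loadings: pd.DataFrame  # genes x PC1..PCm
    variance_fraction: pd.Series


def pca(x: ExpressionMatrix) -> PCAResult:
    """PCA of samples over genes: SVD of the gene-centered sample x gene matrix.

    Genes are centered; no unit-variance scaling. Sign convention: each
    loading vector's largest-magnitude entry is positive.
    """
    if x.transform != "log2":
        raise ValueError(f"pca expects log2-transformed input, got {x.transform!r}")
    mat = x.values.to_numpy(dtype=float).T  # samples x genes
    if mat.shape[0] < 2:
        raise ValueError("pca needs at least 2 samples")
    centered = mat - mat.mean(axis=0, keepdims=True)
    if np.allclose(centered, 0):
        raise ValueError("constant matrix: no variance to decompose")
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    for i in range(len(s)):
        j = int(np.argmax(np.abs(vt[i])))
        if vt[i, j] < 0:
            vt[i] *= -1.0
            u[:, i] *= -1.0
    pcs = [f"PC{i + 1}" for i in range(len(s))]
    scores = pd.DataFrame(u * s, index=x.values.columns, columns=pcs)
    loadings = pd.DataFrame(vt.T, index=x.values.index, columns=pcs)
    var = s**2
    variance_fraction = pd.Series(var / var.sum(), index=pcs, name="variance_fraction")
    return PCAResult(scores=scores, loadings=loadings, variance_fraction=variance_fraction)


@dataclass
class PCAConvergence:
    """Group centroids in the chosen PC plane and the convergence distances."""

    dims: tuple[int, ...]
    centroids: pd.DataFrame  # groups x dims
    d_sdgf_sdgm: float
    d_sdf_sdm: float
    d_sdgf_sdf: float
    converged: bool
    variance_covered: float


def pca_convergence(
    p: PCAResult, samples: pd.DataFrame, dims: tuple[int, ...] = (1, 2)
) -> PCAConvergence:
    """Group-centroid distances in PC space and the convergence flag.

    The flag is d(SDGF, SDGM) < d(SDF, SDM): under convergence the
    grape-diet female centroid sits nearer the grape-diet male centroid than
    the standard-diet sexes sit to each other.
    """
    pcs = [f"PC{d}" for d in dims]
    missing = [c for c in pcs if c not in p.scores.columns]
    if missing:
        raise ValueError(f"PCA has no components {missing}")
    cents = {}
    for group in GROUPS:
        members = [s for s in samples.index[samples["group"] == group] if s in p.scores.index]
        if not members:
            raise ValueError(f"group {group!r} has no samples in the PCA scores")
        cents[group] = p.scores.loc[members, pcs].mean(axis=0)
    centroids = pd.DataFrame(cents).T.loc[list(GROUPS)]

    def dist(a: str, b: str) -> float:
        return float(np.linalg.norm(centroids.loc[a] - centroids.loc[b]))

    d_gfgm = dist("SDGF", "SDGM")
    d_fm = dist("SDF", "SDM")
    return PCAConvergence(
        dims=tuple(dims),
        centroids=centroids,
        d_sdgf_sdgm=d_gfgm,
        d_sdf_sdm=d_fm,
        d_sdgf_sdf=dist("SDGF", "SDF"),
        converged=bool(d_gfgm < d_fm),
        variance_covered=float(p.variance_fraction[pcs].sum()),
    )
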