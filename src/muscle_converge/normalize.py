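"""Depth normalization and expression transforms.

Size factors follow the classical median-of-ratios construction (each
sample's median ratio to the per-gene geometric mean, computed over genes
with all-positive counts) and are rescaled to geometric mean 1 so they are
identifiable. FPKM is counts * 1e9 / (length_bp * column_sum). zFPKM
standardizes log2 FPKM per sample against the mode of its kernel density
estimate, with the spread estimated from the right (high-expression) half of
the distribution treated as half of a Gaussian — the standardization used to
put heatmap expression on a z-score scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountMatrix

TRANSFORMS = ("fpkm", "log2", "zscore")

# zFPKM numerical constants: Silverman/nrd0 bandwidth, 512-point density grid
_ZFPKM_GRID_POINTS = 512
_ZFPKM_MIN_POSITIVE = 50


@dataclass
class ExpressionMatrix:
    """Real-valued gene x sample matrix tagged with its transform."""

    values: pd.DataFrame
    transform: str
    size_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.transform not in TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}; expected one of {TRANSFORMS}")
        if self.transform == "fpkm" and (self.values.to_numpy() < 0).any():
            raise ValueError("FPKM values must be non-negative")


def size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Only genes with strictly positive counts in every sample enter the
    median; raises if no such gene exists.
    """
    mat = counts.counts.to_numpy(dtype=float)
    allpos = (mat > 0).all(axis=1)
    if not allpos.any():
        raise ValueError(
            "no gene has positive counts in every sample; "
            "filter low-count genes or samples before computing size factors"
        )
    sub = mat[allpos]
    log_geomean = np.log(sub).mean(axis=1)
    ratios = np.log(sub) - log_geomean[:, None]
    log_sf = np.median(ratios, axis=0)
    log_sf = log_sf - log_sf.mean()  # geometric mean 1
    return pd.Series(np.exp(log_sf), index=counts.counts.columns, name="size_factor")


def fpkm(counts: CountMatrix, annot: pd.Series) -> ExpressionMatrix:
    """Fragments Per Kilobase of transcript per Million mapped reads.

    FPKM_gj = count_gj * 1e9 / (length_g * total_j), with total_j the raw
    column sum standing in for the sample's mapped-fragment total.
    """
    missing = [g for g in counts.gene_ids if g not in annot.index]
    if missing:
        raise ValueError(f"annotation missing {len(missing)} genes, e.g. {missing[:5]}")
    lengths = annot.loc[counts.gene_ids].to_numpy(dtype=float)
    totals = counts.counts.sum(axis=0).to_numpy(dtype=float)
    if (totals == 0).any():
        bad = counts.counts.columns[totals == 0][0]
        raise ValueError(f"sample {bad!r} has zero total counts")
    vals = counts.counts.to_numpy(dtype=float) * 1e9 / (lengths[:, None] * totals[None, :])
    return ExpressionMatrix(
        values=pd.DataFrame(vals, index=counts.counts.index, columns=counts.counts.columns),
        transform="fpkm",
    )


def log2p1(
    x: ExpressionMatrix | CountMatrix, size_factors: pd.Series | None = None
) -> ExpressionMatrix:
    """Elementwise log2(x + 1); counts are divided by size factors first if given."""
    if isinstance(x, CountMatrix):
        vals = x.counts.astype(float)
    else:
        vals = x.values.astype(float)
    if size_factors is not None:
        vals = vals / size_factors.loc[vals.columns]
    if (vals.to_numpy() < 0).any():
        raise ValueError("log2p1 requires non-negative input")
    return ExpressionMatrix(values=np.log2(vals + 1.0), transform="log2", size_factors=size_factors)


def _nrd0_bandwidth(x: np.ndarray) -> float:
    """Silverman's rule-of-thumb bandwidth (R's bw.nrd0)."""
    sd = x.std(ddof=1)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    sigma = min(sd, iqr / 1.34) if iqr > 0 else sd
    if sigma <= 0:
        raise ValueError("constant log2 FPKM input: bandwidth is zero")
    return 0.9 * sigma * len(x) ** (-0.2)


def _density_mode(x: np.ndarray, h: float) -> float:
    grid = np.linspace(x.min() - 3 * h, x.max() + 3 * h, _ZFPKM_GRID_POINTS)
    dens = np.zeros_like(grid)
    # chunk the gene axis to bound memory on large samples
    for start in range(0, len(x), 4096):
        chunk = x[start : start + 4096]
        dens += np.exp(-0.5 * ((grid[:, None] - chunk[None, :]) / h) ** 2).sum(axis=1)
    return float(grid[int(np.argmax(dens))])


def zfpkm(fpkm_matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Per-sample zFPKM standardization of an FPKM matrix.

    For each sample: x = log2(FPKM) over genes with FPKM > 0; mu is the
    argmax of a Gaussian KDE of x (Silverman bandwidth, 512-point grid on
    [min - 3h, max + 3h]); sigma is the RMS deviation of the values above the
    mode (half-Gaussian fit to the actively-expressed right flank);
    z = (x - mu) / sigma. Genes with FPKM = 0 get that sample's minimum
    finite z minus 1.
    """
    if fpkm_matrix.transform != "fpkm":
        raise ValueError(f"zfpkm expects an fpkm matrix, got {fpkm_matrix.transform!r}")
    vals = fpkm_matrix.values
    out = np.empty(vals.shape, dtype=float)
    for j, sample in enumerate(vals.columns):
        col = vals[sample].to_numpy(dtype=float)
        pos = col > 0
        n_pos = int(pos.sum())
        if n_pos < _ZFPKM_MIN_POSITIVE:
            raise ValueError(
                f"sample {sample!r}: only {n_pos} genes with FPKM > 0 "
                f"(need >= {_ZFPKM_MIN_POSITIVE})"
            )
        x = np.log2(col[pos])
        h = _nrd0_bandwidth(x)
        mu = _density_mode(x, h)
        right = x[x > mu]
        if len(right) == 0:
            raise ValueError(f"sample {sample!r}: no values above the density mode")
        sigma = float(np.sqrt(np.mean((right - mu) ** 2)))
        if sigma == 0:
            raise ValueError(f"sample {sample!r}: zero spread above the mode")
        z = np.empty_like(col)
        z[pos] = (x - mu) / sigma
        z[~pos] = z[pos].min() - 1.0
        out[:, j] = z
    return ExpressionMatrix(
        values=pd.DataFrame(out, index=vals.index, columns=vals.columns),
        transform="zscore",
    )
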