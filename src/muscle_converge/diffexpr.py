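"""Negative-binomial Wald differential expression and DEG summaries.

The two-group test models normalized counts y = count / size_factor as NB
with var(y) approx mu / s + alpha * mu^2. Per-gene dispersion is a pooled
method-of-moments estimate shrunk halfway toward a fitted dispersion-mean
trend alpha(mu) = a0 + a1 / mu; the log2 fold change uses a 0.5 pseudocount
and its standard error comes from the delta method, giving a two-sided
normal Wald p-value. This is a deliberately self-contained NB Wald engine;
exact concordance with any particular DE package is a non-goal — the
downstream convergence statistics are the point.

DEG status uses the thresholds q < 0.05, |log2FC| >= 1, and group-mean
FPKM > 1 (applied to the larger of the two group means).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError
from .io import GROUPS, CountMatrix
from .normalize import ExpressionMatrix

_LN2 = np.log(2.0)
_PSEUDO = 0.5
_ALPHA_FLOOR = 1e-8
_TREND_WEIGHT = 0.5

DE_COLUMNS = [
    "baseMean", "log2fc", "se", "p", "q", "meanFPKM_A", "meanFPKM_B", "status",
]


def bh_adjust(p: np.ndarray | pd.Series | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order.

    q_(i) = min_{j >= i} p_(j) * m / j on the ascending sort, capped at 1.
    """
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1:
        raise ValueError("bh_adjust expects a 1-D vector")
    if np.isnan(arr).any():
        raise ValueError("bh_adjust: missing p-values")
    if ((arr < 0) | (arr > 1)).any():
        bad = arr[(arr < 0) | (arr > 1)][0]
        raise ValueError(f"p-value outside [0, 1]: {bad}")
    m = len(arr)
    if m == 0:
        return arr.copy()
    order = np.argsort(arr, kind="stable")
    ranked = arr[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    out = np.empty(m, dtype=float)
    out[order] = q_sorted
    return out


def _group_columns(counts: CountMatrix, group: str) -> list[str]:
    cols = counts.samples_in(group)
    if len(cols) < 2:
        raise ValueError(f"group {group!r} has {len(cols)} samples; need >= 2 replicates")
    return cols


def _fit_dispersion_trend(alpha_raw: np.ndarray, mu: np.ndarray) -> tuple[float, float]:
    """Least-squares fit of alpha ~ a0 + a1/mu over genes with mu > 0."""
    ok = mu > 0
    if ok.sum() < 2:
        return _ALPHA_FLOOR, 0.0
    x = 1.0 / mu[ok]
    y = alpha_raw[ok]
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    a0 = max(float(coef[0]), _ALPHA_FLOOR)
    a1 = max(float(coef[1]), 0.0)
    return a0, a1


def nb_wald(
    counts: CountMatrix,
    group_a: str,
    group_b: str,
    sf: pd.Series,
    fpkm: ExpressionMatrix | None = None,
) -> pd.DataFrame:
    """Two-group NB Wald test; log2fc is B over A.

    Returns a per-gene DataFrame with columns baseMean, log2fc, se, p, q,
    meanFPKM_A, meanFPKM_B, status. Genes with all-zero raw counts in both
    groups are status='excluded' with p and q unset; all others start 'ns'
    until :func:`classify_degs` applies the DEG thresholds.
    """
    cols_a = _group_columns(counts, group_a)
    cols_b = _group_columns(counts, group_b)
    raw = counts.counts
    sf = sf.loc[raw.columns]
    y = raw / sf

    ya = y[cols_a].to_numpy(dtype=float)
    yb = y[cols_b].to_numpy(dtype=float)
    na, nb = ya.shape[1], yb.shape[1]
    mu_a = ya.mean(axis=1)
    mu_b = yb.mean(axis=1)

    ssq = ((ya - mu_a[:, None]) ** 2).sum(axis=1) + ((yb - mu_b[:, None]) ** 2).sum(axis=1)
    s2 = ssq / (na + nb - 2)
    mu_bar = (na * mu_a + nb * mu_b) / (na + nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_raw = np.where(mu_bar > 0, (s2 - mu_bar) / np.square(mu_bar), 0.0)
    a0, a1 = _fit_dispersion_trend(alpha_raw, mu_bar)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_trend = np.where(mu_bar > 0, a0 + a1 / mu_bar, a0)
    alpha = _TREND_WEIGHT * np.maximum(alpha_raw, _ALPHA_FLOOR) + (1 - _TREND_WEIGHT) * alpha_trend
    alpha = np.maximum(alpha, _ALPHA_FLOOR)

    log2fc = np.log2((mu_b + _PSEUDO) / (mu_a + _PSEUDO))

    inv_sf_a = float((1.0 / sf.loc[cols_a]).sum())
    inv_sf_b = float((1.0 / sf.loc[cols_b]).sum())
    var_mu_a = mu_a * inv_sf_a / na**2 + alpha * np.square(mu_a) / na
    var_mu_b = mu_b * inv_sf_b / nb**2 + alpha * np.square(mu_b) / nb
    var_log_a = var_mu_a / (np.square(mu_a + _PSEUDO) * _LN2**2)
    var_log_b = var_mu_b / (np.square(mu_b + _PSEUDO) * _LN2**2)
    se = np.sqrt(var_log_a + var_log_b)

    excluded = (raw[cols_a].sum(axis=1) + raw[cols_b].sum(axis=1)).to_numpy() == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p[excluded] = np.nan

    q = np.full_like(p, np.nan)
    if (~excluded).any():
        q[~excluded] = bh_adjust(p[~excluded])

    de = pd.DataFrame(
        {
            "baseMean": np.concatenate([ya, yb], axis=1).mean(axis=1),
            "log2fc": log2fc,
            "se": se,
            "p": p,
            "q": q,
            "meanFPKM_A": np.nan,
            "meanFPKM_B": np.nan,
            "status": np.where(excluded, "excluded", "ns"),
        },
        index=raw.index,
    )
    if fpkm is not None:
        de["meanFPKM_A"] = fpkm.values[cols_a].mean(axis=1)
        de["meanFPKM_B"] = fpkm.values[cols_b].mean(axis=1)
    return de


def classify_degs(
    de: pd.DataFrame,
    q_thresh: float = 0.05,
    lfc_thresh: float = 1.0,
    fpkm_thresh: float = 1.0,
) -> pd.DataFrame:
    """Fill DEG status: up iff q < q_thresh, log2fc >= lfc_thresh, and the
    larger group-mean FPKM exceeds fpkm_thresh; down symmetrically; else ns.
    """
    if q_thresh <= 0 or lfc_thresh <= 0 or fpkm_thresh <= 0:
        raise ConfigError("DEG thresholds must be positive")
    out = de.copy()
    sel = out["status"] != "excluded"
    max_fpkm = out[["meanFPKM_A", "meanFPKM_B"]].max(axis=1)
    sig = sel & (out["q"] < q_thresh) & (max_fpkm > fpkm_thresh)
    out.loc[sel, "status"] = "ns"
    out.loc[sig & (out["log2fc"] >= lfc_thresh), "status"] = "up"
    out.loc[sig & (out["log2fc"] <= -lfc_thresh), "status"] = "down"
    return out


def volcano_summary(de: pd.DataFrame) -> tuple[int, int, int]:
    """(total non-excluded, up, down) counts for a classified DE result."""
    non_excl = de["status"] != "excluded"
    return (
        int(non_excl.sum()),
        int((de["status"] == "up").sum()),
        int((de["status"] == "down").sum()),
    )


def deg_sets(de: pd.DataFrame) -> dict[str, set[str]]:
    """Up- and down-regulated gene id sets of a classified DE result."""
    return {
        "up": set(de.index[de["status"] == "up"]),
        "down": set(de.index[de["status"] == "down"]),
    }


def expressed_sets(
    fpkm: ExpressionMatrix, samples: pd.DataFrame, threshold: float = 1.0
) -> dict[str, set[str]]:
    """Per-group sets of genes with group-mean FPKM strictly above threshold."""
    if fpkm.transform != "fpkm":
        raise ValueError(f"expressed_sets expects fpkm, got {fpkm.transform!r}")
    out: dict[str, set[str]] = {}
    for group in GROUPS:
        cols = list(samples.index[samples["group"] == group])
        cols = [c for c in cols if c in fpkm.values.columns]
        if not cols:
            raise ValueError(f"group {group!r} has no samples in the matrix")
        means = fpkm.values[cols].mean(axis=1)
        out[group] = set(means.index[means > threshold])
    return out


def venn_counts(sets: dict[str, set[str]]) -> dict[str, int]:
    """Counts for the 15 membership regions of four named sets.

    Region keys join member set names with '&' in the given key order
    (e.g. 'SDM&SDF'); regions partition the union.
    """
    if len(sets) != 4:
        raise ValueError(f"venn_counts requires exactly 4 sets, got {len(sets)}")
    names = list(sets.keys())
    union = set().union(*sets.values())
    regions: dict[str, int] = {}
    for mask in range(1, 16):
        inside = [names[i] for i in range(4) if mask >> i & 1]
        outside = [names[i] for i in range(4) if not mask >> i & 1]
        region = set(union)
        for nm in inside:
            region &= sets[nm]
        for nm in outside:
            region -= sets[nm]
        regions["&".join(inside)] = len(region)
    return regions
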