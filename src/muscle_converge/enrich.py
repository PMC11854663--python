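"""Hypergeometric over-representation analysis and convergence classification.

ORA tests each gene set for over-representation in a query list (e.g. the
up-regulated DEGs of one contrast) against a universe of expressed genes,
with the upper-tail hypergeometric p-value and BH adjustment across the
retained sets. Sets are intersected with the universe first; sets with fewer
than three members in the universe are dropped (logged).

The classification step reproduces the cross-contrast set-algebra applied to
enriched pathways: a set enriched between the sexes under the standard diet
either *persists* under the grape diet or is *negated*; negation is
attributed to the female shift (the set moves in SDGF vs SDF in the
direction that closes the sex gap), the male shift (SDGM vs SDM), both, or
neither (unattributed). Sets enriched between the sexes only under the grape
diet are *emergent*.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .io import GeneSetCollection

logger = logging.getLogger(__name__)

CATEGORIES = (
    "persistent",
    "negated_female_shift",
    "negated_male_shift",
    "negated_both",
    "negated_unattributed",
    "emergent",
)

ENRICHMENT_COLUMNS = ["set_id", "K", "n", "k", "N", "p", "q"]


def hypergeom_tail(k, K: int, n: int, N: int):
    """P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn).

    ``k`` may be a scalar or an array of overlap counts; the survival
    function is evaluated stably (log-space internally via scipy).
    """
    karr = np.asarray(k)
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent hypergeometric counts K={K}, n={n}, N={N}")
    if ((karr < 0) | (karr > min(K, n))).any():
        raise ValueError(f"overlap k={k} outside [0, min(K, n)] for K={K}, n={n}")
    res = stats.hypergeom.sf(karr - 1, N, K, n)
    if np.isscalar(k):
        return float(res)
    return res


def ora(
    query: set[str],
    gmt: GeneSetCollection,
    universe: set[str],
    min_set_size: int = 3,
) -> pd.DataFrame:
    """Over-representation of each gene set in the query, within the universe.

    Returns one row per retained set (columns set_id, K, n, k, N, p, q),
    sorted by ascending p (ties by set_id for determinism).
    """
    if not query:
        raise ValueError("empty query gene set")
    if not universe:
        raise ValueError("empty universe")
    stray = query - universe
    if stray:
        raise ValueError(f"query contains {len(stray)} genes outside the universe")
    N = len(universe)
    n = len(query)
    rows = []
    for gs in gmt:
        members = set(gs.members) & universe
        if len(members) < min_set_size:
            logger.info("dropping set %r: %d members in universe (< %d)",
                        gs.set_id, len(members), min_set_size)
            continue
        K = len(members)
        k = len(members & query)
        rows.append((gs.set_id, K, n, k, N, hypergeom_tail(k, K, n, N)))
    result = pd.DataFrame(rows, columns=["set_id", "K", "n", "k", "N", "p"])
    if len(result):
        result["q"] = bh_adjust(result["p"].to_numpy())
    else:
        result["q"] = np.array([], dtype=float)
    return result.sort_values(["p", "set_id"], kind="stable").reset_index(drop=True)


def _sig_sets(result: pd.DataFrame, alpha: float) -> set[str]:
    return set(result.loc[result["q"] < alpha, "set_id"])


def _check_universe(results: list[pd.DataFrame]) -> None:
    sizes = {int(r["N"].iloc[0]) for r in results if len(r)}
    if len(sizes) > 1:
        raise ValueError(f"mismatched universes across contrasts: sizes {sorted(sizes)}")


def classify_convergence(
    enr_sd: dict[str, pd.DataFrame],
    enr_sdg: dict[str, pd.DataFrame],
    enr_f: dict[str, pd.DataFrame],
    enr_m: dict[str, pd.DataFrame],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Cross-contrast convergence category per (set, direction).

    Each argument maps direction ('up' | 'down') to an ORA result; the
    contrasts are oriented female-over-male for the sex contrasts (SDF vs
    SDM under the standard diet, SDGF vs SDGM under the grape diet) and
    grape-over-standard for the within-sex diet contrasts (SDGF vs SDF,
    SDGM vs SDM). 'up' in a sex contrast therefore means female-enriched.

    A female-enriched set under SD closes the sex gap if females fall
    (enriched among genes down in SDGF vs SDF) or males rise (up in SDGM vs
    SDM); a male-enriched set symmetrically. Returns rows (set_id,
    direction, category, q_sd, q_sdg, q_f_up, q_f_down, q_m_up, q_m_down).
    """
    for d in ("up", "down"):
        for arg in (enr_sd, enr_sdg, enr_f, enr_m):
            if d not in arg:
                raise ValueError(f"missing {d!r} enrichment result")
    _check_universe(
        [r for arg in (enr_sd, enr_sdg, enr_f, enr_m) for r in arg.values()]
    )

    def qval(result: pd.DataFrame, set_id: str) -> float:
        row = result.loc[result["set_id"] == set_id, "q"]
        return float(row.iloc[0]) if len(row) else np.nan

    rows = []
    for direction in ("up", "down"):
        gap_close_f = "down" if direction == "up" else "up"  # female moves opposite her excess
        gap_close_m = "up" if direction == "up" else "down"  # male moves toward the female side
        sd_sig = _sig_sets(enr_sd[direction], alpha)
        sdg_sig = _sig_sets(enr_sdg[direction], alpha)
        f_sig = _sig_sets(enr_f[gap_close_f], alpha)
        m_sig = _sig_sets(enr_m[gap_close_m], alpha)
        for set_id in sorted(sd_sig | sdg_sig):
            if set_id in sd_sig:
                if set_id in sdg_sig:
                    category = "persistent"
                else:
                    f_hit, m_hit = set_id in f_sig, set_id in m_sig
                    if f_hit and m_hit:
                        category = "negated_both"
                    elif f_hit:
                        category = "negated_female_shift"
                    elif m_hit:
                        category = "negated_male_shift"
                    else:
                        category = "negated_unattributed"
            else:
                category = "emergent"
            rows.append(
                {
                    "set_id": set_id,
                    "direction": direction,
                    "category": category,
                    "q_sd": qval(enr_sd[direction], set_id),
                    "q_sdg": qval(enr_sdg[direction], set_id),
                    "q_f_up": qval(enr_f["up"], set_id),
                    "q_f_down": qval(enr_f["down"], set_id),
                    "q_m_up": qval(enr_m["up"], set_id),
                    "q_m_down": qval(enr_m["down"], set_id),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["set_id", "direction", "category",
                 "q_sd", "q_sdg", "q_f_up", "q_f_down", "q_m_up", "q_m_down"],
    )
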