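import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from muscle_converge.datagen import SimulationConfig, simulate_counts
from muscle_converge.diffexpr import (
    bh_adjust,
    classify_degs,
    deg_sets,
    expressed_sets,
    nb_wald,
    venn_counts,
    volcano_summary,
)
from muscle_converge.errors import ConfigError
from muscle_converge.normalize import ExpressionMatrix, fpkm, size_factors

from conftest import make_count_matrix


def bh_brute_force(p: np.ndarray) -> np.ndarray:
    """Independent step-up oracle: direct min-over-suffix on the sorted array."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank, idx in enumerate(order, start=1):
        suffix = [p[order[j]] * m / (j + 1) for j in range(rank - 1, m)]
        q[idx] = min(1.0, min(suffix))
    return q


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.005, 0.01, 0.03, 0.04]), [0.02, 0.02, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            bh_adjust([0.5, 1.2])
        with pytest.raises(ValueError, match="missing"):
            bh_adjust([0.5, np.nan])

    def test_q_never_below_p(self):
        rng = np.random.default_rng(0)
        p = rng.random(500)
        assert (bh_adjust(p) >= p).all()

    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(rng.integers(1, 40))
        np.testing.assert_allclose(bh_adjust(p), bh_brute_force(p), rtol=1e-12)


class TestNbWald:
    def test_fourfold_change_recovered(self, two_group_nb):
        cm = two_group_nb(np.full(2000, 100.0), np.full(2000, 400.0),
                          alpha=0.01, n_a=50, n_b=50, seed=5)
        sf = pd.Series(1.0, index=cm.sample_ids)
        de = nb_wald(cm, "SDM", "SDF", sf)
        assert de["log2fc"].median() == pytest.approx(2.0, abs=0.1)

    def test_null_false_positive_rate_near_nominal(self, two_group_nb):
        cm = two_group_nb(np.full(2000, 100.0), np.full(2000, 100.0),
                          alpha=0.1, n_a=5, n_b=5, seed=8)
        sf = pd.Series(1.0, index=cm.sample_ids)
        de = nb_wald(cm, "SDM", "SDF", sf)
        assert (de["p"] < 0.05).mean() == pytest.approx(0.05, abs=0.02)

    def test_all_zero_gene_excluded(self):
        counts = np.array([[0, 0, 0, 0], [5, 6, 7, 8]])
        cm = make_count_matrix(counts, ["dead", "live"], ["SDM"] * 2 + ["SDF"] * 2)
        de = nb_wald(cm, "SDM", "SDF", pd.Series(1.0, index=cm.sample_ids))
        assert de.loc["dead", "status"] == "excluded"
        assert np.isnan(de.loc["dead", "p"]) and np.isnan(de.loc["dead", "q"])
        assert de.loc["live", "status"] == "ns"

    def test_swapping_groups_negates_lfc_and_preserves_p(self, small_sim):
        cm, _ = small_sim
        sf = size_factors(cm)
        ab = nb_wald(cm, "SDM", "SDF", sf)
        ba = nb_wald(cm, "SDF", "SDM", sf)
        np.testing.assert_allclose(ab["log2fc"], -ba["log2fc"], rtol=1e-9)
        np.testing.assert_allclose(
            ab["p"].dropna(), ba["p"].dropna(), rtol=1e-9
        )

    def test_single_replicate_group_rejected(self):
        cm = make_count_matrix(np.ones((3, 3), dtype=int), list("abc"),
                               ["SDM", "SDF", "SDF"])
        with pytest.raises(ValueError, match=">= 2"):
            nb_wald(cm, "SDM", "SDF", pd.Series(1.0, index=cm.sample_ids))


TEN_GENE_FIXTURE = pd.DataFrame(
    {
        "q": [0.01, 0.04, 0.001, 0.2, 0.06, 0.01, 0.03, 0.5, 0.02, 0.04],
        "log2fc": [1.5, 1.0, 2.5, 3.0, 3.0, -1.2, -2.0, -3.0, 0.5, 1.4],
        "meanFPKM_A": [5.0, 2.0, 9.0, 8.0, 8.0, 4.0, 3.0, 7.0, 6.0, 0.4],
        "meanFPKM_B": [9.0, 4.0, 30.0, 60.0, 60.0, 1.5, 0.4, 0.5, 7.0, 0.9],
    },
    index=[f"g{i}" for i in range(10)],
)
# rule-by-rule enumeration: up needs q<0.05 & lfc>=1 & maxFPKM>1
#   g0 up, g1 up, g2 up; g3 fails q; g4 fails q; g5 down, g6 down;
#   g7 fails q; g8 fails lfc; g9 fails FPKM  -> 3 up, 2 down, 5 ns


def _with_status(df):
    df = df.copy()
    df["status"] = "ns"
    df["p"] = df["q"] / 2
    return df


class TestClassifyDegs:
    def test_ten_gene_fixture_counts(self):
        de = classify_degs(_with_status(TEN_GENE_FIXTURE))
        assert (de["status"] == "up").sum() == 3
        assert (de["status"] == "down").sum() == 2
        assert (de["status"] == "ns").sum() == 5

    def test_lfc_threshold_is_inclusive(self):
        de = _with_status(
            pd.DataFrame({"q": [0.01], "log2fc": [1.0],
                          "meanFPKM_A": [5.0], "meanFPKM_B": [2.0]}, index=["g"])
        )
        assert classify_degs(de).loc["g", "status"] == "up"

    def test_q_rule_failure_is_ns(self):
        de = _with_status(
            pd.DataFrame({"q": [0.06], "log2fc": [3.0],
                          "meanFPKM_A": [5.0], "meanFPKM_B": [2.0]}, index=["g"])
        )
        assert classify_degs(de).loc["g", "status"] == "ns"

    def test_non_positive_thresholds_rejected(self):
        with pytest.raises(ConfigError):
            classify_degs(_with_status(TEN_GENE_FIXTURE), q_thresh=0.0)


class TestVolcanoSummary:
    def test_ten_gene_fixture(self):
        de = classify_degs(_with_status(TEN_GENE_FIXTURE))
        assert volcano_summary(de) == (10, 3, 2)

    def test_reordering_invariant(self):
        de = classify_degs(_with_status(TEN_GENE_FIXTURE))
        assert volcano_summary(de.iloc[::-1]) == volcano_summary(de)

    def test_all_ns(self):
        de = _with_status(TEN_GENE_FIXTURE)
        assert volcano_summary(de) == (10, 0, 0)


class TestExpressedSets:
    def _fpkm(self, values, groups):
        genes = [f"g{i}" for i in range(len(values))]
        cm = make_count_matrix(np.ones((len(values), len(groups)), dtype=int),
                               genes, groups)
        vals = pd.DataFrame(values, index=genes, columns=cm.sample_ids)
        return ExpressionMatrix(vals, transform="fpkm"), cm.samples

    def test_group_mean_rule_and_strict_boundary(self):
        em, samples = self._fpkm(
            [[1.0, 1.4, 0.8, 1.0, 1.0, 1.0, 0.0, 0.0],
             [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0]],
            ["SDM", "SDM", "SDF", "SDF", "SDGM", "SDGM", "SDGF", "SDGF"],
        )
        # g0: SDM mean 1.2 > 1 in; SDF mean 0.9 out; SDGM mean exactly 1 out
        sets = expressed_sets(em, samples)
        assert sets["SDM"] == {"g0"}
        assert sets["SDF"] == set() and sets["SDGM"] == set()
        # all-zero gene in no set
        assert all("g1" not in s for s in sets.values())

    def test_absent_group_rejected(self):
        genes = ["g0"]
        cm = make_count_matrix(np.ones((1, 2), dtype=int), genes, ["SDM", "SDM"])
        em = ExpressionMatrix(
            pd.DataFrame([[2.0, 2.0]], index=genes, columns=cm.sample_ids), "fpkm"
        )
        with pytest.raises(ValueError, match="no samples"):
            expressed_sets(em, cm.samples)

    def test_strict_threshold_boundary(self, small_sim):
        cm, truth = small_sim
        em = fpkm(cm, truth.genes["length_bp"].astype(float))
        forced = em.values.copy()
        forced.iloc[0, :] = 1.0  # group means exactly 1
        sets = expressed_sets(ExpressionMatrix(forced, "fpkm"), cm.samples)
        assert all(forced.index[0] not in s for s in sets.values())


class TestVennCounts:
    def test_enumerated_example(self):
        sets = {"A": {"g1", "g2"}, "B": {"g1", "g3"}, "C": {"g1"}, "D": {"g1", "g4"}}
        v = venn_counts(sets)
        assert v["A&B&C&D"] == 1
        assert v["A"] == 1 and v["B"] == 1 and v["D"] == 1
        assert sum(v.values()) == 4
        assert v["C"] == 0

    def test_identical_sets(self):
        s = {"A": {"x", "y"}, "B": {"x", "y"}, "C": {"x", "y"}, "D": {"x", "y"}}
        v = venn_counts(s)
        assert v["A&B&C&D"] == 2
        assert sum(v.values()) == 2

    @given(st.integers(0, 2**31 - 1))
    def test_regions_partition_the_union(self, seed):
        rng = np.random.default_rng(seed)
        universe = [f"g{i}" for i in range(30)]
        sets = {
            name: set(rng.choice(universe, size=rng.integers(0, 20), replace=False))
            for name in ("A", "B", "C", "D")
        }
        v = venn_counts(sets)
        assert len(v) == 15
        assert sum(v.values()) == len(set().union(*sets.values()))

    def test_wrong_set_count_rejected(self):
        with pytest.raises(ValueError, match="4 sets"):
            venn_counts({"A": set(), "B": set()})


class TestDERecoveryOnSimulatedTruth:
    def test_sensitivity_and_fdr_with_planted_two_unit_effects(self):
        """|log2fc|=2 effects at n=5/group: sensitivity >= 0.8, FDR <= 0.1."""
        sens, fdr = [], []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 2000
            base = rng.lognormal(4.5, 0.8, n)
            signs = rng.choice([-1.0, 1.0], size=n)
            is_deg = np.zeros(n, dtype=bool)
            is_deg[rng.choice(n, size=200, replace=False)] = True
            mu_a = base
            mu_b = np.where(is_deg, base * np.exp2(2.0 * signs), base)
            counts = np.empty((n, 10), dtype=np.int64)
            for j in range(5):
                alpha = 0.05 + 5.0 / mu_a
                r = 1 / alpha
                counts[:, j] = rng.negative_binomial(r, r / (r + mu_a))
            for j in range(5, 10):
                alpha = 0.05 + 5.0 / mu_b
                r = 1 / alpha
                counts[:, j] = rng.negative_binomial(r, r / (r + mu_b))
            cm = make_count_matrix(counts, [f"g{i}" for i in range(n)],
                                   ["SDM"] * 5 + ["SDF"] * 5)
            sf = size_factors(cm)
            annot = pd.Series(1000.0, index=cm.counts.index)
            de = classify_degs(nb_wald(cm, "SDM", "SDF", sf, fpkm=fpkm(cm, annot)))
            called = de["status"].isin(["up", "down"]).to_numpy()
            tp = (called & is_deg).sum()
            sens.append(tp / is_deg.sum())
            fdr.append((called & ~is_deg).sum() / max(called.sum(), 1))
        assert np.mean(sens) >= 0.8
        assert np.mean(fdr) <= 0.1

    def test_degs_enriched_in_true_sex_dimorphic_genes(self):
        cfg = SimulationConfig(n_genes=1000, seed=4)
        cm, truth = simulate_counts(cfg)
        sf = size_factors(cm)
        em = fpkm(cm, truth.genes["length_bp"].astype(float))
        de = classify_degs(nb_wald(cm, "SDM", "SDF", sf, fpkm=em))
        called = deg_sets(de)
        hits = called["up"] | called["down"]
        true = set(truth.genes.index[truth.genes["sex_dimorphic"]])
        if hits:
            assert len(hits & true) / len(hits) > 0.5
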