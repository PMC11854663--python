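import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from muscle_converge.datagen import SimulationConfig, simulate_counts
from muscle_converge.io import CountMatrix

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated four-group experiment with known truth."""
    cfg = SimulationConfig(n_genes=600, seed=11, rho_convergence=0.5)
    return simulate_counts(cfg)


def make_count_matrix(counts: np.ndarray, gene_ids, groups_per_sample) -> CountMatrix:
    """Build a validated CountMatrix from an array and per-sample group labels."""
    sex_of = {"SDM": "M", "SDGM": "M", "SDF": "F", "SDGF": "F"}
    diet_of = {"SDM": "SD", "SDGM": "SDG", "SDF": "SD", "SDGF": "SDG"}
    counters: dict[str, int] = {}
    sample_ids = []
    for g in groups_per_sample:
        counters[g] = counters.get(g, 0) + 1
        sample_ids.append(f"{g}_{counters[g]}")
    samples = pd.DataFrame(
        {
            "sex": [sex_of[g] for g in groups_per_sample],
            "diet": [diet_of[g] for g in groups_per_sample],
            "group": list(groups_per_sample),
        },
        index=pd.Index(sample_ids, name="sample"),
    )
    return CountMatrix(
        counts=pd.DataFrame(counts, index=list(gene_ids), columns=sample_ids),
        samples=samples,
    )


@pytest.fixture()
def two_group_nb():
    """Factory for two-group NB count matrices with chosen means/dispersion."""

    def build(mu_a, mu_b, alpha, n_a, n_b, seed=0, group_a="SDM", group_b="SDF"):
        rng = np.random.default_rng(seed)
        mu_a = np.asarray(mu_a, dtype=float)
        mu_b = np.asarray(mu_b, dtype=float)
        r = 1.0 / alpha
        ca = rng.negative_binomial(r, r / (r + mu_a[:, None]), size=(len(mu_a), n_a))
        cb = rng.negative_binomial(r, r / (r + mu_b[:, None]), size=(len(mu_b), n_b))
        genes = [f"g{i}" for i in range(len(mu_a))]
        return make_count_matrix(
            np.hstack([ca, cb]), genes, [group_a] * n_a + [group_b] * n_b
        )

    return build
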