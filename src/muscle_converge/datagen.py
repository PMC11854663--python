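"""Synthetic four-group (sex x diet) RNA-seq count generator with ground truth.

The generator emulates the study design the pipeline analyses: male and female
mice on a standard (SD) or grape-supplemented (SDG) diet, giving four groups
SDM, SDGM, SDF, SDGF with ``n_reps`` biological replicates each. Counts are
negative-binomial with a DESeq-style dispersion-mean trend alpha(mu) = a0 +
a1/mu. A fraction of genes carries a sex effect (SDF mean shifted from the
SDM baseline by a log2 fold change), each sex carries diet-responsive genes,
and a tunable fraction ``rho_convergence`` of the sex-dimorphic genes is
"converged": the SDGF expectation is moved back to the male level under the
grape diet (or to the male/female midpoint when
``convergence_target='midpoint'``), which is the structure behind the
sex-convergence claim the downstream statistics test.

Diet response has a shared component and sex-specific components: genes in
the shared pool move by the same log2 fold change in both sexes (a diet that
"impacts both sexes similarly"), while the sex-specific pools move one sex
only. The shared component is what makes the grape-diet groups SDGM and SDGF
cluster together once the sex gap closes.

Per-gene effects are drawn before any counts, on one seeded RNG stream, so
the ground truth is reproducible independently of the count noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import (
    CONTRASTS,
    GROUP_OF,
    GROUPS,
    CountMatrix,
    GeneSet,
    GeneSetCollection,
    canonical_contrast,
    contrast_name,
    write_annotation,
    write_counts,
)

_LFC_COLS = [contrast_name(b, a) for b, a in CONTRASTS]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic four-group experiment.

    Defaults are the desk-scale study conditions: 2000 genes, 5 replicates
    per group (the study design), ~10% sex-dimorphic genes with log2
    fold-change SD 2, a 10% shared diet-response pool plus 3% sex-specific
    pools with log2 fold-change SD 1, and a DESeq-style dispersion trend
    alpha(mu) = 0.05 + 5/mu.
    """

    n_genes: int = 2000
    n_reps: int = 5
    baseline_logmean_mu: float = 4.0
    baseline_logmean_sd: float = 1.2
    dispersion_a0: float = 0.05
    dispersion_a1: float = 5.0
    frac_sex_dimorphic: float = 0.10
    sex_lfc_sd: float = 2.0
    frac_diet_responsive_m: float = 0.03
    frac_diet_responsive_f: float = 0.03
    frac_diet_responsive_shared: float = 0.10
    diet_lfc_sd: float = 1.0
    rho_convergence: float = 0.0
    libsize_mu: float = 0.0
    libsize_sd: float = 0.2
    gene_length_min: int = 200
    gene_length_max: int = 10000
    convergence_target: str = "male"  # "male" (female moves to male) or "midpoint"
    seed: int = 0

    def validate(self) -> None:
        fracs = {
            "frac_sex_dimorphic": self.frac_sex_dimorphic,
            "frac_diet_responsive_m": self.frac_diet_responsive_m,
            "frac_diet_responsive_f": self.frac_diet_responsive_f,
            "frac_diet_responsive_shared": self.frac_diet_responsive_shared,
            "rho_convergence": self.rho_convergence,
        }
        for name, value in fracs.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {value}")
        if self.n_genes < 1:
            raise ConfigError(f"n_genes must be positive, got {self.n_genes}")
        if self.n_reps < 2:
            raise ConfigError(f"n_reps must be >= 2, got {self.n_reps}")
        # alpha(mu) = a0 + a1/mu must be positive for every mu > 0
        if self.dispersion_a0 <= 0 or self.dispersion_a1 < 0:
            raise ConfigError(
                "dispersion trend requires a0 > 0 and a1 >= 0, got "
                f"a0={self.dispersion_a0}, a1={self.dispersion_a1}"
            )
        if self.gene_length_min < 1 or self.gene_length_max < self.gene_length_min:
            raise ConfigError(
                f"invalid gene length range [{self.gene_length_min}, {self.gene_length_max}]"
            )
        if self.baseline_logmean_sd < 0 or self.sex_lfc_sd < 0 or self.diet_lfc_sd < 0:
            raise ConfigError("effect and baseline SDs must be non-negative")
        if self.libsize_sd < 0:
            raise ConfigError("libsize_sd must be non-negative")
        if self.convergence_target not in ("male", "midpoint"):
            raise ConfigError(
                f"convergence_target must be 'male' or 'midpoint', got {self.convergence_target!r}"
            )


@dataclass
class GroundTruth:
    """Per-gene flags, true per-contrast log2 effects, lengths; per-sample library sizes.

    ``genes`` is indexed by gene id with boolean columns sex_dimorphic,
    diet_responsive_m, diet_responsive_f, converged, integer length_bp, and
    one true-log2-effect column per canonical contrast (B_vs_A).
    """

    genes: pd.DataFrame
    library_sizes: pd.Series
    group_means: pd.DataFrame = field(repr=False, default=None)

    def contrast_set(self, group_a: str, group_b: str) -> set[str]:
        """Gene ids with a nonzero true log2 effect for an unordered group pair."""
        b, a = canonical_contrast(group_a, group_b)
        col = contrast_name(b, a)
        lfc = self.genes[col]
        return set(self.genes.index[lfc.abs() > 1e-12])


def ground_truth_contrast(truth: GroundTruth, contrast: tuple[str, str]) -> set[str]:
    """Genes with a nonzero true effect for one of the six group pairs."""
    return truth.contrast_set(*contrast)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB draws with var = mean + alpha * mean^2 (gamma-Poisson mixture)."""
    alpha = np.maximum(alpha, 1e-12)
    r = 1.0 / alpha
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_counts(config: SimulationConfig) -> tuple[CountMatrix, GroundTruth]:
    """Draw a CountMatrix and its GroundTruth from the generative model.

    Group expectations per gene: SDM = baseline; SDF = baseline * 2^sex_lfc;
    SDGM = baseline * 2^dietM_lfc; SDGF = baseline * 2^(sex_lfc + dietF_lfc),
    except that converged genes have their SDGF expectation reset to the SDM
    baseline (or the log-midpoint). Counts are NB with mean s_j * mu and
    dispersion alpha(mu) evaluated at the group expectation.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    gene_ids = [f"g{i:05d}" for i in range(n)]

    baseline = rng.lognormal(config.baseline_logmean_mu, config.baseline_logmean_sd, n)
    lengths = rng.integers(config.gene_length_min, config.gene_length_max + 1, n)

    sex_flag = rng.random(n) < config.frac_sex_dimorphic
    sex_lfc = np.where(sex_flag, rng.normal(0.0, config.sex_lfc_sd, n), 0.0)
    sex_flag &= sex_lfc != 0.0  # zero effect SD collapses the flag

    dm_flag = rng.random(n) < config.frac_diet_responsive_m
    dm_lfc = np.where(dm_flag, rng.normal(0.0, config.diet_lfc_sd, n), 0.0)
    dm_flag &= dm_lfc != 0.0

    df_flag = rng.random(n) < config.frac_diet_responsive_f
    df_lfc = np.where(df_flag, rng.normal(0.0, config.diet_lfc_sd, n), 0.0)
    df_flag &= df_lfc != 0.0

    sh_flag = rng.random(n) < config.frac_diet_responsive_shared
    sh_lfc = np.where(sh_flag, rng.normal(0.0, config.diet_lfc_sd, n), 0.0)

    converged = sex_flag & (rng.random(n) < config.rho_convergence)

    mean = pd.DataFrame(index=pd.Index(gene_ids, name="gene_id"), columns=list(GROUPS), dtype=float)
    mean["SDM"] = baseline
    mean["SDF"] = baseline * np.exp2(sex_lfc)
    mean["SDGM"] = baseline * np.exp2(dm_lfc + sh_lfc)
    sdgf = baseline * np.exp2(sex_lfc + df_lfc + sh_lfc)
    if config.convergence_target == "male":
        # the male level under the grape diet: baseline shifted by the
        # shared diet effect only (= the SDM baseline when there is none)
        sdgf = np.where(converged, baseline * np.exp2(sh_lfc), sdgf)
    else:
        sdgf = np.where(converged, baseline * np.exp2(sex_lfc / 2.0 + sh_lfc), sdgf)
    mean["SDGF"] = sdgf

    sample_ids, sexes, diets, groups = [], [], [], []
    for group in GROUPS:
        for i in range(config.n_reps):
            sample_ids.append(f"{group}_{i + 1}")
            groups.append(group)
    sex_of = {v: k[0] for k, v in GROUP_OF.items()}
    diet_of = {v: k[1] for k, v in GROUP_OF.items()}
    sexes = [sex_of[g] for g in groups]
    diets = [diet_of[g] for g in groups]

    libsizes = rng.lognormal(config.libsize_mu, config.libsize_sd, len(sample_ids))

    counts = np.empty((n, len(sample_ids)), dtype=np.int64)
    for j, group in enumerate(groups):
        mu = mean[group].to_numpy()
        alpha = config.dispersion_a0 + config.dispersion_a1 / mu
        counts[:, j] = _nb_draw(rng, libsizes[j] * mu, alpha)

    samples = pd.DataFrame(
        {"sex": sexes, "diet": diets, "group": groups},
        index=pd.Index(sample_ids, name="sample"),
    )
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids),
        samples=samples,
    )

    genes = pd.DataFrame(
        {
            "length_bp": lengths,
            "sex_dimorphic": sex_flag,
            "diet_responsive_m": dm_flag,
            # converged genes move SDGF, so they are diet-responsive in females
            "diet_responsive_f": df_flag | converged,
            "converged": converged,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    with np.errstate(divide="ignore"):
        for b, a in CONTRASTS:
            genes[contrast_name(b, a)] = np.log2(mean[b].to_numpy() / mean[a].to_numpy())
    # clean float fuzz: genes built with no effect get exactly 0
    for col in _LFC_COLS:
        genes.loc[genes[col].abs() < 1e-12, col] = 0.0
    genes["diet_responsive_f"] = genes[contrast_name("SDGF", "SDF")].abs() > 1e-12
    genes["diet_responsive_m"] = genes[contrast_name("SDGM", "SDM")].abs() > 1e-12

    truth = GroundTruth(
        genes=genes,
        library_sizes=pd.Series(libsizes, index=samples.index, name="library_size"),
        group_means=mean,
    )
    return cm, truth


def annotation_from_truth(truth: GroundTruth) -> pd.Series:
    """Gene length annotation Series (for FPKM) extracted from the ground truth."""
    return truth.genes["length_bp"].astype(float)


def planted_gene_sets(
    truth: GroundTruth,
    n_decoys: int = 10,
    set_size: int = 30,
    seed: int = 0,
) -> GeneSetCollection:
    """Gene-set collection with one set planted on converged female-high genes.

    The 'PLANTED_FEMALE_DIET' set holds genes whose female excess under the
    standard diet is removed by the grape diet (converged, positive
    female-over-male effect) — the genes a female-shift negation call should
    pick up. Decoy sets are sampled from genes with no sex effect.
    """
    g = truth.genes
    planted = [
        gid
        for gid in g.index
        if g.loc[gid, "converged"] and g.loc[gid, contrast_name("SDF", "SDM")] > 0
    ][:set_size]
    if len(planted) < 3:
        raise ValueError(
            f"only {len(planted)} converged female-high genes; "
            "increase frac_sex_dimorphic or rho_convergence"
        )
    rng = np.random.default_rng(seed)
    background = np.array([gid for gid in g.index if not g.loc[gid, "sex_dimorphic"]])
    sets = {
        "PLANTED_FEMALE_DIET": GeneSet(
            "PLANTED_FEMALE_DIET", "converged female-dimorphic genes", tuple(planted)
        )
    }
    for i in range(n_decoys):
        members = rng.choice(background, size=min(set_size, len(background)), replace=False)
        sid = f"DECOY_{i}"
        sets[sid] = GeneSet(sid, "background genes", tuple(members))
    return GeneSetCollection(sets)


def write_simulation(
    cm: CountMatrix, truth: GroundTruth, outdir: str | Path
) -> dict[str, Path]:
    """Write counts, sample sheet, annotation, and truth tables to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "samples": outdir / "samples.tsv",
        "annotation": outdir / "annotation.tsv",
        "truth_genes": outdir / "truth_genes.tsv",
        "truth_libsizes": outdir / "truth_library_sizes.tsv",
    }
    write_counts(cm, paths["counts"], paths["samples"])
    write_annotation(annotation_from_truth(truth), paths["annotation"])
    truth.genes.to_csv(paths["truth_genes"], sep="\t", float_format="%.10g")
    truth.library_sizes.rename_axis("sample").to_csv(
        paths["truth_libsizes"], sep="\t", float_format="%.10g"
    )
    return paths
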