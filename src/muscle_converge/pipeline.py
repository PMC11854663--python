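"""End-to-end orchestration: counts (real or simulated) through the report.

The run order mirrors the analysis sequence: size factors -> FPKM ->
expressed sets -> four-group Venn; per-contrast NB Wald DE -> volcano
counts; zFPKM -> group-mean z -> k-means cluster quantization -> net
differences for the four comparisons (SDF:SDM, SDGF:SDGM, SDGM:SDM,
SDGF:SDF) plus the column dendrogram adjacency; log2 PCA -> centroid
convergence; hypergeometric ORA on the four contrasts -> the cross-contrast
convergence classification. All intermediates are written as TSV and every
report number is recomputable from them. The run is deterministic given the
config (one seed drives simulation and clustering).

The sex-contrast DEG panel is the union of DEGs from SDF-vs-SDM and
SDGF-vs-SDGM; the diet-contrast panel the union from SDGM-vs-SDM and
SDGF-vs-SDF. Net differences between the standard-diet sexes and the
grape-diet sexes are read from the sex panel's quantized 40-cluster profile,
and the within-sex diet differences from the diet panel's, so the four
numbers line up with the two DEG heatmaps they summarize. The report always
prints both net-difference modes and the sum identity
D(SDM,SDGM) + D(SDF,SDGF) alongside D(SDF,SDM).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster as clustermod
from . import converge as convergemod
from . import datagen, diffexpr, enrich, io, normalize
from .errors import ConfigError, PipelineError

logger = logging.getLogger(__name__)

#: The four contrasts the analysis reports, as (B, A): log2fc is B over A.
PIPELINE_CONTRASTS = {
    "sex_sd": ("SDF", "SDM"),
    "sex_sdg": ("SDGF", "SDGM"),
    "diet_m": ("SDGM", "SDM"),
    "diet_f": ("SDGF", "SDF"),
}

#: Muscle-relevant 25-gene panel for use with real four-group data.
MUSCLE_PANEL = (
    "Ahsg", "Alb", "Apoa1", "Apoa4", "Apobec3", "Apoc3", "Arg1", "Camp",
    "Casq1", "Cbs", "Clstn3", "Cxcr6", "Fga", "Fgb", "Irf4", "Kif11",
    "Kng2", "Lcn2", "Lipg", "Ltf", "Ngp", "Nnat", "Serpina1d", "Slc4a1",
    "Slpi",
)


@dataclass
class PipelineConfig:
    """Paths or a simulation block, thresholds, and cluster settings."""

    counts: str | None = None
    samples: str | None = None
    annotation: str | None = None
    gmt: str | None = None
    simulation: datagen.SimulationConfig | None = None
    q_thresh: float = 0.05
    lfc_thresh: float = 1.0
    fpkm_thresh: float = 1.0
    alpha_enrich: float = 0.05
    k_global: int = 10
    k_deg: int = 40
    linkage: str = "complete"
    metric: str = "euclidean"
    cluster_seed: int = 0
    convergence_mode: str = "per_cluster_L1"
    panel: tuple[str, ...] | None = None
    outdir: str = "results"

    def validate(self) -> None:
        has_paths = self.counts is not None and self.samples is not None
        if not has_paths and self.simulation is None:
            raise ConfigError("config needs either data paths or a simulation block")
        if has_paths and self.annotation is None:
            raise ConfigError("data paths require an annotation table for FPKM")
        for name in ("q_thresh", "lfc_thresh", "fpkm_thresh", "alpha_enrich"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.k_global < 1 or self.k_deg < 1:
            raise ConfigError("cluster counts must be >= 1")
        if self.convergence_mode not in convergemod.NET_DIFFERENCE_MODES:
            raise ConfigError(f"unknown convergence mode {self.convergence_mode!r}")
        if self.simulation is not None:
            self.simulation.validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulation = datagen.SimulationConfig(**sim)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.panel is not None:
            d["panel"] = list(self.panel)
        return d

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("outdir")  # where results land does not change what they are
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Every headline number of one pipeline run, traceable to intermediates."""

    config_hash: str
    seed: int | None
    volcano: dict[str, tuple[int, int, int]] = field(default_factory=dict)
    venn: dict[str, int] = field(default_factory=dict)
    net_changes: dict[str, dict[str, float]] = field(default_factory=dict)
    net_differences: dict[str, dict[str, float]] = field(default_factory=dict)
    net_difference_sum_identity: dict[str, float] = field(default_factory=dict)
    column_first_merge: tuple[str, str] | None = None
    pca_variance_pc1_pc2: float | None = None
    pca_distances: dict[str, float] = field(default_factory=dict)
    pca_converged: bool | None = None
    enrichment_categories: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "volcano": {k: list(v) for k, v in self.volcano.items()},
            "venn": self.venn,
            "net_changes": self.net_changes,
            "net_differences": self.net_differences,
            "net_difference_sum_identity": self.net_difference_sum_identity,
            "column_first_merge": list(self.column_first_merge)
            if self.column_first_merge
            else None,
            "pca_variance_pc1_pc2": self.pca_variance_pc1_pc2,
            "pca_distances": self.pca_distances,
            "pca_converged": self.pca_converged,
            "enrichment_categories": self.enrichment_categories,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def _stage(name: str):
    """Decorate-free stage wrapper: re-raise with the stage name."""

    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done", name)
            return False

    return _Ctx()


def run_all(config: PipelineConfig, write: bool = True) -> RunReport:
    """Execute the full analysis; returns the report (and writes intermediates)."""
    config.validate()
    outdir = Path(config.outdir)
    if write:
        outdir.mkdir(parents=True, exist_ok=True)

    truth = None
    with _stage("input"):
        if config.simulation is not None:
            cm, truth = datagen.simulate_counts(config.simulation)
            annot = datagen.annotation_from_truth(truth)
            if write:
                datagen.write_simulation(cm, truth, outdir / "simulated")
        else:
            cm = io.read_counts(config.counts, config.samples)
            annot = io.read_annotation(config.annotation)

    with _stage("normalize"):
        sf = normalize.size_factors(cm)
        fpkm_mat = normalize.fpkm(cm, annot)
        log2_mat = normalize.log2p1(cm, size_factors=sf)
        z_mat = normalize.zfpkm(fpkm_mat)
        if write:
            io.write_table(sf.to_frame(), outdir / "size_factors.tsv")
            io.write_table(fpkm_mat.values, outdir / "fpkm.tsv")
            io.write_table(z_mat.values, outdir / "zfpkm.tsv")

    report = RunReport(
        config_hash=config.config_hash(),
        seed=config.simulation.seed if config.simulation else None,
    )

    with _stage("venn"):
        expressed = diffexpr.expressed_sets(fpkm_mat, cm.samples, config.fpkm_thresh)
        report.venn = diffexpr.venn_counts(expressed)
        if write:
            venn_df = pd.DataFrame(
                sorted(report.venn.items()), columns=["region", "count"]
            )
            io.write_table(venn_df, outdir / "venn.tsv")

    de_results: dict[str, pd.DataFrame] = {}
    with _stage("diffexpr"):
        for name, (b, a) in PIPELINE_CONTRASTS.items():
            de = diffexpr.nb_wald(cm, a, b, sf, fpkm=fpkm_mat)
            de = diffexpr.classify_degs(
                de, config.q_thresh, config.lfc_thresh, config.fpkm_thresh
            )
            de_results[name] = de
            report.volcano[io.contrast_name(b, a)] = diffexpr.volcano_summary(de)
            if write:
                io.write_table(de, outdir / f"de_{io.contrast_name(b, a)}.tsv")

    with _stage("cluster"):
        gm = clustermod.group_mean_z(z_mat, cm.samples)
        grid = convergemod.make_grid()

        k_global = min(config.k_global, len(gm))
        global_assign = clustermod.kmeans(gm, k_global, seed=config.cluster_seed)
        if write:
            io.write_table(global_assign.labels.to_frame(), outdir / "clusters_global.tsv")

        def deg_panel(names: list[str]) -> list[str]:
            genes: set[str] = set()
            for nm in names:
                sets = diffexpr.deg_sets(de_results[nm])
                genes |= sets["up"] | sets["down"]
            return [g for g in gm.index if g in genes]

        sex_genes = deg_panel(["sex_sd", "sex_sdg"])
        diet_genes = deg_panel(["diet_m", "diet_f"])

        def quantized_profile(genes: list[str], tag: str):
            if len(genes) < 2:
                logger.warning("%s DEG panel has %d genes; skipping profile", tag, len(genes))
                return None
            sub = gm.loc[genes]
            k = min(config.k_deg, len(genes))
            assign = clustermod.kmeans(sub, k, seed=config.cluster_seed)
            profile = convergemod.cluster_profile(sub, assign, grid)
            if write:
                io.write_table(assign.labels.to_frame(), outdir / f"clusters_{tag}.tsv")
                io.write_table(profile.values, outdir / f"profile_{tag}.tsv")
            return profile

        sex_profile = quantized_profile(sex_genes, "sex_degs")
        diet_profile = quantized_profile(diet_genes, "diet_degs")

        pairs = {
            "SDF_vs_SDM": (sex_profile, "SDF", "SDM"),
            "SDGF_vs_SDGM": (sex_profile, "SDGF", "SDGM"),
            "SDGM_vs_SDM": (diet_profile, "SDGM", "SDM"),
            "SDGF_vs_SDF": (diet_profile, "SDGF", "SDF"),
        }
        for mode in convergemod.NET_DIFFERENCE_MODES:
            diffs = {}
            for label, (profile, gb, ga) in pairs.items():
                diffs[label] = (
                    convergemod.net_difference(profile, ga, gb, mode=mode)
                    if profile is not None
                    else float("nan")
                )
            report.net_differences[mode] = diffs
            report.net_difference_sum_identity[mode] = (
                diffs["SDGM_vs_SDM"] + diffs["SDGF_vs_SDF"]
            )
        for tag, profile in (("sex_degs", sex_profile), ("diet_degs", diet_profile)):
            if profile is not None:
                report.net_changes[tag] = {
                    g: convergemod.net_change(profile, g) for g in io.GROUPS
                }

        # the diet-linked dendrogram claim is read off the diet-DEG panel:
        # its columns separate by diet once the sex gap has closed
        if len(diet_genes) >= 2:
            dendro = clustermod.hclust(
                gm.loc[diet_genes], axis="columns",
                metric=config.metric, linkage=config.linkage,
            )
            report.column_first_merge = clustermod.column_adjacency(dendro)
            if write:
                (outdir / "columns_dendrogram.nwk").write_text(dendro.to_newick() + "\n")

    with _stage("pca"):
        p = convergemod.pca(log2_mat)
        conv = convergemod.pca_convergence(p, cm.samples, dims=(1, 2))
        report.pca_variance_pc1_pc2 = conv.variance_covered
        report.pca_distances = {
            "SDGF_vs_SDGM": conv.d_sdgf_sdgm,
            "SDF_vs_SDM": conv.d_sdf_sdm,
            "SDGF_vs_SDF": conv.d_sdgf_sdf,
        }
        report.pca_converged = conv.converged
        if write:
            io.write_table(p.scores, outdir / "pca_scores.tsv")
            io.write_table(
                p.variance_fraction.to_frame(), outdir / "pca_variance.tsv"
            )

    if config.gmt is not None:
        with _stage("enrich"):
            gmt = io.read_gmt(config.gmt)
            universe = set().union(*expressed.values())
            contrast_enr: dict[str, dict[str, pd.DataFrame]] = {}
            for name, de in de_results.items():
                sets = diffexpr.deg_sets(de)
                contrast_enr[name] = {}
                for direction in ("up", "down"):
                    query = sets[direction] & universe
                    if query:
                        result = enrich.ora(query, gmt, universe)
                    else:
                        result = pd.DataFrame(columns=enrich.ENRICHMENT_COLUMNS)
                    contrast_enr[name][direction] = result
                    if write:
                        io.write_table(
                            result, outdir / f"ora_{name}_{direction}.tsv"
                        )
            classification = enrich.classify_convergence(
                contrast_enr["sex_sd"], contrast_enr["sex_sdg"],
                contrast_enr["diet_f"], contrast_enr["diet_m"],
                alpha=config.alpha_enrich,
            )
            report.enrichment_categories = {
                c: int((classification["category"] == c).sum())
                for c in enrich.CATEGORIES
            }
            if write:
                io.write_table(classification, outdir / "enrichment_classification.tsv")

    if config.panel:
        with _stage("gene_panel"):
            panel_tab = gene_panel_table(fpkm_mat, cm.samples, list(config.panel))
            if write:
                io.write_table(panel_tab, outdir / "gene_panel.tsv")

    if write:
        (outdir / "report.json").write_text(report.to_json() + "\n")
    return report


def gene_panel_table(
    fpkm: normalize.ExpressionMatrix,
    samples: pd.DataFrame,
    panel: list[str],
    flat_lfc: float = 0.25,
) -> pd.DataFrame:
    """Per-group mean FPKM for a gene panel, with diet-direction calls.

    Calls up/down/flat for SDGF-vs-SDF and SDGM-vs-SDM (flat when the
    |log2 ratio| of group means is below ``flat_lfc``) and flags genes whose
    standard-diet female mean exceeds the male mean.
    """
    missing = [g for g in panel if g not in fpkm.values.index]
    if missing:
        raise ValueError(f"panel genes missing from the matrix: {missing}")
    means = {}
    for group in io.GROUPS:
        cols = [s for s in samples.index[samples["group"] == group] if s in fpkm.values.columns]
        if not cols:
            raise ValueError(f"group {group!r} has no samples")
        means[group] = fpkm.values.loc[panel, cols].mean(axis=1)
    tab = pd.DataFrame(means)

    def call(numer: pd.Series, denom: pd.Series) -> pd.Series:
        eps = 1e-9
        lfc = np.log2((numer + eps) / (denom + eps))
        out = pd.Series("flat", index=numer.index)
        out[lfc >= flat_lfc] = "up"
        out[lfc <= -flat_lfc] = "down"
        return out

    tab["call_SDGF_vs_SDF"] = call(tab["SDGF"], tab["SDF"])
    tab["call_SDGM_vs_SDM"] = call(tab["SDGM"], tab["SDM"])
    tab["female_higher_SD"] = tab["SDF"] > tab["SDM"]
    tab.index.name = "gene_id"
    return tab
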