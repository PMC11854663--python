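# muscle-converge

Tools for asking a specific question of a four-group bulk RNA-seq design:
when male (M) and female (F) animals are raised on a standard diet (SD) or an
intervention diet (SDG — here, grape-supplemented), does the intervention
move the female muscle transcriptome toward the male one? The four groups are
**SDM, SDGM, SDF, SDGF**, and "convergence" means the SDF–SDM difference
shrinks when measured between SDGF and SDGM.

The package takes a gene × sample count matrix (real data or its own
negative-binomial simulator with planted ground truth) and computes:

- **Normalization** — median-of-ratios size factors
  (s<sub>j</sub> = median<sub>g</sub> K<sub>gj</sub>/(∏<sub>j</sub>K<sub>gj</sub>)<sup>1/m</sup>,
  over genes positive in all samples), FPKM
  (K<sub>gj</sub>·10⁹ / (ℓ<sub>g</sub>·N<sub>j</sub>)), and the zFPKM
  standardization: per sample, z = (log₂FPKM − μ)/σ with μ the mode of a
  Gaussian kernel density estimate and σ a half-Gaussian fit to the values
  above the mode.
- **Differential expression** — a two-group negative-binomial Wald test
  (Var(y) = μ + αμ², method-of-moments dispersion shrunk toward the trend
  α(μ) = a₀ + a₁/μ) with Benjamini–Hochberg FDR. DEGs satisfy q < 0.05,
  |log₂FC| ≥ 1, group-mean FPKM > 1.
- **The convergence statistic** — genes are k-means clustered (k = 40 for DEG
  panels), each cluster × group mean z-score is quantized onto the 11-level
  palette grid −1.5, −1.2, …, +1.5 (step 0.3), and the **net difference in
  units** between two group columns is Σ<sub>c</sub> |q(c,A) − q(c,B)|
  (default), with the column-sum reading |Σq(c,A) − Σq(c,B)| always reported
  alongside. Convergence shows up as D(SDGF,SDGM) ≪ D(SDF,SDM).
- **Geometry** — PCA of the log₂ expression matrix with group centroids in
  PC1–PC2 and the flag d(SDGF,SDGM) < d(SDF,SDM); hierarchical clustering of
  the four group columns, reading off which pair merges first.
- **Enrichment set-algebra** — hypergeometric over-representation of up/down
  DEG lists against GMT gene sets, then a cross-contrast classification of
  each sex-linked set as *persistent*, *negated* (attributed to the female
  shift, the male shift, both, or unattributed), or *emergent*.

## Worked example

Simulate the full design at 2000 genes, 5 replicates per group, with every
sex-dimorphic gene converged (`rho_convergence=1`), and run the pipeline:

```python
from muscle_converge import SimulationConfig, run_all
from muscle_converge.pipeline import PipelineConfig

cfg = PipelineConfig(
    simulation=SimulationConfig(n_genes=2000, n_reps=5,
                                rho_convergence=1.0, seed=1),
    outdir="results/example",
)
report = run_all(cfg)
print(report.net_differences["per_cluster_L1"])
print(report.column_first_merge, report.pca_converged)
```

Output:

```
{'SDF_vs_SDM': 25.8, 'SDGF_vs_SDGM': 7.5, 'SDGM_vs_SDM': 11.1, 'SDGF_vs_SDF': 24.3}
('SDGM', 'SDGF') True
```

Read: on the standard diet the sexes sit 25.8 quantized units apart, but on
the grape diet only 7.5 — the planted convergence recovered. Each sex moved
(11.1 units for males, 24.3 for females, the female shift larger because the
females are doing the converging), the first-merging dendrogram columns are
the two grape-diet groups, and the PCA flag confirms the SDGF centroid sits
nearer SDGM than SDF sits to SDM. The same run reports per-contrast volcano
counts (e.g. `SDF_vs_SDM: (2000, 68, 48)` — genes tested, up, down), the
15-region four-group Venn of expressed genes, both net-difference modes, and
(when a GMT file is configured) the enrichment classification counts. All
intermediates are written as TSV next to `report.json`.

The same analysis runs from the shell:

```
muscle-converge write-config --out cfg.yaml
muscle-converge run --config cfg.yaml
muscle-converge de --counts counts.tsv --samples samples.tsv \
    --annot annot.tsv --contrast SDGM:SDM --out de.tsv
```

With real data, point `counts`/`samples`/`annotation` (and optionally `gmt`)
at your files instead of the simulation block; `muscle_converge.MUSCLE_PANEL`
holds a 25-gene muscle-function panel for the per-group FPKM table.

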