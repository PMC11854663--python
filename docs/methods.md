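# Methods

## The question and the design

Four groups cross sex with diet: SDM and SDF are males and females on a
standard diet, SDGM and SDGF the same sexes on the grape-supplemented diet.
Many muscle transcripts are sex-dimorphic at baseline; the analysis asks
whether the intervention shrinks that dimorphism — whether SDGF moves toward
the male expression program. The package measures this three independent
ways: a quantized cluster statistic ("net difference units"), the column
dendrogram of the group-mean z-score matrix, and group-centroid distances in
PCA space, backed by an enrichment-level classification of which sex-linked
pathways persist or are negated under the intervention.

## Synthetic data generator

Counts are negative binomial, K ~ NB(mean = s·μ, Var = m + αm²), with

- per-gene baselines μ ~ LogNormal(4.0, 1.2) (median ≈ 55 counts — a
  realistic bulk library once scaled);
- a DESeq-style dispersion trend α(μ) = a₀ + a₁/μ, defaults a₀ = 0.05,
  a₁ = 5: strong overdispersion for weak genes, ~22% biological CV for
  strong ones;
- per-sample library-size factors s ~ LogNormal(0, 0.2), geometric mean ≈ 1;
- transcript lengths uniform on [200, 10000] bp (they matter only through
  FPKM).

Effects are planted as log₂ fold changes drawn before any counts on a single
seeded RNG stream, so ground truth is reproducible independently of count
noise:

- **Sex**: a fraction `frac_sex_dimorphic` (default 0.10) of genes gets
  SDF = SDM·2^β with β ~ N(0, 2²). The large effect SD reflects that
  baseline sex dimorphism in muscle is driven by strongly dimorphic
  transcripts; it also makes the planted signal detectable at n = 5.
- **Diet**: three pools. A *shared* pool (default 0.10 of genes) shifts both
  sexes by the same log₂ effect ~ N(0, 1); sex-specific pools (default 0.03
  each) shift one sex only. The shared pool is essential structure, not a
  convenience: a diet that moves both sexes together is what makes the two
  grape-diet groups the most similar column pair, which is exactly the
  dendrogram signature the statistic is meant to detect. Without it, a
  converged SDGF column is indistinguishable from SDM and the diet-linked
  dendrogram cannot arise.
- **Convergence**: a fraction ρ = `rho_convergence` of the sex-dimorphic
  genes has its SDGF expectation reset to the male level under the grape
  diet — baseline × 2^(shared diet effect), which reduces to the plain SDM
  baseline for genes with no shared diet response. A `convergence_target`
  of `"midpoint"` instead moves SDGF halfway (in log space) between the sex
  levels, since which sex does the moving is not observable from a
  difference statistic alone.

Ground truth stores per-gene flags and the true log₂ effect for each of the
six group contrasts, derived from the final group means so flags and effects
are consistent by construction (a converged gene is, by definition,
diet-responsive in females).

What the generator does **not** emulate: batch effects, GC/length bias,
correlated gene modules (genes are independent given their flags), library
preparation artifacts, and realistic within-group biological covariance.
Passing the recovery tests therefore shows the statistics detect the planted
structure at this noise level, not that real tissue data are this clean.

## Normalization

- **Size factors**: classical median-of-ratios restricted to genes positive
  in every sample, rescaled to geometric mean 1 (scale-identifiable, so a
  doubled sample gets exactly a doubled factor up to renormalization).
- **FPKM**: K·10⁹/(ℓ·N) with N the raw column sum.
- **zFPKM**: per sample, x = log₂FPKM over genes with FPKM > 0; μ is the
  argmax of a Gaussian KDE of x (bandwidth 0.9·min(sd, IQR/1.34)·n^(−1/5),
  evaluated on 512 grid points spanning [min − 3h, max + 3h]); σ is the RMS
  of x − μ over x > μ, i.e. a half-Gaussian fitted to the actively-expressed
  right flank; z = (x − μ)/σ. Genes at FPKM = 0 get the sample's minimum
  finite z minus 1 — an "unexpressed" sentinel that keeps them below every
  measured gene without producing −∞. At least 50 positive genes per sample
  are required for the density fit to be meaningful. The transform is
  invariant to rescaling a sample's FPKM by a constant (a pure shift in log
  space moves mode and values together).

## Differential expression

For groups A and B with size-factor-normalized counts y: group means μ̂_A,
μ̂_B; pooled within-group method-of-moments dispersion
α̂ = (s² − μ̄)/μ̄², floored at 10⁻⁸ and averaged half-and-half with a
dispersion-mean trend α(μ) = a₀ + a₁/μ fitted across genes by least squares
(the raw, unclipped α̂ enters the fit so the trend stays unbiased under the
null). log₂FC = log₂((μ̂_B + ½)/(μ̂_A + ½)); the ½ pseudocount bounds fold
changes for weak genes. The standard error comes from the delta method under
Var(y) = μ/s + αμ², and p is the two-sided normal tail of log₂FC/SE. Genes
with zero counts in both groups are excluded (no p, no q). BH adjustment is
the exact step-up: q₍ᵢ₎ = min over j ≥ i of p₍ⱼ₎·m/j, capped at 1.

This is a deliberately self-contained Wald engine: method-of-moments plus
trend shrinkage instead of a likelihood fit, no independent filtering, no
outlier handling, no fold-change shrinkage. Null simulations at n = 5 per
group show the p < 0.05 fraction within two points of nominal and a KS
distance to uniform under 0.05, which is the calibration that matters for
the downstream set statistics. Concordance with any specific DE package is
out of scope.

DEG thresholds: q < 0.05, |log₂FC| ≥ 1 (inclusive — the Methods-style
reading wins over a strict inequality, configurable), and group-mean
FPKM > 1 applied to the **larger** of the two group means, since which
group's expression the filter should inspect is not determined; the larger
mean is the permissive, symmetric choice. "Expressed" for Venn membership is
group-mean FPKM strictly > 1.

## Clustering

Hierarchical clustering is a plain agglomeration (Euclidean; complete
linkage by default, single/average available) with a deterministic tie-break
(earliest-created pair merges first on equal heights). It is quadratic per
merge and used on small item sets: the four group columns, samples, DEG
panels for cutree. Gene-scale clustering uses k-means (scikit-learn,
k-means++ seeding, best of 10 starts, seeded): k = 10 for the global
heatmap, k = 40 for DEG panels, with k capped at the panel size. Cutting a
dendrogram at k clusters takes the first n − k merges; cluster ids are
renumbered 1..k by first appearance in leaf order.

## The convergence statistic

The group-mean z-score matrix (gene × 4 groups) restricted to a DEG panel is
k-means clustered; each cluster × group cell is the quantized mean z of its
member genes, snapped to the nearest level of the palette grid −1.5 … +1.5
step 0.3 (11 levels). Values beyond the ends clamp; exact midpoints round
toward zero (a fixed conservative rule — the level nearer zero claims the
tie). The quantization emulates reading cluster colors off a heatmap's
11-color scale, which is why the statistic is reported in "units" that are
multiples of 0.3.

Two readings of the between-column comparison are both computed on every
run, because "net change per column, then comparisons between columns" is
ambiguous:

- `per_cluster_L1` (default): Σ_c |q(c,A) − q(c,B)|. Sensitive to
  compensating shifts in opposite directions, which is the property a
  difference-of-profiles statistic should have; it is a true metric on
  profiles.
- `column_sum`: |Σ_c q(c,A) − Σ_c q(c,B)| — the difference of the column
  "net changes". Blind to compensating shifts (a column that goes +0.9 in
  one cluster and −0.9 in another nets to zero).

The pipeline computes the sex comparisons D(SDF,SDM) and D(SDGF,SDGM) on the
panel of DEGs from the two sex contrasts (union of SDF-vs-SDM and
SDGF-vs-SDGM calls), and the diet comparisons D(SDGM,SDM) and D(SDGF,SDF) on
the panel from the two diet contrasts, so each number summarizes the heatmap
it belongs to. The sum D(SDGM,SDM) + D(SDGF,SDF) is always printed next to
D(SDF,SDM) for the real-data comparison. The union (rather than
intersection) of the two contrasts' DEG lists is used for each panel: under
convergence the grape-diet contrast loses exactly the genes of interest, so
an intersection would empty the panel of the signal it is meant to display.

The column dendrogram readout (which pair of group columns merges first) is
taken on the diet-panel matrix — that is the panel where a diet-linked
pairing is the discriminating outcome; the sex panel groups by sex
essentially by construction.

## PCA

Samples over genes, gene-centered, no variance scaling, via SVD. Sign
convention: each loading vector's largest-magnitude entry is positive (makes
outputs reproducible across SVD implementations). Group centroids are
computed in PC1–PC2 by default; the convergence flag is
d(SDGF,SDGM) < d(SDF,SDM). PC3 can be included via `dims`.

## Enrichment

Hypergeometric upper-tail ORA of each up/down DEG list against GMT sets,
universe = genes expressed (group-mean FPKM > 1) in **any** group (the
natural "could have been called" background when no universe is given),
sets intersected with the universe and dropped below 3 members, BH within
each (contrast, direction) result. The cross-contrast classification walks
each set significant between the sexes on the standard diet: *persistent*
if still significant, same direction, between the grape-diet sexes;
otherwise *negated*, attributed to the female shift if the set is enriched
among the female diet-contrast genes moving in the gap-closing direction
(down in SDGF vs SDF for a female-enriched set, up for a male-enriched
one), to the male shift symmetrically, to both, or left unattributed.
Sets significant only between the grape-diet sexes are *emergent*.

## Problem sizes and determinism

The validation suite and the acceptance script run the full pipeline at
2000 genes × 20 samples (5 per group), 5 seeds per condition and a
convergence-fraction grid ρ ∈ {0, 0.25, 0.5, 0.75, 1} — small enough to
iterate on a laptop, large enough that the DEG panels hold a few hundred
genes and the cluster profiles are stable. A full pipeline run at this size
takes about one second. Every run is deterministic given its configuration:
one seed drives the generator, a separate seed the k-means restarts, and a
repeated run reproduces every output file byte for byte.

## Known limitations

- The NB Wald test is approximate at very small replication; its normal
  tail is slightly anticonservative for genes with extreme dispersion.
  Calibration is verified empirically at the study's n = 5.
- The quantized statistic has no sampling theory attached here; the package
  establishes its behavior by simulation (monotone in the planted
  convergence fraction; orders the group pairs correctly at high ρ).
- Gene-level independence in the generator understates the variance of
  set-level statistics on real data; enrichment recovery rates on synthetic
  data are optimistic in that respect.
- Which aggregation the original "units" figures used (per-cluster L1 vs
  column sums, whole clusters vs sub-blocks) cannot be determined from a
  printed heatmap; both modes are first-class outputs and reports always
  carry both.
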