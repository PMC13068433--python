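# Methods

## The procedure

`trapdiff` implements a threshold-based differential-expression procedure for
TRAP-seq designed around very small group sizes (three biological replicates
per group). Instead of a null-hypothesis test, a gene is called differentially
expressed when three complementary statistics jointly exceed fixed effect-size
thresholds. The pipeline stages run in a fixed order:

coding filter → per-sample TPM re-normalization → percentile-rank consistency
filters → quantile normalization → statistics → joint call.

### Percentile ranks

Within each sample, gene g among N genes receives

    rank(g) = (#{values < v_g} + ½·#{other values = v_g}) / (N − 1)

so ranks span [0, 1], ties share a rank and a fully tied column maps to 0.5.
This is the average-rank convention (`scipy.stats.rankdata(method="average")`
shifted and scaled); the test suite pins it against a direct counting oracle.
Zero-TPM genes participate in ranking (tied at the bottom) — absent detection
must be encoded as 0, never missing, so each column has a total order.

### Consistency filters

Two nested analysis universes:

* **transcriptome-expressed** — rank **strictly above** 0.30 in *every* INPUT
  sample;
* **translatome-expressed** — rank **on or above** 0.10 in *every* IP sample,
  with ranks recomputed on the transcriptome-expressed universe (the reduced
  N changes the ranks; slicing ranks computed on all genes would be wrong,
  and the API rejects it).

The strict/non-strict asymmetry between the two thresholds is deliberate.
Both filters are antitone in their threshold and invariant to any strictly
increasing per-sample transform. The expressed sets are computed per
(cell type, timepoint) block across both conditions' samples; requiring
consistency in *every* sample means a gene strongly down-regulated in one
condition can drop out of the universe entirely (see Limitations).

### Quantile normalization

All sample columns are forced onto the per-rank mean of the sorted columns.
Tied input values receive the mean of the reference values over the tied rank
span, which preserves column sums and makes the transform idempotent. This
exact tie convention is implemented directly (no installed library exposes
it) and cross-checked against a brute-force oracle.

### Per-gene statistics

With group a = SNI and group b = sham (positive always means up in SNI):

* **log₂ fold change** = log₂((median_a + pc)/(median_b + pc)) on
  re-normalized TPM. Default pseudocount pc = 0.01 TPM keeps zero-median
  genes finite; a gene with both medians zero and pc = 0 is flagged
  not-evaluable (NaN) and never called.
* **SSMD** = (μ_a − μ_b)/√(σ_a² + σ_b²) with unbiased (n − 1) variances,
  computed on percentile ranks of the quantile-normalized TPM — the effect
  size lives on the rank scale, making it invariant to location/scale changes
  of the raw data. When both variances are zero the value is 0 for equal
  means and capped at ±10⁶ otherwise so sorting stays defined. A switch
  (`ssmd_input="raw_ranks"`) ranks the un-normalized TPM instead; with few
  ties the two agree because quantile normalization preserves within-column
  order.
* **Sign-modified Bhattacharyya coefficient.** Each group's TPM values are
  summarized by a Gaussian fit (sample mean, unbiased variance). The
  Bhattacharyya distance between two Gaussians,

      D = ¼·(μ_a − μ_b)²/(σ_a² + σ_b²) + ½·ln((σ_a² + σ_b²)/(2σ_aσ_b)),

  gives the overlap coefficient BC = e^(−D) = ∫√(p_a p_b); the reported
  statistic is sign(log₂FC)·(1 − BC): 0 for identical distributions, ±1 in
  the non-overlap limit. The Gaussian fit is the smallest distributional
  assumption workable at n = 3, where empirical density estimation is
  hopeless; the closed form is verified against numerical quadrature to
  1e-6. A variance floor of 1e-8·(grand mean)² guards zero-variance groups.

* **Joint call**: DE ⇔ |SSMD| ≥ 0.97 ∧ |BC| ≥ 0.5 ∧ 2^|log₂FC| ≥ 1.33, all
  boundaries inclusive; direction from the sign of log₂FC. The rule is
  monotone in each statistic. No p-values or multiple-testing correction are
  computed — the procedure is effect-size based by design, and bolting an FDR
  onto it would misrepresent it.

### Marker enrichment

Cell-type specificity of the IP is summarized per marker gene as
log₂((median IP TPM + pc)/(median INPUT TPM + pc)); positive values mean
IP-enriched. Markers absent from the matrix are reported with a flag, not
dropped.

### Regulatory-mode classification

Given per-gene mRNA and ribosome-footprint (rFP) log₂ fold changes with
upstream significance flags, genes partition into five categories:
rFP-only significant → translation_only; mRNA-only → transcription_only;
both, same sign → homodirectional; both, strictly opposite signs →
opposite_change; neither → stable. An exact-zero significant fold change
cannot carry a direction: such genes fall into the non-strict
(homodirectional) branch and are flagged as anomalies. The significance flags
are inputs — this package does not recompute the upstream Ribo-seq statistics.
The summary ratio is #(rFP-significant)/#(mRNA-significant); values above 1
indicate translation-dominated regulation. This rule set is the simplest one
consistent with the five-way partition; a buffering-aware definition (e.g.
requiring a translational-efficiency test for "translation only") would need
the upstream tool's internals and is out of scope.

## Synthetic-data generator

`generate_trap_dataset` emulates one (cell type, timepoint) block of a TRAP
design: 3 replicates × {IP, INPUT} × {sham, SNI} = 12 samples; 18,000 coding
genes plus 2,000 decoys (half non-coding biotype, half mitochondrial) that
the coding filter must remove. Defaults, chosen once as field-realistic:

| parameter | default | meaning |
|---|---|---|
| `baseline_log_mean`, `baseline_log_sd` | 1.0, 2.0 | natural-log parameters of the log-normal TPM baseline (heavy tail: top 1% of genes ≈ a third of library mass, as in real bulk data) |
| `noise_sd` | 0.1 | replicate-level multiplicative noise, log2 units |
| `de_fraction`, `de_log2fc` | 0.05, 2.0 | share of coding genes with a planted effect and its \|log₂FC\| |
| `de_mode_probs` | 0.6/0.2/0.2 | translational (IP only) / transcriptional (both fractions) / both (both fractions, doubled IP effect) |
| `de_min/max_abundance_quantile` | 0.60/0.95 | planting stratum (see below) |
| `marker_genes` | ±3/−2 log2 | IP enrichment of neuronal markers, depletion of non-neuronal decoys |
| `dropout_rate` | 0.05 | per-entry zeroing probability, restricted to the bottom 30% of baseline abundance |

Planted effects are applied as a **centered contrast**: sham columns get
−fc/2 and SNI columns +fc/2 in log2, so the between-condition log₂FC equals
the planted value exactly while each condition is displaced only half as far
from baseline. Effects are planted in the 60th–95th abundance percentile
stratum: below it, planted genes fall under the detection filters and
recovery would measure dropout rather than the caller; above it, the planted
genes carry so much library mass that a net up/down imbalance shifts every
other gene compositionally after TPM re-normalization. One seed drives all
randomness through fixed per-component `SeedSequence` child streams, so e.g.
changing the noise level does not re-draw the baselines; identical configs
give bit-identical matrices.

`generate_riboseq_table` plants regulatory-mode categories directly:
significant fold changes at ±1.5 (log2) plus Gaussian noise, flags set
exactly per planted category. With zero noise the classifier's confusion
matrix is the identity by construction.

**What the generator does not emulate:** count-level sampling noise
(mean–variance relationships), correlated replicates or batch effects,
library-composition shifts, low-expression DE genes (below the planting
stratum), isoform-level effects, and any dependence between IP enrichment and
condition. Passing recovery tests therefore show that the pipeline correctly
recovers effects of the planted kind at the planted scale — not that it is
robust to every pathology of real sequencing data.

## Numerical and design choices

* Mitochondrial genes are identified by chromosome name; both `chrM` and `MT`
  are accepted by default (configurable).
* Re-normalization (to 1e6 per sample) is applied after coding filtering,
  per column independently; it is idempotent and order within the pipeline is
  fixed.
* Both fractions are quantile-normalized within their own analysis universe
  (whether the translatome side needs it is genuinely open; normalizing both
  is the symmetric default and is configurable by operating on the matrices
  directly).
* Orientation is fixed globally: group a = SNI, group b = sham.
* Expressed-gene sets are computed across both conditions' samples of a
  (cell type, timepoint) block; computing them per condition instead changes
  which borderline genes enter the universe.

## Known limitations

* **Compositional sensitivity.** TPM re-normalization makes every gene's
  value depend on the totals; a strong net mass change concentrated in
  highly abundant genes shifts all other genes' apparent fold changes, and
  with small replicate noise those shifts can clear the joint thresholds.
  This is inherent to relative-abundance DE at fixed thresholds, not a
  property of the implementation.
* **Down-regulation near the detection boundary.** Because the consistency
  filters require expression in every sample, a gene strongly down-regulated
  in SNI can leave the universe entirely and become uncallable.
* **Gaussian overlap at n = 3.** The Bhattacharyya statistic trusts a
  two-parameter fit from three points; heavy-tailed replicate noise will make
  |BC| optimistic. The statistic is isolated behind one function if another
  density model is ever needed.
* SSMD at near-zero rank variance is effectively unbounded (hence the cap);
  its magnitude ordering is meaningful, its absolute scale is not.
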