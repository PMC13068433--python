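# trapdiff

Differential ribosome-occupancy analysis for TRAP-seq (translating ribosome
affinity purification) experiments, plus five-way regulatory-mode
classification of paired transcriptome/translatome fold changes.

## Who this is for

TRAP-seq reads out the translatome of a genetically defined cell type: tagged
ribosomes are immunoprecipitated (IP fraction) from a whole-tissue lysate
(INPUT fraction) and the bound mRNAs are sequenced. With only three biological
replicates per group, classical test-based DE frameworks are underpowered and
poorly calibrated, so this package implements an effect-size/overlap-threshold
procedure instead, operating on gene-level TPM matrices:

1. **Coding-gene re-normalization** — non-coding and mitochondrial genes are
   removed and TPM is re-normalized so the coding genes of each sample sum to
   one million.
2. **Consistency filters** — per-sample percentile ranks define the analysis
   universes: genes ranked strictly above the 30th percentile in *every*
   INPUT sample are "transcriptome-expressed"; among those, genes ranked on
   or above the 10th percentile in *every* IP sample (ranks recomputed on the
   reduced universe) are "translatome-expressed".
3. **Quantile normalization** across samples on the coding-gene set.
4. **Per-gene statistics** between SNI (nerve-injured) and sham groups:
   - log₂ fold change from group medians,
     log₂((med_SNI + pc)/(med_sham + pc));
   - SSMD (strictly standardized mean difference),
     (μ₁ − μ₂)/√(σ₁² + σ₂²), computed on percentile ranks of the
     quantile-normalized TPM;
   - a sign-modified Bhattacharyya coefficient, sign(log₂FC)·(1 − e^(−D))
     with D the Bhattacharyya distance between per-group Gaussian fits on
     TPM — 0 for identical distributions, ±1 for disjoint ones.
5. **Joint DE call** — a gene is differentially expressed when |SSMD| ≥ 0.97,
   |BC| ≥ 0.5 **and** fold change ≥ 1.33, all boundaries inclusive; the
   dual-flashlight table/plot (SSMD vs log₂FC) and top-15 up/down lists
   summarize each comparison.

A separate classifier assigns genes from paired mRNA/ribosome-footprint (rFP)
DE results to five regulatory modes — translation only, transcription only,
homodirectional, opposite change, stable — and computes the rFP/mRNA ratio of
significant-gene counts.

A synthetic-data generator with planted ground truth (log-normal baselines,
multiplicative replicate noise, known fold changes, IP-enriched markers,
non-coding/mitochondrial decoys, dropout) makes every stage testable without
any external download.

## Worked example

```python
import trapdiff as td

cfg = td.SyntheticConfig(n_coding=5000, n_decoys=500, seed=42)
matrix, truth = td.generate_trap_dataset(cfg)
coding = td.renormalize_tpm(td.filter_coding(matrix))
comp = td.analyze_comparison(coding, "GAD2", "D60", td.RunConfig("", "", "", ""))
print(comp.de.summary())
```

prints

```
Translatome differential expression (SSMD + Bhattacharyya)
==========================================================
Comparison:        GAD2 D60
Group a (SNI):     3 samples
Group b (sham):    3 samples
Genes tested:      2998
Thresholds:        |SSMD| >= 0.97, |BC| >= 0.5, FC >= 1.33
SSMD input:        qn_ranks
DE genes:          241 (122 up, 119 down)
```

The generator planted 250 DE genes (4-fold, 5% of coding genes); 2,998 of the
5,000 coding genes survive both consistency filters, and the joint rule calls
241 genes — all of them planted, with 0 false calls (the 9 misses fall below
the expression filters in one condition). The top of the dual-flashlight
table, `comp.de.dual_flashlight()`, shows the strongest hits:

```
  gene_id   log2fc       ssmd  bc_mod
gene00810 2.012910 119.876176     1.0
gene01898 3.965777 109.422256     1.0
gene03640 4.065998  86.717936     1.0
```

`log2fc ≈ 2` is the planted 4-fold effect; SSMD is huge because replicate
noise is small on the rank scale, and `bc_mod = 1` indicates completely
disjoint group distributions.

The same run from the shell:

```sh
trapdiff simulate trap --out sim/ --seed 42 --n-coding 5000 --n-decoys 500
trapdiff run-all --config run.yaml   # paths + thresholds; see RunConfig
trapdiff classify --table riboseq_fc.tsv --out classified.tsv
```

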