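"""Synthetic TRAP-seq datasets with planted ground truth.

The generator emulates the study design the pipeline targets: one spinal-cord
cell type and timepoint, 3 biological replicates per group, two fractions
(IP = ribosome-bound, INPUT = whole lysate), two conditions (sham, SNI),
~18,000 detected coding genes plus non-coding and mitochondrial decoy genes
that the upstream filters must remove.

Per-gene TPM-like abundance is log-normal; replicate noise is multiplicative
(Gaussian in log2 space); a planted fraction of coding genes carries a known
condition effect, applied in the IP fraction only (translational mode), in
both fractions (transcriptional mode), or in both with a doubled IP effect
(mode ``both``); cell-type markers carry an IP-enrichment effect in both
conditions; low-abundance entries suffer random dropout to zero.  Columns are
deliberately NOT normalized — the pipeline must do that itself.

One integer seed drives everything through per-component child streams
(numpy ``SeedSequence.spawn``), so the baseline draw is stable when, say,
only the noise level changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

DE_MODES = ("translational", "transcriptional", "both")

#: default marker panel: inhibitory-neuron markers enriched in a GAD2 IP,
#: non-neuronal genes depleted
DEFAULT_MARKERS: dict[str, float] = {
    "Gad2": 3.0, "Slc32a1": 3.0, "Pax2": 3.0, "Pvalb": 3.0,
    "Gfap": -2.0, "Aldh1l1": -2.0, "Tmem119": -2.0, "Cx3cr1": -2.0,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the TRAP dataset generator (defaults = study-scale)."""

    n_coding: int = 18_000
    n_decoys: int = 2_000            # split evenly: non-coding / mitochondrial
    n_replicates: int = 3
    baseline_log_mean: float = 1.0   # natural-log mean of the log-normal TPM baseline
    baseline_log_sd: float = 2.0
    noise_sd: float = 0.1            # replicate noise sd, log2 units
    de_fraction: float = 0.05
    de_log2fc: float = 2.0           # |planted effect|, applied in SNI
    # effects are planted in well-expressed genes (above the detection filters)
    # but below the extreme-abundance tail, whose genes carry so much library
    # mass that planted effects would shift every other gene compositionally
    de_min_abundance_quantile: float = 0.60
    de_max_abundance_quantile: float = 0.95
    de_mode_probs: tuple[float, float, float] = (0.6, 0.2, 0.2)  # translational, transcriptional, both
    marker_genes: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MARKERS))
    dropout_rate: float = 0.05
    dropout_abundance_quantile: float = 0.3  # only this bottom fraction can drop out
    cell_type: str = "GAD2"
    timepoint: str = "D60"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_coding < 2 or self.n_replicates < 1:
            raise ValueError("need at least 2 coding genes and 1 replicate")
        for name in ("de_fraction", "dropout_rate", "dropout_abundance_quantile",
                     "de_min_abundance_quantile", "de_max_abundance_quantile"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.noise_sd < 0 or self.baseline_log_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if abs(sum(self.de_mode_probs) - 1.0) > 1e-9:
            raise ValueError("de_mode_probs must sum to 1")


@dataclass
class SyntheticTruth:
    """Planted ground truth: which genes are DE, their true effect and mode,
    and which genes are cell-type markers."""

    genes: pd.DataFrame  # gene_id, is_de, true_log2fc, mode, is_marker, marker_log2_enrichment

    def de_genes(self) -> frozenset[str]:
        return frozenset(self.genes.loc[self.genes["is_de"], "gene_id"])

    def marker_genes(self) -> frozenset[str]:
        return frozenset(self.genes.loc[self.genes["is_marker"], "gene_id"])

    def to_tsv(self, path: str | Path) -> None:
        self.genes.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SyntheticTruth":
        t = pd.read_csv(path, sep="\t")
        t["is_de"] = t["is_de"].astype(bool)
        t["is_marker"] = t["is_marker"].astype(bool)
        t["mode"] = t["mode"].fillna("")
        return cls(t)


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_trap_dataset(config: SyntheticConfig) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Generate the raw (un-normalized) TPM matrix and its ground truth.

    Deterministic given ``config.seed``: the same config yields bit-identical
    output.
    """
    rng_base, rng_de, rng_noise, rng_drop = _child_rngs(config.seed, 4)

    markers = list(config.marker_genes)
    n_named = len(markers)
    n_anon = config.n_coding - n_named
    if n_anon < 0:
        raise ValueError("more marker genes than coding genes")
    coding_ids = markers + [f"gene{i:05d}" for i in range(n_anon)]
    n_nc = config.n_decoys // 2
    n_mt = config.n_decoys - n_nc
    decoy_ids = [f"nc{i:04d}" for i in range(n_nc)] + [f"mt{i:04d}" for i in range(n_mt)]
    gene_ids = coding_ids + decoy_ids

    annotations = pd.DataFrame({
        "gene_id": gene_ids,
        "biotype": ["protein_coding"] * config.n_coding
                   + ["non_coding"] * n_nc + ["protein_coding"] * n_mt,
        "chromosome": ["chr1"] * config.n_coding + ["chr1"] * n_nc + ["chrM"] * n_mt,
    }).set_index("gene_id")

    rows = []
    for fraction in ("INPUT", "IP"):
        for condition in ("sham", "SNI"):
            for rep in range(1, config.n_replicates + 1):
                rows.append({
                    "sample_id": f"{config.cell_type}_{config.timepoint}_{fraction}_{condition}_{rep}",
                    "fraction": fraction, "condition": condition,
                    "cell_type": config.cell_type, "timepoint": config.timepoint,
                    "replicate": rep,
                })
    samples = pd.DataFrame(rows).set_index("sample_id")

    n_genes = len(gene_ids)
    baseline = rng_base.lognormal(config.baseline_log_mean, config.baseline_log_sd,
                                  size=n_genes)

    # planted DE genes: anonymous coding genes only (markers stay clean), and
    # only in the well-expressed stratum so recovery measures the DE caller
    # rather than detection dropout at the percentile filters
    n_de = int(round(config.de_fraction * config.n_coding))
    anon_idx = np.arange(n_named, config.n_coding)
    lo = np.quantile(baseline[:config.n_coding], config.de_min_abundance_quantile)
    hi = np.quantile(baseline[:config.n_coding], config.de_max_abundance_quantile)
    eligible = anon_idx[(baseline[anon_idx] >= lo) & (baseline[anon_idx] <= hi)]
    de_idx = rng_de.choice(eligible, size=min(n_de, eligible.size), replace=False)
    true_fc = np.zeros(n_genes)
    true_fc[de_idx] = np.where(rng_de.random(de_idx.size) < 0.5, 1.0, -1.0) * config.de_log2fc
    modes = np.full(n_genes, "", dtype=object)
    modes[de_idx] = rng_de.choice(DE_MODES, size=de_idx.size, p=config.de_mode_probs)

    marker_enrich = np.zeros(n_genes)
    marker_enrich[:n_named] = [config.marker_genes[m] for m in markers]

    # condition effect in log2 per (gene, fraction)
    effect_input = np.where(np.isin(modes, ("transcriptional", "both")), true_fc, 0.0)
    effect_ip = np.where(modes == "translational", true_fc, 0.0) \
        + np.where(modes == "transcriptional", true_fc, 0.0) \
        + np.where(modes == "both", 2.0 * true_fc, 0.0)

    # centered contrast: sham at −fc/2, SNI at +fc/2 around baseline, so the
    # between-condition log2FC equals the planted fc exactly
    arr = np.empty((n_genes, len(samples)))
    for j, (sid, meta) in enumerate(samples.iterrows()):
        half = effect_ip if meta["fraction"] == "IP" else effect_input
        log2_effect = 0.5 * half if meta["condition"] == "SNI" else -0.5 * half
        if meta["fraction"] == "IP":
            log2_effect = log2_effect + marker_enrich
        noise = rng_noise.normal(0.0, config.noise_sd, size=n_genes) if config.noise_sd > 0 \
            else np.zeros(n_genes)
        arr[:, j] = baseline * np.exp2(log2_effect + noise)

    if config.dropout_rate > 0:
        cutoff = np.quantile(baseline, config.dropout_abundance_quantile)
        low = baseline <= cutoff
        drop = rng_drop.random(arr.shape) < config.dropout_rate
        arr[drop & low[:, None]] = 0.0
    frame = pd.DataFrame(arr, index=gene_ids, columns=samples.index)

    truth = SyntheticTruth(pd.DataFrame({
        "gene_id": gene_ids,
        "is_de": true_fc != 0,
        "true_log2fc": true_fc,
        "mode": modes,
        "is_marker": [g in config.marker_genes for g in gene_ids],
        "marker_log2_enrichment": marker_enrich,
    }))
    return ExpressionMatrix(frame, samples, annotations), truth


# ------------------------------------------------------- paired mRNA/rFP tables

@dataclass(frozen=True)
class RiboseqConfig:
    """Parameters of the paired mRNA/rFP fold-change table generator.

    ``category_fractions`` gives the planted share of each non-stable
    regulatory mode; the remainder is stable.
    """

    n_genes: int = 10_000
    category_fractions: dict[str, float] = field(default_factory=lambda: {
        "translation_only": 0.10, "transcription_only": 0.10,
        "homodirectional": 0.05, "opposite_change": 0.02,
    })
    effect_log2fc: float = 1.5
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        bad = set(self.category_fractions) - {"translation_only", "transcription_only",
                                              "homodirectional", "opposite_change"}
        if bad:
            raise ValueError(f"unknown categories: {sorted(bad)}")
        if any(f < 0 for f in self.category_fractions.values()):
            raise ValueError("category fractions must be non-negative")
        if sum(self.category_fractions.values()) > 1 + 1e-9:
            raise ValueError("category fractions must sum to at most 1")


def generate_riboseq_table(config: RiboseqConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Emit a per-gene mRNA/rFP log2FC table with flags and planted categories.

    Significant fold changes are drawn at ±``effect_log2fc`` plus Gaussian
    noise; non-significant ones are pure noise around zero.  Significance
    flags follow the planted category exactly (they stand in for an upstream
    DE caller's verdicts).
    """
    rng_assign, rng_fc = _child_rngs(config.seed + 1_000_003, 2)
    n = config.n_genes
    gene_ids = [f"gene{i:05d}" for i in range(n)]

    counts = {c: int(round(f * n)) for c, f in config.category_fractions.items()}
    if sum(counts.values()) > n:
        raise ValueError("category fractions must sum to at most 1")
    category = np.full(n, "stable", dtype=object)
    perm = rng_assign.permutation(n)
    pos = 0
    for cat, k in counts.items():
        category[perm[pos:pos + k]] = cat
        pos += k

    def noise(size):
        return rng_fc.normal(0.0, config.noise_sd, size=size) if config.noise_sd > 0 \
            else np.zeros(size)

    sign = np.where(rng_fc.random(n) < 0.5, 1.0, -1.0)
    mrna_fc = noise(n)
    rfp_fc = noise(n)
    mrna_sig = np.zeros(n, dtype=bool)
    rfp_sig = np.zeros(n, dtype=bool)

    e = config.effect_log2fc
    m = category == "translation_only"
    rfp_fc[m] += sign[m] * e
    rfp_sig[m] = True
    m = category == "transcription_only"
    mrna_fc[m] += sign[m] * e
    mrna_sig[m] = True
    m = category == "homodirectional"
    mrna_fc[m] += sign[m] * e
    rfp_fc[m] += sign[m] * e
    mrna_sig[m] = rfp_sig[m] = True
    m = category == "opposite_change"
    mrna_fc[m] += sign[m] * e
    rfp_fc[m] -= sign[m] * e
    mrna_sig[m] = rfp_sig[m] = True

    table = pd.DataFrame({
        "gene_id": gene_ids,
        "mrna_log2fc": mrna_fc, "rfp_log2fc": rfp_fc,
        "mrna_sig": mrna_sig, "rfp_sig": rfp_sig,
    })
    truth = SyntheticTruth(pd.DataFrame({
        "gene_id": gene_ids,
        "is_de": category != "stable",
        "true_log2fc": np.where(category != "stable", sign * e, 0.0),
        "mode": category,
        "is_marker": False,
        "marker_log2_enrichment": 0.0,
    }))
    return table, truth
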