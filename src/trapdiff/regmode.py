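"""Five-way regulatory-mode classification of paired mRNA / ribosome-footprint
differential results.

Each gene carries an mRNA (transcriptome) and an rFP (ribosome footprint,
translatome) log2 fold change plus upstream significance flags; the two flags
and the two signs define a partition into five categories:

===================  =======================================================
translation_only     rFP significant, mRNA not — purely translational control
transcription_only   mRNA significant, rFP not
homodirectional      both significant, same sign (footprints follow mRNA)
opposite_change      both significant, opposite signs (translational buffering
                     or reversal)
stable               neither significant
===================  =======================================================

The significance flags are inputs, produced upstream by a Ribo-seq DE tool;
this module does not recompute them (a helper derives flags from adjusted
p-value columns when those are what the upstream table provides).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CATEGORIES = ("translation_only", "transcription_only", "stable",
              "opposite_change", "homodirectional")

REQUIRED_COLUMNS = ("gene_id", "mrna_log2fc", "rfp_log2fc", "mrna_sig", "rfp_sig")


def classify_gene(mrna_log2fc: float, rfp_log2fc: float,
                  mrna_sig: bool, rfp_sig: bool) -> str:
    """Assign one gene its regulatory-mode category.

    A significant pair with strictly opposite signs is ``opposite_change``;
    a significant pair that is not strictly opposite (including a degenerate
    exact-zero fold change) is ``homodirectional``.
    """
    if not (np.isfinite(mrna_log2fc) and np.isfinite(rfp_log2fc)):
        raise ValueError("fold changes must be finite")
    if rfp_sig and not mrna_sig:
        return "translation_only"
    if mrna_sig and not rfp_sig:
        return "transcription_only"
    if not (mrna_sig or rfp_sig):
        return "stable"
    if mrna_log2fc * rfp_log2fc < 0:
        return "opposite_change"
    return "homodirectional"


def classify_table(table: pd.DataFrame) -> pd.DataFrame:
    """Vectorized classification; appends a ``category`` column.

    Exact-zero significant fold changes cannot carry a direction, so genes
    where both flags are set and either fold change is exactly 0 are
    additionally marked in an ``anomaly`` column (they classify as
    homodirectional, the non-strict branch).
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"table missing columns: {missing}")
    t = table.copy()
    mrna_fc = t["mrna_log2fc"].to_numpy(dtype=float)
    rfp_fc = t["rfp_log2fc"].to_numpy(dtype=float)
    if not (np.isfinite(mrna_fc).all() and np.isfinite(rfp_fc).all()):
        raise ValueError("fold changes must be finite")
    mrna = t["mrna_sig"].to_numpy(dtype=bool)
    rfp = t["rfp_sig"].to_numpy(dtype=bool)
    cat = np.full(len(t), "stable", dtype=object)
    cat[rfp & ~mrna] = "translation_only"
    cat[mrna & ~rfp] = "transcription_only"
    both = mrna & rfp
    cat[both & (mrna_fc * rfp_fc < 0)] = "opposite_change"
    cat[both & (mrna_fc * rfp_fc >= 0)] = "homodirectional"
    t["category"] = cat
    t["anomaly"] = both & ((mrna_fc == 0) | (rfp_fc == 0))
    return t


def flags_from_padj(table: pd.DataFrame, alpha: float = 0.05,
                    mrna_col: str = "mrna_padj",
                    rfp_col: str = "rfp_padj") -> pd.DataFrame:
    """Derive boolean significance flags from adjusted p-value columns."""
    t = table.copy()
    t["mrna_sig"] = t[mrna_col].to_numpy(dtype=float) < alpha
    t["rfp_sig"] = t[rfp_col].to_numpy(dtype=float) < alpha
    return t


def category_counts(records: pd.DataFrame) -> pd.Series:
    """Gene count per category, zero-count categories included."""
    if "category" not in records.columns:
        records = classify_table(records)
    counts = records["category"].value_counts()
    return counts.reindex(CATEGORIES, fill_value=0).astype(int)


def rfp_mrna_ratio(records: pd.DataFrame) -> float:
    """#(rFP-significant genes) / #(mRNA-significant genes).

    Values above 1 indicate translation-dominated regulation.  NaN when no
    gene is mRNA-significant (undefined).
    """
    n_mrna = int(records["mrna_sig"].sum())
    n_rfp = int(records["rfp_sig"].sum())
    if n_mrna == 0:
        return float("nan")
    return n_rfp / n_mrna


class RegulatoryModeClassifier:
    """Model-style wrapper: build from the upstream DE table, ``fit`` to get
    the classified results object."""

    def __init__(self, table: pd.DataFrame, alpha: float | None = None):
        if "mrna_sig" not in table.columns and alpha is not None:
            table = flags_from_padj(table, alpha)
        missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"table missing columns: {missing}")
        self.table = table

    def fit(self) -> "RegulatoryModeResults":
        return RegulatoryModeResults(classify_table(self.table))


@dataclass
class RegulatoryModeResults:
    """Classified regulatory-mode table with count and ratio summaries."""

    table: pd.DataFrame = field(repr=False)

    def counts(self) -> pd.Series:
        return category_counts(self.table)

    @property
    def ratio(self) -> float:
        return rfp_mrna_ratio(self.table)

    def summary(self) -> str:
        counts = self.counts()
        lines = ["Regulatory-mode classification", "=" * 38,
                 f"Genes:             {len(self.table)}"]
        for cat in CATEGORIES:
            lines.append(f"{cat:<19}{counts[cat]}")
        ratio = self.ratio
        lines.append(f"rFP/mRNA ratio:    "
                     f"{'undefined (no mRNA-significant genes)' if np.isnan(ratio) else f'{ratio:.3f}'}")
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")
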