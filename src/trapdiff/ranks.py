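"""Percentile ranks and two-stage expressed-gene consistency filters.

Within each sample, every coding gene gets a percentile rank in [0, 1]:

    rank(g) = (#{genes strictly below g} + 0.5 · #{other genes tied with g}) / (N − 1)

so the smallest value maps to 0, the largest to 1, and full ties sit at 0.5.
Two filters then define the analysis universes:

* transcriptome-expressed — rank strictly above the 30th percentile in every
  INPUT (whole-lysate) sample;
* translatome-expressed — rank on or above the 10th percentile in every IP
  (ribosome-bound) sample, with ranks recomputed on the
  transcriptome-expressed universe only (the changed N changes the ranks).

The strict/non-strict asymmetry between the two thresholds is deliberate and
load-bearing for boundary genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .matrix import ExpressionMatrix

TRANSCRIPTOME_THRESHOLD = 0.30
TRANSLATOME_THRESHOLD = 0.10


@dataclass(frozen=True)
class ExpressedGeneSets:
    """The two nested expressed-gene universes of one analysis."""

    transcriptome_expressed: frozenset[str]
    translatome_expressed: frozenset[str]

    def __post_init__(self) -> None:
        if not self.translatome_expressed <= self.transcriptome_expressed:
            raise ValueError("translatome-expressed set must be a subset of "
                             "the transcriptome-expressed set")

    def summary(self) -> dict[str, int]:
        return {
            "n_transcriptome_expressed": len(self.transcriptome_expressed),
            "n_translatome_expressed": len(self.translatome_expressed),
        }


def percentile_ranks(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-sample percentile ranks of TPM, one column per sample, in [0, 1].

    Ties share the average rank; at least two genes are required for the
    denominator N − 1 to be positive.
    """
    n = matrix.n_genes
    if n < 2:
        raise ValueError("percentile ranks need at least 2 genes")
    # 1-based average ranks − 1 == strict-less count + half the co-tied count
    ranks = rankdata(matrix.values.to_numpy(), method="average", axis=0) - 1.0
    ranks /= (n - 1)
    return pd.DataFrame(ranks, index=matrix.genes, columns=matrix.sample_ids)


def _consistent(ranks: pd.DataFrame, sample_ids: Sequence[str],
                threshold: float, strict: bool) -> frozenset[str]:
    if not len(sample_ids):
        raise ValueError("empty sample list")
    sub = ranks[list(sample_ids)].to_numpy()
    ok = (sub > threshold) if strict else (sub >= threshold)
    return frozenset(ranks.index[ok.all(axis=1)])


def transcriptome_expressed(input_ranks: pd.DataFrame,
                            input_samples: Sequence[str],
                            threshold: float = TRANSCRIPTOME_THRESHOLD) -> frozenset[str]:
    """Genes ranked strictly above ``threshold`` in every INPUT sample."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    return _consistent(input_ranks, input_samples, threshold, strict=True)


def translatome_expressed(ip_ranks: pd.DataFrame,
                          gene_universe: frozenset[str] | set[str],
                          ip_samples: Sequence[str],
                          threshold: float = TRANSLATOME_THRESHOLD) -> frozenset[str]:
    """Genes ranked on or above ``threshold`` in every IP sample.

    ``ip_ranks`` must already be computed on the matrix restricted to
    ``gene_universe`` (the transcriptome-expressed set); this function checks
    the containment rather than slicing ranks computed on all genes.
    """
    if not gene_universe:
        raise ValueError("empty gene universe")
    extra = set(ip_ranks.index) - set(gene_universe)
    if extra:
        raise ValueError("IP ranks must be computed on the transcriptome-"
                         f"expressed universe only; unexpected genes: {sorted(extra)[:5]}")
    return _consistent(ip_ranks, ip_samples, threshold, strict=False)


def expressed_gene_sets(matrix: ExpressionMatrix,
                        input_samples: Sequence[str],
                        ip_samples: Sequence[str],
                        transcriptome_threshold: float = TRANSCRIPTOME_THRESHOLD,
                        translatome_threshold: float = TRANSLATOME_THRESHOLD) -> ExpressedGeneSets:
    """Run both consistency filters on a coding-gene matrix.

    INPUT ranks are computed on all genes of ``matrix``; IP ranks are
    recomputed after restricting to the transcriptome-expressed universe.
    """
    input_ranks = percentile_ranks(matrix.subset(samples=list(input_samples)))
    tx = transcriptome_expressed(input_ranks, list(input_samples),
                                 transcriptome_threshold)
    if not tx:
        return ExpressedGeneSets(frozenset(), frozenset())
    universe_order = [g for g in matrix.genes if g in tx]
    ip_matrix = matrix.subset(genes=universe_order, samples=list(ip_samples))
    ip_ranks = percentile_ranks(ip_matrix)
    tl = translatome_expressed(ip_ranks, tx, list(ip_samples), translatome_threshold)
    return ExpressedGeneSets(tx, tl)
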