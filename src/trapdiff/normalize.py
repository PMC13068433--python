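"""Quantile normalization across samples.

Every sample column is forced onto a common reference distribution: the
per-rank mean of the sorted columns.  Within a column the input ordering is
preserved; tied input values receive the mean of the reference values over the
tied rank span, so column sums — and hence the grand sum — are conserved.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .matrix import ExpressionMatrix


def quantile_normalize_frame(values: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize a genes × samples DataFrame (see module docstring)."""
    if values.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    if values.shape[0] < 2:
        raise ValueError("quantile normalization needs at least 2 genes")
    arr = values.to_numpy(dtype=float)
    reference = np.sort(arr, axis=0).mean(axis=1)
    # cumulative means let a tied span's mean be read off in O(1)
    csum = np.concatenate([[0.0], np.cumsum(reference)])

    out = np.empty_like(arr)
    n = arr.shape[0]
    for j in range(arr.shape[1]):
        col = arr[:, j]
        order = np.argsort(col, kind="mergesort")
        sorted_col = col[order]
        # tied spans in the sorted column: [start, stop) of equal values
        boundaries = np.flatnonzero(np.diff(sorted_col)) + 1
        starts = np.concatenate([[0], boundaries])
        stops = np.concatenate([boundaries, [n]])
        span_means = (csum[stops] - csum[starts]) / (stops - starts)
        # scatter the span mean back to every member of the span
        col_out = np.empty(n)
        span_of_pos = np.repeat(np.arange(len(starts)), stops - starts)
        col_out[order] = span_means[span_of_pos]
        out[:, j] = col_out
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize an expression matrix across its samples."""
    return matrix.with_values(quantile_normalize_frame(matrix.values))
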