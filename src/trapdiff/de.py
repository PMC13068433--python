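"""Differential ribosome-occupancy statistics: SSMD, sign-modified
Bhattacharyya coefficient, median-TPM log2 fold change, and the joint
threshold decision rule.

The design is statsmodels-like: :class:`TranslatomeDE` is built from an
expression matrix and a two-group design, ``fit()`` returns a
:class:`TranslatomeDEResults` carrying the per-gene table, the DE calls,
``summary()``, the dual-flashlight table and plot, and the top-15 gene lists.

Three statistics, three input surfaces
--------------------------------------
* **log2 fold change** — ``log2((median_a + pc) / (median_b + pc))`` on
  re-normalized TPM; positive means up in SNI (group a) relative to sham.
* **SSMD** — ``(μa − μb) / sqrt(σa² + σb²)`` with unbiased variances, computed
  on percentile ranks of the quantile-normalized TPM so the effect size is in
  rank units and robust to scale.
* **sign-modified Bhattacharyya coefficient** — each group is summarized by a
  Gaussian fit on TPM; the Bhattacharyya distance D between the two Gaussians
  gives an overlap coefficient BC = exp(−D) and the reported statistic is
  ``sign(log2fc) · (1 − BC)``: 0 for identical distributions, ±1 in the
  non-overlap limit.

A gene is called differentially expressed when all three pass jointly:
|SSMD| ≥ 0.97, |BC| ≥ 0.5 and fold change ≥ 1.33 (boundaries inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix
from .normalize import quantile_normalize_frame
from .ranks import percentile_ranks

#: cap used in place of an infinite SSMD (zero variance, unequal means)
SSMD_CAP = 1e6
#: relative variance floor for the Gaussian Bhattacharyya fit
VARIANCE_FLOOR_REL = 1e-8
DEFAULT_PSEUDOCOUNT = 0.01


@dataclass(frozen=True)
class DEThresholds:
    """Joint DE decision thresholds (all boundaries inclusive)."""

    ssmd_min: float = 0.97
    bc_min: float = 0.5
    fc_min: float = 1.33

    def __post_init__(self) -> None:
        if min(self.ssmd_min, self.bc_min, self.fc_min) <= 0:
            raise ValueError("all thresholds must be strictly positive")


@dataclass(frozen=True)
class GroupDesign:
    """Two disjoint replicate groups for one comparison.

    ``group_a`` is the treatment group (SNI) and ``group_b`` the control
    (sham); all fold changes and signs are oriented a-over-b.
    """

    group_a: tuple[str, ...]
    group_b: tuple[str, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if set(self.group_a) & set(self.group_b):
            raise ValueError("groups must be disjoint")
        if len(self.group_a) < 2 or len(self.group_b) < 2:
            raise ValueError("each group needs at least 2 replicates")

    @classmethod
    def from_matrix(cls, matrix: ExpressionMatrix, *, fraction: str,
                    cell_type: str | None = None, timepoint: str | None = None,
                    label: str | None = None) -> "GroupDesign":
        """Build the SNI-vs-sham design for one fraction/cell type/timepoint."""
        crit: dict[str, object] = {"fraction": fraction}
        if cell_type is not None:
            crit["cell_type"] = cell_type
        if timepoint is not None:
            crit["timepoint"] = timepoint
        sni = matrix.select_samples(condition="SNI", **crit)
        sham = matrix.select_samples(condition="sham", **crit)
        if label is None:
            label = " ".join(str(v) for v in (cell_type, timepoint) if v is not None)
        return cls(tuple(sni), tuple(sham), label)


# ----------------------------------------------------------- scalar statistics

def log2_fold_change(group_a: Sequence[float], group_b: Sequence[float],
                     pseudocount: float = DEFAULT_PSEUDOCOUNT) -> float:
    """log2 of the pseudocounted ratio of group medians (a over b).

    NaN when both medians and the pseudocount are zero (not evaluable).
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    ma = float(np.median(group_a)) + pseudocount
    mb = float(np.median(group_b)) + pseudocount
    if ma == 0 and mb == 0:
        return float("nan")
    if ma == 0 or mb == 0:
        return float("-inf") if ma == 0 else float("inf")
    return float(np.log2(ma / mb))


def ssmd(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Strictly standardized mean difference (μa − μb)/√(σa² + σb²).

    Unbiased (n−1) variances.  With both variances zero, returns 0 for equal
    means and the ±1e6 cap otherwise so sorting stays well-defined.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("SSMD needs at least 2 values per group")
    num = a.mean() - b.mean()
    denom = np.sqrt(a.var(ddof=1) + b.var(ddof=1))
    if denom == 0:
        return 0.0 if num == 0 else float(np.sign(num)) * SSMD_CAP
    return float(np.clip(num / denom, -SSMD_CAP, SSMD_CAP))


def bhattacharyya_coefficient_gaussian(mu_a: float, var_a: float,
                                       mu_b: float, var_b: float) -> float:
    """Overlap coefficient exp(−D) of two Gaussians (closed form)."""
    if var_a <= 0 or var_b <= 0:
        raise ValueError("variances must be positive")
    s = var_a + var_b
    d = 0.25 * (mu_a - mu_b) ** 2 / s + 0.5 * np.log(s / (2.0 * np.sqrt(var_a * var_b)))
    return float(np.exp(-d))


def bhattacharyya_modified(group_a: Sequence[float], group_b: Sequence[float],
                           sign_source: float) -> float:
    """Sign-modified Bhattacharyya coefficient in [−1, 1].

    Each group is fitted with a Gaussian (sample mean, unbiased variance; a
    variance floor of ``1e-8 · grand_mean²`` guards degenerate groups) and
    the statistic is ``sign(sign_source) · (1 − exp(−D))`` — 0 for identical
    distributions, approaching ±1 as the distributions separate, the sign
    taken from the log fold change.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("Bhattacharyya needs at least 2 values per group")
    grand = np.concatenate([a, b]).mean()
    floor = max(VARIANCE_FLOOR_REL * grand * grand, np.finfo(float).tiny)
    bc = bhattacharyya_coefficient_gaussian(
        a.mean(), max(a.var(ddof=1), floor), b.mean(), max(b.var(ddof=1), floor))
    sign = np.sign(sign_source) if np.isfinite(sign_source) else np.sign(a.mean() - b.mean())
    return float(sign * (1.0 - bc))


# --------------------------------------------------------- vectorized internals

def _group_stats(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise mean, unbiased variance, median of a genes × replicates array."""
    return arr.mean(axis=1), arr.var(axis=1, ddof=1), np.median(arr, axis=1)


def _ssmd_vec(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    mu_a, var_a, _ = _group_stats(a)
    mu_b, var_b, _ = _group_stats(b)
    num = mu_a - mu_b
    denom = np.sqrt(var_a + var_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = num / denom
    zero_den = denom == 0
    out[zero_den & (num == 0)] = 0.0
    out[zero_den & (num != 0)] = np.sign(num[zero_den & (num != 0)]) * SSMD_CAP
    return np.clip(out, -SSMD_CAP, SSMD_CAP)


def _bc_mod_vec(a: np.ndarray, b: np.ndarray, log2fc: np.ndarray) -> np.ndarray:
    mu_a, var_a, _ = _group_stats(a)
    mu_b, var_b, _ = _group_stats(b)
    grand = np.concatenate([a, b], axis=1).mean(axis=1)
    floor = np.maximum(VARIANCE_FLOOR_REL * grand * grand, np.finfo(float).tiny)
    var_a = np.maximum(var_a, floor)
    var_b = np.maximum(var_b, floor)
    s = var_a + var_b
    d = 0.25 * (mu_a - mu_b) ** 2 / s + 0.5 * np.log(s / (2.0 * np.sqrt(var_a * var_b)))
    sign = np.sign(log2fc)
    fallback = ~np.isfinite(log2fc)
    if fallback.any():
        sign = np.where(fallback, np.sign(mu_a - mu_b), sign)
    return sign * (1.0 - np.exp(-d))


def _log2fc_vec(a: np.ndarray, b: np.ndarray, pseudocount: float) -> np.ndarray:
    ma = np.median(a, axis=1) + pseudocount
    mb = np.median(b, axis=1) + pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.log2(ma) - np.log2(mb)


# --------------------------------------------------------------- decision rule

def call_de(table: pd.DataFrame, thresholds: DEThresholds = DEThresholds()) -> pd.DataFrame:
    """Apply the joint DE rule to a table with log2fc / ssmd / bc_mod columns.

    Adds ``is_de`` and ``direction`` (up/down/none).  All three criteria are
    inclusive at the boundary; a gene with non-evaluable (NaN) log2fc is never
    called.
    """
    t = table.copy()
    fc = 2.0 ** np.abs(t["log2fc"].to_numpy())
    with np.errstate(invalid="ignore"):
        is_de = ((np.abs(t["ssmd"].to_numpy()) >= thresholds.ssmd_min)
                 & (np.abs(t["bc_mod"].to_numpy()) >= thresholds.bc_min)
                 & (fc >= thresholds.fc_min)
                 & np.isfinite(t["log2fc"].to_numpy()))
    t["is_de"] = is_de
    direction = np.where(t["log2fc"].to_numpy() > 0, "up", "down")
    t["direction"] = np.where(is_de, direction, "none")
    return t


def dual_flashlight_table(results: pd.DataFrame, n_top: int = 15
                          ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Plot-ready table sorted by |SSMD| descending, plus top up/down DE lists.

    Returns ``(table, top_up, top_down)``; the top lists hold at most
    ``n_top`` DE genes each, as in the published top-15 panels.
    """
    if results.empty:
        raise ValueError("empty results table")
    order = results.reindex(results["ssmd"].abs().sort_values(ascending=False).index)
    up = order[(order["is_de"]) & (order["direction"] == "up")].head(n_top)
    down = order[(order["is_de"]) & (order["direction"] == "down")].head(n_top)
    cols = [c for c in ("gene_id", "log2fc", "ssmd", "bc_mod", "is_de") if c in order.columns]
    return order[cols + [c for c in order.columns if c not in cols]], up, down


def marker_enrichment(matrix: ExpressionMatrix, markers: Sequence[str],
                      pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.DataFrame:
    """Per-marker log2 IP/INPUT enrichment from median TPM.

    Markers absent from the matrix are listed with ``present=False`` and NaN
    ratio rather than silently dropped.  Positive values indicate enrichment
    in the immunoprecipitated (cell-type-specific) fraction.
    """
    ip = matrix.select_samples(fraction="IP")
    inp = matrix.select_samples(fraction="INPUT")
    if not ip or not inp:
        raise ValueError("both IP and INPUT samples are required")
    rows = []
    for g in markers:
        if g in matrix.genes:
            med_ip = float(matrix.values.loc[g, ip].median())
            med_in = float(matrix.values.loc[g, inp].median())
            ratio = log2_fold_change([med_ip], [med_in], pseudocount)
            rows.append((g, True, med_ip, med_in, ratio))
        else:
            rows.append((g, False, np.nan, np.nan, np.nan))
    return pd.DataFrame(rows, columns=["gene_id", "present", "median_ip",
                                       "median_input", "log2_ip_in"])


# -------------------------------------------------------------- Model / Results

class TranslatomeDE:
    """Differential ribosome-occupancy model for one two-group comparison.

    Parameters
    ----------
    matrix : ExpressionMatrix
        Re-normalized TPM restricted to the expressed-gene universe for the
        fraction under analysis (typically IP / translatome-expressed).
    design : GroupDesign
        The SNI (group a) versus sham (group b) sample split.
    thresholds : DEThresholds
        Joint decision thresholds.
    pseudocount : float
        Added to both medians in the fold change.
    ssmd_input : {"qn_ranks", "raw_ranks"}
        Whether SSMD sees percentile ranks of quantile-normalized TPM
        (default) or ranks of the raw TPM.
    """

    def __init__(self, matrix: ExpressionMatrix, design: GroupDesign,
                 thresholds: DEThresholds = DEThresholds(),
                 pseudocount: float = DEFAULT_PSEUDOCOUNT,
                 ssmd_input: Literal["qn_ranks", "raw_ranks"] = "qn_ranks"):
        all_samples = list(design.group_a) + list(design.group_b)
        missing = set(all_samples) - set(matrix.sample_ids)
        if missing:
            raise ValueError(f"design samples absent from matrix: {sorted(missing)}")
        if ssmd_input not in ("qn_ranks", "raw_ranks"):
            raise ValueError(f"unknown ssmd_input {ssmd_input!r}")
        self.matrix = matrix.subset(samples=all_samples)
        self.design = design
        self.thresholds = thresholds
        self.pseudocount = pseudocount
        self.ssmd_input = ssmd_input

    def fit(self) -> "TranslatomeDEResults":
        """Compute all three statistics per gene and apply the decision rule."""
        tpm = self.matrix.values
        a_tpm = tpm[list(self.design.group_a)].to_numpy()
        b_tpm = tpm[list(self.design.group_b)].to_numpy()

        if self.ssmd_input == "qn_ranks":
            rank_source = self.matrix.with_values(quantile_normalize_frame(tpm))
        else:
            rank_source = self.matrix
        rank_frame = percentile_ranks(rank_source)
        a_rank = rank_frame[list(self.design.group_a)].to_numpy()
        b_rank = rank_frame[list(self.design.group_b)].to_numpy()

        log2fc = _log2fc_vec(a_tpm, b_tpm, self.pseudocount)
        table = pd.DataFrame({
            "gene_id": self.matrix.genes,
            "log2fc": log2fc,
            "ssmd": _ssmd_vec(a_rank, b_rank),
            "bc_mod": _bc_mod_vec(a_tpm, b_tpm, log2fc),
        }).reset_index(drop=True)
        table = call_de(table, self.thresholds)
        return TranslatomeDEResults(self, table)


@dataclass
class TranslatomeDEResults:
    """Fitted per-gene DE statistics and calls for one comparison."""

    model: TranslatomeDE
    table: pd.DataFrame = field(repr=False)

    @property
    def n_de(self) -> int:
        return int(self.table["is_de"].sum())

    @property
    def n_up(self) -> int:
        return int((self.table["direction"] == "up").sum())

    @property
    def n_down(self) -> int:
        return int((self.table["direction"] == "down").sum())

    def de_genes(self) -> list[str]:
        return self.table.loc[self.table["is_de"], "gene_id"].tolist()

    def dual_flashlight(self, n_top: int = 15):
        return dual_flashlight_table(self.table, n_top)

    def summary(self) -> str:
        """Human-readable summary block, statsmodels-style."""
        d = self.model.design
        th = self.model.thresholds
        lines = [
            "Translatome differential expression (SSMD + Bhattacharyya)",
            "=" * 58,
            f"Comparison:        {d.label or '(unlabelled)'}",
            f"Group a (SNI):     {len(d.group_a)} samples",
            f"Group b (sham):    {len(d.group_b)} samples",
            f"Genes tested:      {len(self.table)}",
            f"Thresholds:        |SSMD| >= {th.ssmd_min}, |BC| >= {th.bc_min}, "
            f"FC >= {th.fc_min}",
            f"SSMD input:        {self.model.ssmd_input}",
            f"DE genes:          {self.n_de} ({self.n_up} up, {self.n_down} down)",
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.12g")

    def plot_dual_flashlight(self, ax=None, n_top: int = 15):
        """SSMD versus log2 fold change scatter with DE genes highlighted."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        t = self.table
        bg = t[~t["is_de"]]
        ax.scatter(bg["log2fc"], bg["ssmd"], s=6, c="0.7", label="not DE")
        for direction, color in (("up", "tab:red"), ("down", "tab:blue")):
            sel = t[t["direction"] == direction]
            if len(sel):
                ax.scatter(sel["log2fc"], sel["ssmd"], s=10, c=color,
                           label=f"{direction} ({len(sel)})")
        th = self.model.thresholds
        for y in (th.ssmd_min, -th.ssmd_min):
            ax.axhline(y, ls="--", lw=0.6, c="k")
        ax.set_xlabel("log2 fold change (SNI / sham)")
        ax.set_ylabel("SSMD (rank scale)")
        ax.set_title(self.model.design.label or "dual-flashlight")
        ax.legend(frameon=False, fontsize=8)
        return ax
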