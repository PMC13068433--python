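"""Expression-matrix container and TSV I/O.

The pipeline's single data currency is a genes × samples TPM matrix carrying a
gene annotation table (biotype, chromosome) and a sample sheet (fraction,
condition, cell type, timepoint, replicate).  TPM values are non-negative and
finite; missing detection is encoded as 0, never NaN, because the downstream
percentile-rank machinery needs a total order on each sample column.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

TPM_TOTAL = 1_000_000.0

#: chromosome names treated as mitochondrial by default
DEFAULT_MITO_CHROMS = ("chrM", "MT")

VALID_BIOTYPES = frozenset({"protein_coding", "non_coding"})
VALID_FRACTIONS = frozenset({"IP", "INPUT"})
VALID_CONDITIONS = frozenset({"sham", "SNI"})

SAMPLE_SHEET_COLUMNS = [
    "sample_id", "fraction", "condition", "cell_type", "timepoint", "replicate",
]
ANNOTATION_COLUMNS = ["gene_id", "biotype", "chromosome"]


class MatrixError(ValueError):
    """Raised for malformed expression matrices, annotations or sample sheets."""


@dataclass
class ExpressionMatrix:
    """Genes × samples TPM matrix with annotations and sample metadata.

    Parameters
    ----------
    values : pandas.DataFrame
        TPM values, index = gene ids, columns = sample ids.
    samples : pandas.DataFrame
        Sample sheet indexed by sample id with columns ``fraction``,
        ``condition``, ``cell_type``, ``timepoint``, ``replicate``.
    annotations : pandas.DataFrame
        Gene annotation indexed by gene id with columns ``biotype`` and
        ``chromosome``.  May contain genes beyond those in ``values``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    annotations: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self._validate()

    # ------------------------------------------------------------------ checks
    def _validate(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise MatrixError(f"duplicate gene ids: {dups[:5]}")
        if v.columns.has_duplicates:
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise MatrixError(f"duplicate sample ids: {dups[:5]}")
        arr = v.to_numpy()
        if not np.isfinite(arr).all():
            raise MatrixError("non-finite expression value (NaN/inf); encode absent detection as 0")
        if (arr < 0).any():
            gene = v.index[np.where(arr < 0)[0][0]]
            raise MatrixError(f"negative expression value for gene {gene!r}")
        missing = v.columns.difference(self.samples.index)
        if len(missing):
            raise MatrixError(f"samples absent from sample sheet: {sorted(missing)[:5]}")
        if not self.annotations.empty:
            unannotated = v.index.difference(self.annotations.index)
            if len(unannotated):
                raise MatrixError(f"genes lacking annotation: {sorted(unannotated)[:5]}")

    # --------------------------------------------------------------- accessors
    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def sample_meta(self) -> pd.DataFrame:
        """Sample sheet rows for the samples present in the matrix, in order."""
        return self.samples.loc[self.sample_ids]

    def select_samples(self, **criteria: object) -> list[str]:
        """Sample ids matching metadata equality criteria.

        ``matrix.select_samples(fraction="IP", condition="SNI")``
        """
        meta = self.sample_meta()
        mask = pd.Series(True, index=meta.index)
        for key, val in criteria.items():
            if key not in meta.columns:
                raise KeyError(f"unknown sample attribute {key!r}")
            mask &= meta[key] == val
        return meta.index[mask].tolist()

    def subset(self, genes: Iterable[str] | None = None,
               samples: Iterable[str] | None = None) -> "ExpressionMatrix":
        """Restrict to the given genes and/or samples (order preserved as given)."""
        v = self.values
        if genes is not None:
            genes = list(genes)
            missing = set(genes) - set(v.index)
            if missing:
                raise MatrixError(f"unknown genes: {sorted(missing)[:5]}")
            v = v.loc[genes]
        if samples is not None:
            samples = list(samples)
            missing = set(samples) - set(v.columns)
            if missing:
                raise MatrixError(f"unknown samples: {sorted(missing)[:5]}")
            v = v[samples]
        return ExpressionMatrix(v, self.samples, self.annotations)

    def with_values(self, values: pd.DataFrame) -> "ExpressionMatrix":
        """Same metadata, new value matrix (axes must be compatible)."""
        return ExpressionMatrix(values, self.samples, self.annotations)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.samples.copy(),
                                self.annotations.copy())


# ---------------------------------------------------------------------- I/O

def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a TSV gene annotation table (gene_id, biotype, chromosome)."""
    ann = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise MatrixError(f"annotation table missing columns: {missing}")
    if ann["gene_id"].duplicated().any():
        raise MatrixError("duplicate gene ids in annotation table")
    bad = set(ann["biotype"]) - VALID_BIOTYPES
    if bad:
        raise MatrixError(f"unknown biotypes: {sorted(bad)}")
    return ann.set_index("gene_id")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a TSV sample sheet; validates fractions/conditions and uniqueness."""
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise MatrixError(f"sample sheet missing columns: {missing}")
    if sheet["sample_id"].duplicated().any():
        raise MatrixError("duplicate sample ids in sample sheet")
    bad = set(sheet["fraction"]) - VALID_FRACTIONS
    if bad:
        raise MatrixError(f"unknown fractions: {sorted(bad)} (expected IP/INPUT)")
    bad = set(sheet["condition"]) - VALID_CONDITIONS
    if bad:
        raise MatrixError(f"unknown conditions: {sorted(bad)} (expected sham/SNI)")
    sheet["replicate"] = sheet["replicate"].astype(int)
    if (sheet["replicate"] < 1).any():
        raise MatrixError("replicate numbers must be positive")
    return sheet.set_index("sample_id")


def read_matrix(path: str | Path, annotation_path: str | Path,
                sample_sheet_path: str | Path) -> ExpressionMatrix:
    """Read a TPM matrix (genes as rows, samples as columns) with its metadata.

    The returned matrix carries exactly the sample-sheet samples that appear in
    the TSV header, in sample-sheet order.  Samples in the matrix but absent
    from the sheet, genes lacking annotation, and negative or non-numeric
    values are all errors.
    """
    for p in (path, annotation_path, sample_sheet_path):
        if not Path(p).exists():
            raise FileNotFoundError(p)
    annotations = read_annotations(annotation_path)
    samples = read_sample_sheet(sample_sheet_path)
    raw = pd.read_csv(path, sep="\t", index_col=0)
    try:
        raw = raw.astype(float)
    except (TypeError, ValueError) as exc:
        raise MatrixError(f"non-numeric expression value: {exc}") from exc
    ordered = [s for s in samples.index if s in raw.columns]
    extra = raw.columns.difference(samples.index)
    if len(extra):
        raise MatrixError(f"samples in matrix absent from sheet: {sorted(extra)[:5]}")
    return ExpressionMatrix(raw[ordered], samples, annotations)


def write_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write the TPM matrix as TSV with 12 significant digits."""
    out = matrix.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.12g")


def write_sample_sheet(matrix: ExpressionMatrix, path: str | Path) -> None:
    meta = matrix.sample_meta().copy()
    meta.index.name = "sample_id"
    meta.to_csv(path, sep="\t")


def write_annotations(matrix: ExpressionMatrix, path: str | Path) -> None:
    ann = matrix.annotations.copy()
    ann.index.name = "gene_id"
    ann.to_csv(path, sep="\t")


# ----------------------------------------------------------- transformations

def filter_coding(matrix: ExpressionMatrix,
                  mito_chroms: Sequence[str] = DEFAULT_MITO_CHROMS) -> ExpressionMatrix:
    """Drop non-coding and mitochondrial genes; values and samples untouched.

    Mitochondrial genes are identified by chromosome name (default accepts
    both ``chrM`` and ``MT`` spellings).
    """
    if matrix.annotations.empty:
        raise MatrixError("cannot filter without gene annotations")
    ann = matrix.annotations.loc[matrix.genes]
    keep = (ann["biotype"] == "protein_coding") & (~ann["chromosome"].isin(mito_chroms))
    if not keep.any():
        raise MatrixError("empty matrix after coding/mitochondrial filtering")
    return matrix.subset(genes=matrix.genes[keep.to_numpy()])


def renormalize_tpm(matrix: ExpressionMatrix, total: float = TPM_TOTAL) -> ExpressionMatrix:
    """Rescale every sample column so it sums to one million.

    Applied after coding-gene filtering so that coding genes alone carry the
    per-sample total.  Idempotent.
    """
    sums = matrix.values.sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero):
        raise MatrixError(f"all-zero sample column(s): {zero.index.tolist()}")
    return matrix.with_values(matrix.values * (total / sums))
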