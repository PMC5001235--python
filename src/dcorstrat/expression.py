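"""Gene x sample expression matrices and per-patient SMG submatrices.

Every pairwise comparison in the workflow happens over one shared cohort of
expression samples: patient a's SMG list g_a selects n_a rows of the cohort
matrix, giving the submatrix E^a whose N columns are the cohort samples'
expression profiles restricted to those genes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .variant_io import SMGProfile, normalize_gene_symbol

logger = logging.getLogger(__name__)


class ExpressionFormatError(ValueError):
    """Raised for structurally unusable expression tables."""


class UnmatchableProfileError(ValueError):
    """Raised when none of a patient's SMG symbols match the expression index."""


@dataclass
class ExpressionMatrix:
    """Gene x sample numeric matrix with identifier indexes.

    ``data`` is indexed by normalized gene symbol (rows) and sample id
    (columns); ``transform_tag`` records the value transform applied at load.
    """

    data: pd.DataFrame
    transform_tag: str = "none"

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ExpressionFormatError("duplicate gene identifiers after collapse")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ExpressionFormatError(f"duplicate sample identifiers: {dupes}")
        if not np.isfinite(self.data.to_numpy()).all():
            raise ExpressionFormatError("expression matrix contains non-finite values")


@dataclass
class ExpressionSubmatrix:
    """E^a: the cohort expression matrix restricted to one patient's SMGs.

    Rows are the matched profile genes (in cohort matrix order); the N columns
    are the shared cohort samples, identical in order across all submatrices
    of a run.
    """

    owner_patient: str
    genes_matched: list[str]
    samples: list[str]
    values: np.ndarray
    genes_missing: list[str] = field(default_factory=list)

    @property
    def n_genes(self) -> int:
        return len(self.genes_matched)


def read_expression_table(path, transform: str = "log2p1") -> ExpressionMatrix:
    """Load a tab-delimited expression table (first column gene ids, header
    sample ids).

    Composite ``SYMBOL|entrez`` identifiers are split and the symbol kept
    (``?`` rows dropped); duplicate gene rows are collapsed by mean. The
    default ``log2p1`` transform applies log2(x+1), appropriate for
    nonnegative RNA-seq abundance values whose raw distances would otherwise
    be dominated by a few high-abundance genes; pass ``"none"`` to keep raw
    values.
    """
    if transform not in ("log2p1", "none"):
        raise ValueError(f"unknown transform {transform!r}")
    with open(path) as fh:  # pandas mangles duplicate header names; check raw
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        dupes = sorted({s for s in header if header.count(s) > 1})
        raise ExpressionFormatError(f"duplicate sample identifiers: {dupes}")
    table = pd.read_csv(path, sep="\t", index_col=0)
    for col in table.columns:
        if not pd.api.types.is_numeric_dtype(table[col]):
            bad = table[pd.to_numeric(table[col], errors="coerce").isna()].index
            raise ExpressionFormatError(
                f"non-numeric value in column {col!r} at gene row(s) {list(bad)[:5]}"
            )

    symbols = [normalize_gene_symbol(str(g)) for g in table.index]
    keep = [s is not None for s in symbols]
    if not all(keep):
        logger.info("dropping %d row(s) with unresolvable gene symbol", keep.count(False))
    table = table.loc[keep]
    table.index = [s for s in symbols if s is not None]

    if table.index.has_duplicates:
        n_dup = int(table.index.duplicated().sum())
        logger.info("collapsing %d duplicate gene row(s) by mean", n_dup)
        table = table.groupby(level=0, sort=False).mean()

    if transform == "log2p1":
        if (table.to_numpy() < 0).any():
            raise ExpressionFormatError("log2p1 transform requires nonnegative values")
        table = np.log2(table + 1.0)
    return ExpressionMatrix(data=table, transform_tag=transform)


def extract_submatrix(expr: ExpressionMatrix, profile: SMGProfile) -> ExpressionSubmatrix:
    """Select the expression rows for one patient's SMG profile.

    Matched rows keep the cohort matrix's gene order; symbols absent from the
    expression index go to ``genes_missing``. A profile with zero matches is
    an error — such patients have no expression submatrix and are excluded
    upstream.
    """
    if profile.size == 0:
        raise UnmatchableProfileError(f"patient {profile.patient_id}: empty SMG profile")
    index = set(expr.data.index)
    matched = [g for g in expr.genes if g in profile.genes]
    missing = sorted(g for g in profile.genes if g not in index)
    if not matched:
        raise UnmatchableProfileError(
            f"patient {profile.patient_id}: no SMG symbol matches the expression index"
        )
    if missing:
        logger.debug("patient %s: %d SMG(s) missing from expression", profile.patient_id, len(missing))
    return ExpressionSubmatrix(
        owner_patient=profile.patient_id,
        genes_matched=matched,
        samples=expr.samples,
        values=expr.data.loc[matched].to_numpy(dtype=float),
        genes_missing=missing,
    )


def cohort_columns(expr: ExpressionMatrix, sample_filter: list[str]) -> ExpressionMatrix:
    """Column-subset the matrix to a cohort, preserving the original sample
    order. Lets the whole workflow run against alternative backgrounds (e.g.
    tumor vs normal-tissue samples)."""
    known = set(expr.samples)
    unknown = [s for s in sample_filter if s not in known]
    if unknown:
        raise KeyError(f"unknown sample id(s): {unknown}")
    wanted = set(sample_filter)
    cols = [s for s in expr.samples if s in wanted]
    return ExpressionMatrix(data=expr.data[cols], transform_tag=expr.transform_tag)


def missing_gene_report(submatrices: list[ExpressionSubmatrix]) -> pd.DataFrame:
    """Long-format (patient_id, missing_symbol) table across a run."""
    rows = [
        {"patient_id": sm.owner_patient, "missing_symbol": g}
        for sm in submatrices
        for g in sm.genes_missing
    ]
    return pd.DataFrame(rows, columns=["patient_id", "missing_symbol"])


def log2p1(x: float) -> float:
    """The default expression transform for a single value."""
    return math.log2(x + 1.0)
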