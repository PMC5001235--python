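"""Somatic mutation (MAF) ingestion and per-patient SMG profile construction.

A significantly mutated gene (SMG) is a gene carrying a protein-disrupting
somatic variant: a frame-shift indel, splice-site change, non-stop mutation,
or nonsense mutation. Missense ("mismatch"), silent, RNA and in-frame indel
calls do not qualify. Each patient's SMG profile is the deduplicated set of
qualifying gene symbols; these sets are the features the downstream
distance-correlation workflow compares.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

#: Variant_Classification values that make a gene an SMG.
QUALIFYING_CLASSES = frozenset(
    {
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "Splice_Site",
        "Nonstop_Mutation",
        "Nonsense_Mutation",
    }
)

#: Explicitly excluded classes (protein-tolerant or non-coding calls).
EXCLUDED_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Silent",
        "RNA",
        "In_Frame_Del",
        "In_Frame_Ins",
    }
)

#: Remaining values of the standard MAF vocabulary; excluded by default but
#: overridable via ``extra_qualifying``.
OTHER_KNOWN_CLASSES = frozenset(
    {
        "3'UTR",
        "5'UTR",
        "3'Flank",
        "5'Flank",
        "IGR",
        "Intron",
        "Translation_Start_Site",
        "Targeted_Region",
        "De_novo_Start_InFrame",
        "De_novo_Start_OutOfFrame",
        "Splice_Region",
        "Nonstop_Mutation",
    }
)

KNOWN_CLASSES = QUALIFYING_CLASSES | EXCLUDED_CLASSES | OTHER_KNOWN_CLASSES

REQUIRED_COLUMNS = ("Hugo_Symbol", "Variant_Classification", "Tumor_Sample_Barcode")


class MafFormatError(ValueError):
    """Raised when a MAF file is structurally unusable."""


@dataclass(frozen=True)
class VariantRecord:
    """One somatic variant call reduced to the fields the workflow uses."""

    patient_id: str
    gene_symbol: str
    variant_classification: str


@dataclass(frozen=True)
class SMGProfile:
    """A patient's set of significantly mutated genes."""

    patient_id: str
    genes: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass
class MafParseResult:
    """Parsed records plus a skip summary for the run log/roster report."""

    records: list[VariantRecord]
    n_rows: int = 0
    n_skipped: int = 0
    skip_reasons: Counter = field(default_factory=Counter)


def normalize_gene_symbol(raw: str) -> str | None:
    """Normalize a gene identifier: split composite ``SYMBOL|entrez`` ids,
    uppercase, and map the unknown-symbol placeholder ``?`` to None."""
    symbol = raw.split("|", 1)[0].strip().upper()
    if not symbol or symbol == "?":
        return None
    return symbol


def truncate_barcode(barcode: str, prefix_len: int = 12) -> str:
    """Reduce a TCGA-style sample barcode to its patient-level prefix."""
    barcode = barcode.strip()
    return barcode[:prefix_len] if prefix_len else barcode


def read_maf(
    path,
    *,
    patient_prefix_len: int = 12,
) -> MafParseResult:
    """Read a tab-delimited MAF-dialect table into variant records.

    Any column order is accepted and extra columns are ignored; the three
    required columns are matched case-insensitively. Rows with a missing
    required field or an unresolvable gene symbol are skipped and counted.

    Parameters
    ----------
    path : path-like
        Tab-delimited file with a header row.
    patient_prefix_len : int
        Number of leading barcode characters that identify the patient
        (12 for TCGA barcodes); 0 keeps the full barcode.
    """
    try:
        table = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        raise MafFormatError(f"empty MAF file: {path}") from None

    colmap = {c.lower(): c for c in table.columns}
    missing = [c for c in REQUIRED_COLUMNS if c.lower() not in colmap]
    if missing:
        raise MafFormatError(f"MAF file {path} lacks required column(s): {', '.join(missing)}")

    result = MafParseResult(records=[], n_rows=len(table))
    gene_col = colmap["hugo_symbol"]
    class_col = colmap["variant_classification"]
    barcode_col = colmap["tumor_sample_barcode"]

    i_gene = table.columns.get_loc(gene_col)
    i_class = table.columns.get_loc(class_col)
    i_barcode = table.columns.get_loc(barcode_col)
    for row in table.itertuples(index=False, name=None):
        raw_gene = row[i_gene]
        raw_class = row[i_class]
        raw_barcode = row[i_barcode]
        if pd.isna(raw_barcode) or not str(raw_barcode).strip():
            result.n_skipped += 1
            result.skip_reasons["missing_barcode"] += 1
            continue
        if pd.isna(raw_class) or not str(raw_class).strip():
            result.n_skipped += 1
            result.skip_reasons["missing_classification"] += 1
            continue
        if pd.isna(raw_gene) or not str(raw_gene).strip():
            result.n_skipped += 1
            result.skip_reasons["missing_gene_symbol"] += 1
            continue
        symbol = normalize_gene_symbol(str(raw_gene))
        if symbol is None:
            result.n_skipped += 1
            result.skip_reasons["unresolvable_gene_symbol"] += 1
            continue
        vc = str(raw_class).strip()
        if vc not in KNOWN_CLASSES:
            logger.debug("unknown Variant_Classification %r (kept, non-qualifying)", vc)
        result.records.append(
            VariantRecord(
                patient_id=truncate_barcode(str(raw_barcode), patient_prefix_len),
                gene_symbol=symbol,
                variant_classification=vc,
            )
        )
    if result.n_skipped:
        logger.info(
            "read_maf: %d/%d rows skipped (%s)",
            result.n_skipped,
            result.n_rows,
            dict(result.skip_reasons),
        )
    return result


def is_smg_qualifying(
    variant_classification: str,
    extra_qualifying: frozenset[str] | set[str] = frozenset(),
) -> bool:
    """Whether a Variant_Classification value makes the gene an SMG.

    Frame-shift indels, splice-site, non-stop and nonsense mutations qualify;
    missense, silent, RNA and in-frame indels do not. Any other value
    (including unknown vocabulary) is non-qualifying unless listed in
    ``extra_qualifying``.
    """
    vc = variant_classification.strip()
    if vc in QUALIFYING_CLASSES:
        return True
    if vc in EXCLUDED_CLASSES:
        return False
    if vc in extra_qualifying:
        return True
    if vc not in KNOWN_CLASSES:
        logger.debug("unknown Variant_Classification %r treated as non-qualifying", vc)
    return False


def build_smg_profiles(
    records: list[VariantRecord],
    extra_qualifying: frozenset[str] | set[str] = frozenset(),
) -> dict[str, SMGProfile]:
    """Reduce variant records to one SMG profile per patient.

    A gene enters a patient's profile if it carries at least one qualifying
    variant in that patient; duplicates collapse. Patients whose variants are
    all non-qualifying keep an empty profile in the roster (they are excluded
    later from the distance-correlation matrix, where an expression submatrix
    is required).
    """
    genes_by_patient: dict[str, set[str]] = {}
    for rec in records:
        bucket = genes_by_patient.setdefault(rec.patient_id, set())
        if is_smg_qualifying(rec.variant_classification, extra_qualifying):
            bucket.add(rec.gene_symbol)
    profiles = {
        pid: SMGProfile(patient_id=pid, genes=frozenset(genes))
        for pid, genes in genes_by_patient.items()
    }
    n_empty = sum(1 for p in profiles.values() if p.size == 0)
    if n_empty:
        logger.info("build_smg_profiles: %d patient(s) with empty SMG profile", n_empty)
    return profiles


def profiles_to_table(profiles: dict[str, SMGProfile]) -> pd.DataFrame:
    """Two-column long-format table (patient_id, gene), sorted for stable output."""
    rows = [
        {"patient_id": pid, "gene": g}
        for pid, prof in sorted(profiles.items())
        for g in sorted(prof.genes)
    ]
    return pd.DataFrame(rows, columns=["patient_id", "gene"])
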