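"""Cohort domain types, the bundled variant tables, and HGVS-based annotation.

The bundled fixture (``data/cohort_tables.tsv``) holds 120 reported mosaic
variant records: 80 carried by probands and 40 by parents or a grandparent.
One parental row is a reconstructed placeholder (``106-PLACEHOLDER``) whose
category, classification, and consequence class are forced by the published
aggregate counts; its gene symbol is a unique sentinel and its allele
fraction is deliberately absent so that no group mean is contaminated.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Union

log = logging.getLogger(__name__)

__all__ = [
    "Table",
    "Carrier",
    "Sex",
    "Inheritance",
    "Classification",
    "AafMethod",
    "ConsequenceClass",
    "SequenceContext",
    "CohortRecord",
    "FixtureError",
    "load_cohort_fixture",
    "classify_consequence",
    "is_substitution",
    "is_cpg_site",
    "substitution_alleles",
]


class Table(str, Enum):
    PROBAND = "proband"
    PARENTAL = "parental"


class Carrier(str, Enum):
    PROBAND = "proband"
    MOTHER = "mother"
    FATHER = "father"
    GRANDMOTHER = "grandmother"


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Inheritance(str, Enum):
    AD = "AD"
    AD_AR = "AD_AR"
    AD_SOMATIC = "AD_somatic"
    AR = "AR"
    XL = "XL"
    SOMATIC_ONLY = "somatic_only"


class Classification(str, Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    VOUS = "VOUS"


class AafMethod(str, Enum):
    EXOME = "exome"
    AMPLICON = "amplicon"
    SANGER_ONLY = "sanger_only"
    UNAVAILABLE = "unavailable"


class ConsequenceClass(str, Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    INFRAME_INDEL = "inframe_indel"
    SPLICE = "splice"
    OTHER = "other"


_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class SequenceContext:
    """Reference base of a substitution site with its immediate flanks."""

    ref_base: str
    five_prime: str
    three_prime: str

    def __post_init__(self) -> None:
        for name in ("ref_base", "five_prime", "three_prime"):
            base = getattr(self, name)
            if base not in _BASES:
                raise ValueError(f"{name} must be one of A/C/G/T, got {base!r}")


@dataclass(frozen=True)
class CohortRecord:
    """One reported mosaic variant: carrier, gene, HGVS, label, and AAF."""

    record_id: str
    table: Table
    carrier: Carrier
    carrier_sex: Sex
    inheritance_category: Inheritance
    gene: str
    transcript: str
    cdna_hgvs: str
    protein_hgvs: Optional[str]
    classification: Classification
    aaf_percent: Optional[float]
    aaf_method: AafMethod

    def __post_init__(self) -> None:
        if self.aaf_percent is not None and not 0.0 < self.aaf_percent <= 100.0:
            raise ValueError(
                f"{self.record_id}: aaf_percent must lie in (0, 100], "
                f"got {self.aaf_percent}"
            )
        if (self.carrier is Carrier.PROBAND) != (self.table is Table.PROBAND):
            raise ValueError(
                f"{self.record_id}: carrier=proband iff table=proband "
                f"(carrier={self.carrier.value}, table={self.table.value})"
            )

    @property
    def aaf_fraction(self) -> Optional[float]:
        return None if self.aaf_percent is None else self.aaf_percent / 100.0


class FixtureError(ValueError):
    """Raised when the cohort table cannot be parsed or validated."""


_COLUMNS = [
    "record_id",
    "table",
    "carrier",
    "carrier_sex",
    "inheritance_category",
    "gene",
    "transcript",
    "cdna_hgvs",
    "protein_hgvs",
    "classification",
    "aaf_percent",
    "aaf_method",
]

_MISSING = {"", "."}


def builtin_fixture_path() -> Path:
    """Filesystem path of the bundled cohort table."""
    return Path(str(resources.files("mosascan").joinpath("data/cohort_tables.tsv")))


def load_cohort_fixture(
    path: Union[str, Path, None] = None,
) -> list[CohortRecord]:
    """Load cohort records from ``path`` (default: the bundled fixture).

    Parameters
    ----------
    path:
        TSV file with the :class:`CohortRecord` column schema, or ``None``
        for the table shipped inside the package.

    Returns
    -------
    list of CohortRecord, in file order.

    Raises
    ------
    FixtureError
        On a malformed row (the error names the 1-based data row number),
        a wrong header, or a duplicate ``record_id``.
    """
    src = Path(path) if path is not None else builtin_fixture_path()
    records: list[CohortRecord] = []
    seen: set[str] = set()
    with open(src, encoding="utf-8", newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FixtureError(f"{src}: empty fixture file") from None
        if header != _COLUMNS:
            raise FixtureError(
                f"{src}: unexpected header {header!r}; expected {_COLUMNS!r}"
            )
        for row_number, row in enumerate(reader, start=1):
            if not row or row == [""]:
                continue
            if len(row) != len(_COLUMNS):
                raise FixtureError(
                    f"{src}: row {row_number}: expected {len(_COLUMNS)} "
                    f"columns, found {len(row)}"
                )
            fields = dict(zip(_COLUMNS, (value.strip() for value in row)))
            try:
                record = _parse_record(fields)
            except (ValueError, KeyError) as exc:
                raise FixtureError(f"{src}: row {row_number}: {exc}") from exc
            if record.record_id in seen:
                raise FixtureError(
                    f"{src}: row {row_number}: duplicate record_id "
                    f"{record.record_id!r}"
                )
            seen.add(record.record_id)
            records.append(record)
    return records


def _parse_record(fields: dict[str, str]) -> CohortRecord:
    aaf_raw = fields["aaf_percent"]
    protein_raw = fields["protein_hgvs"]
    return CohortRecord(
        record_id=fields["record_id"],
        table=Table(fields["table"]),
        carrier=Carrier(fields["carrier"]),
        carrier_sex=Sex(fields["carrier_sex"]),
        inheritance_category=Inheritance(fields["inheritance_category"]),
        gene=fields["gene"],
        transcript=fields["transcript"],
        cdna_hgvs=fields["cdna_hgvs"],
        protein_hgvs=None if protein_raw in _MISSING else protein_raw,
        classification=Classification(fields["classification"]),
        aaf_percent=None if aaf_raw in _MISSING else float(aaf_raw),
        aaf_method=AafMethod(fields["aaf_method"]),
    )


# --- HGVS consequence annotation -------------------------------------------

# Single-residue substitution, one- or three-letter amino-acid codes.
_AA = r"(?:[A-Z][a-z]{2}|[A-Z])"
_PROT_SUB = re.compile(rf"^({_AA})(\d+)({_AA})$")
_SUBSTITUTION = re.compile(r"^c\.[\d*]+(?:[+-]\d+)?[ACGT]>[ACGT]$")
_INTRONIC = re.compile(r"\d+[+-]\d+")
_CDNA_SPAN = re.compile(r"^c\.(\d+)(?:_(\d+))?(del|dup|delins|ins)([ACGT]*)$")
_MISSING_PROTEIN = {None, "", ".", "N/A", "n/a", "p.?", "-"}


def _normalize_protein(protein_hgvs: Optional[str]) -> Optional[str]:
    if protein_hgvs in _MISSING_PROTEIN:
        return None
    text = protein_hgvs.strip()
    if text in _MISSING_PROTEIN:
        return None
    if text.startswith("p."):
        text = text[2:]
    return text.strip("()")


def classify_consequence(
    cdna_hgvs: str, protein_hgvs: Optional[str] = None
) -> ConsequenceClass:
    """Map HGVS notation to a coarse consequence class.

    Protein notation takes precedence over the cDNA description: frameshift
    (``fs``) beats everything, a terminating change is nonsense, a
    single-residue exchange is missense, and a non-frameshifting
    del/dup/ins is an in-frame indel. Without protein notation, an
    intronic-offset position is a splice change, and a del/dup whose span
    is divisible by three is an in-frame indel. Unparseable input is
    logged and classified ``other`` — this function never raises.
    """
    try:
        protein = _normalize_protein(protein_hgvs)
        if protein:
            if "fs" in protein:
                return ConsequenceClass.FRAMESHIFT
            if protein.endswith("*") or protein.endswith("Ter"):
                return ConsequenceClass.NONSENSE
            match = _PROT_SUB.match(protein)
            if match:
                ref_aa, _, alt_aa = match.groups()
                if ref_aa == alt_aa:
                    return ConsequenceClass.OTHER
                return ConsequenceClass.MISSENSE
            if any(token in protein for token in ("del", "dup", "ins")):
                return ConsequenceClass.INFRAME_INDEL

        cdna = (cdna_hgvs or "").strip()
        if not cdna:
            raise ValueError("empty cDNA notation")
        position_part = cdna.split(">", 1)[0]
        if _INTRONIC.search(position_part):
            return ConsequenceClass.SPLICE
        span_match = _CDNA_SPAN.match(cdna)
        if span_match:
            start, end, kind, inserted = span_match.groups()
            span = int(end or start) - int(start) + 1
            if kind == "delins":
                net = span - len(inserted)
            elif kind == "ins":
                net = len(inserted)
            else:
                net = span
            if net % 3 == 0:
                return ConsequenceClass.INFRAME_INDEL
            return ConsequenceClass.FRAMESHIFT
        log.warning("unrecognized HGVS notation %r / %r", cdna_hgvs, protein_hgvs)
        return ConsequenceClass.OTHER
    except Exception:  # noqa: BLE001 - totality is part of the contract
        log.warning(
            "failed to classify HGVS notation %r / %r",
            cdna_hgvs,
            protein_hgvs,
            exc_info=True,
        )
        return ConsequenceClass.OTHER


def is_substitution(cdna_hgvs: str) -> bool:
    """True iff the cDNA notation denotes a single-nucleotide substitution.

    Intronic (splice-region) substitutions count; indels and unparseable
    notation do not (the latter with a warning, never an exception).
    """
    try:
        return bool(_SUBSTITUTION.match((cdna_hgvs or "").strip()))
    except Exception:  # noqa: BLE001
        log.warning("failed to parse cDNA notation %r", cdna_hgvs, exc_info=True)
        return False


def substitution_alleles(cdna_hgvs: str) -> Optional[tuple[str, str]]:
    """(ref, alt) bases of a substitution notation, or None."""
    text = (cdna_hgvs or "").strip()
    if not _SUBSTITUTION.match(text):
        return None
    ref, alt = text[-3], text[-1]
    return ref, alt


def is_cpg_site(context: SequenceContext, alt_base: str) -> bool:
    """True iff the substituted reference base sits in a CpG dinucleotide.

    Either the reference C is directly followed by G, or the reference G is
    directly preceded by C (the reverse-strand CpG).
    """
    if alt_base not in _BASES:
        raise ValueError(f"alt_base must be one of A/C/G/T, got {alt_base!r}")
    if context.ref_base == "C" and context.three_prime == "G":
        return True
    if context.ref_base == "G" and context.five_prime == "C":
        return True
    return False
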