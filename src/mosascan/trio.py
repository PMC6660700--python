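"""Inheritance origin assignment for proband variants from trio read counts."""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Optional

from .caller import (
    CANDIDATE_STATUSES,
    CallStatus,
    ChromClass,
    MosaicCall,
    ThresholdPolicy,
    classify_observation,
)
from .cohort import Sex

__all__ = [
    "Origin",
    "OriginCall",
    "SampleCounts",
    "TrioObservation",
    "assign_origin",
    "flag_aaf_inconsistency",
]


class Origin(str, Enum):
    DE_NOVO = "de_novo"
    INHERITED_MATERNAL = "inherited_maternal"
    INHERITED_PATERNAL = "inherited_paternal"
    PARENTAL_MOSAIC_MATERNAL = "parental_mosaic_maternal"
    PARENTAL_MOSAIC_PATERNAL = "parental_mosaic_paternal"
    INCOMPLETE_TRIO = "incomplete_trio"
    AMBIGUOUS = "ambiguous"


_INHERITED = frozenset({Origin.INHERITED_MATERNAL, Origin.INHERITED_PATERNAL})


@dataclass(frozen=True)
class SampleCounts:
    """Read support of one individual at one site."""

    alt_reads: int
    total_reads: int
    sex: Sex


@dataclass(frozen=True)
class TrioObservation:
    """Proband read support plus whichever parental samples exist.

    An unavailable parent is ``None`` — never a zero-read stand-in, since
    absence of data and absence of the allele must stay distinguishable.
    """

    proband: SampleCounts
    mother: Optional[SampleCounts] = None
    father: Optional[SampleCounts] = None
    chrom_class: ChromClass = ChromClass.AUTOSOME


@dataclass(frozen=True)
class OriginCall:
    origin: Origin
    upd_suspicion: bool = False
    notes: str = ""

    def __post_init__(self) -> None:
        if self.upd_suspicion and self.origin not in _INHERITED:
            raise ValueError("upd_suspicion is only meaningful for inherited origins")


def _parent_verdict(
    parent: SampleCounts,
    chrom_class: ChromClass,
    policy: ThresholdPolicy,
    inherited: Origin,
    mosaic: Origin,
) -> tuple[Origin, str]:
    """Map a variant-positive parent's classification to an origin."""
    effective = policy
    note = ""
    if parent.total_reads < policy.min_depth:
        # The allele is demonstrably present; classify on the point AAF
        # but record that parental depth was below the reporting floor.
        effective = replace(policy, min_depth=1)
        note = "parental depth below min_depth; "
    call = classify_observation(
        parent.alt_reads, parent.total_reads, parent.sex, chrom_class, effective
    )
    if call.status in (CallStatus.CONSISTENT_HET, CallStatus.CONSISTENT_HEMI):
        return inherited, note + "parent consistent with constitutional carrier"
    if call.status in CANDIDATE_STATUSES or call.status is CallStatus.BELOW_DETECTION:
        return mosaic, note + f"parent AAF {call.aaf.value:.3f} in mosaic range"
    return Origin.AMBIGUOUS, note + f"parent classification {call.status.value}"


def assign_origin(
    trio: TrioObservation,
    policy: ThresholdPolicy = ThresholdPolicy(),
    presence_min_reads: int = 3,
) -> OriginCall:
    """Assign the inheritance origin of a proband variant.

    A parent carries the variant when at least ``presence_min_reads``
    alternate reads support it. Absent from every available parent of a
    complete trio, the variant is de novo; with a parent missing it can
    only be called ``incomplete_trio``. A variant-positive parent yields
    ``inherited_*`` when their own classification is consistent with a
    constitutional carrier and ``parental_mosaic_*`` when it is in the
    mosaic range; presence in both parents is ``ambiguous``.
    """
    if trio.proband.total_reads < policy.min_depth:
        raise ValueError(
            "proband observation below min_depth; origin assignment requires "
            f"at least {policy.min_depth} reads"
        )
    mother, father = trio.mother, trio.father
    mother_has = mother is not None and mother.alt_reads >= presence_min_reads
    father_has = father is not None and father.alt_reads >= presence_min_reads

    if mother_has and father_has:
        return OriginCall(
            Origin.AMBIGUOUS, notes="variant present in both parents"
        )
    if mother_has:
        origin, notes = _parent_verdict(
            mother,
            trio.chrom_class,
            policy,
            Origin.INHERITED_MATERNAL,
            Origin.PARENTAL_MOSAIC_MATERNAL,
        )
        return OriginCall(origin, notes=notes)
    if father_has:
        origin, notes = _parent_verdict(
            father,
            trio.chrom_class,
            policy,
            Origin.INHERITED_PATERNAL,
            Origin.PARENTAL_MOSAIC_PATERNAL,
        )
        return OriginCall(origin, notes=notes)

    if mother is not None and father is not None:
        return OriginCall(
            Origin.DE_NOVO, notes="variant absent from both parental samples"
        )
    available = "mother" if mother is not None else "father" if father is not None else "none"
    return OriginCall(
        Origin.INCOMPLETE_TRIO,
        notes=f"parental sample(s) missing (available: {available})",
    )


def flag_aaf_inconsistency(
    proband_call: MosaicCall, origin: OriginCall
) -> OriginCall:
    """Raise the UPD/AOH suspicion flag on anomalous inherited variants.

    An inherited variant whose proband AAF sits in the mosaic range (far
    below or above the heterozygous band) suggests underlying uniparental
    disomy or absence of heterozygosity rather than true SNV mosaicism;
    the note recommends orthogonal SNP-array review.
    """
    if origin.origin in _INHERITED and proband_call.status in (
        CallStatus.CANDIDATE_MOSAIC_LOW,
        CallStatus.CANDIDATE_MOSAIC_HIGH,
    ):
        note = (
            "inherited variant with mosaic-range proband AAF "
            f"({proband_call.aaf.value:.3f}); recommend SNP-array AOH/UPD review"
        )
        combined = f"{origin.notes}; {note}" if origin.notes else note
        return OriginCall(origin.origin, upd_suspicion=True, notes=combined)
    return origin
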