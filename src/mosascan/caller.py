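"""Allele-fraction estimation and mosaicism classification.

A diploid site (autosome, or X in a female) whose alternate allele fraction
(AAF) falls strictly below ``het_lower`` or strictly above ``het_upper`` is
a mosaic candidate; a hemizygous site (non-pseudoautosomal X in a male) is a
mosaic candidate for any AAF between ``hemi_min`` and ``hemi_upper``
inclusive. The default 0.36/0.64 heterozygote bounds coincide with a normal
binomial confidence interval around 0.5 at roughly 48x depth; the
``depth_adaptive`` mode re-derives them per site from an exact binomial
tail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Iterator, Mapping, Optional, Sequence

from scipy import stats

from .cohort import Sex

__all__ = [
    "AafEstimate",
    "ThresholdPolicy",
    "ThresholdMode",
    "CallStatus",
    "PloidyContext",
    "ChromClass",
    "MosaicCall",
    "compute_aaf",
    "derive_het_thresholds",
    "classify_chrom",
    "classify_observation",
    "concordance",
    "filter_common",
    "CANDIDATE_STATUSES",
]


class ThresholdMode(str, Enum):
    FIXED = "fixed"
    DEPTH_ADAPTIVE = "depth_adaptive"


class CallStatus(str, Enum):
    CONSISTENT_HET = "consistent_het"
    CANDIDATE_MOSAIC_LOW = "candidate_mosaic_low"
    CANDIDATE_MOSAIC_HIGH = "candidate_mosaic_high"
    CANDIDATE_MOSAIC_HEMI = "candidate_mosaic_hemi"
    CONSISTENT_HEMI = "consistent_hemi"
    BELOW_DETECTION = "below_detection"
    INSUFFICIENT_DEPTH = "insufficient_depth"
    # Not a classification: X_nonPAR observation with unknown sex.
    UNCALLABLE = "uncallable"


CANDIDATE_STATUSES = frozenset(
    {
        CallStatus.CANDIDATE_MOSAIC_LOW,
        CallStatus.CANDIDATE_MOSAIC_HIGH,
        CallStatus.CANDIDATE_MOSAIC_HEMI,
    }
)


class PloidyContext(str, Enum):
    DIPLOID = "diploid"
    HEMIZYGOUS = "hemizygous"


class ChromClass(str, Enum):
    AUTOSOME = "autosome"
    X_NONPAR = "X_nonPAR"
    OTHER = "other"


@dataclass(frozen=True)
class AafEstimate:
    """Point estimate and exact binomial CI of the alternate allele fraction."""

    value: float
    ci_low: float
    ci_high: float
    alt_reads: int
    total_reads: int
    method: str = "exome"

    def __post_init__(self) -> None:
        if not 0.0 <= self.ci_low <= self.value <= self.ci_high <= 1.0:
            raise ValueError(
                f"CI ordering violated: {self.ci_low} <= {self.value} "
                f"<= {self.ci_high}"
            )


# GRCh37 pseudoautosomal regions on X, 1-based inclusive.
GRCH37_X_PAR: tuple[tuple[int, int], ...] = (
    (60001, 2_699_520),
    (154_931_044, 155_260_560),
)


@dataclass(frozen=True)
class ThresholdPolicy:
    """Reporting thresholds for mosaic candidate selection."""

    het_lower: float = 0.36
    het_upper: float = 0.64
    hemi_min: float = 0.10
    hemi_upper: float = 0.90
    min_depth: int = 20
    alpha: float = 0.05
    mode: ThresholdMode = ThresholdMode.FIXED
    par_regions: tuple[tuple[int, int], ...] = GRCH37_X_PAR

    def __post_init__(self) -> None:
        if not 0.0 < self.het_lower < 0.5 < self.het_upper < 1.0:
            raise ValueError(
                f"require 0 < het_lower < 0.5 < het_upper < 1, got "
                f"({self.het_lower}, {self.het_upper})"
            )
        if not self.hemi_min < self.hemi_upper:
            raise ValueError("hemi_min must be below hemi_upper")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class MosaicCall:
    status: CallStatus
    aaf: AafEstimate
    ploidy_context: PloidyContext


def compute_aaf(
    alt_reads: int,
    total_reads: int,
    alpha: float = 0.05,
    method: str = "exome",
) -> AafEstimate:
    """Exact AAF with a Clopper-Pearson interval at level ``1 - alpha``."""
    if total_reads < 1:
        raise ValueError(f"total_reads must be >= 1, got {total_reads}")
    if not 0 <= alt_reads <= total_reads:
        raise ValueError(
            f"alt_reads must lie in [0, total_reads], got "
            f"{alt_reads}/{total_reads}"
        )
    value = alt_reads / total_reads
    if alt_reads == 0:
        ci_low = 0.0
    else:
        ci_low = float(stats.beta.ppf(alpha / 2, alt_reads, total_reads - alt_reads + 1))
    if alt_reads == total_reads:
        ci_high = 1.0
    else:
        ci_high = float(
            stats.beta.ppf(1 - alpha / 2, alt_reads + 1, total_reads - alt_reads)
        )
    return AafEstimate(
        value=value,
        ci_low=min(ci_low, value),
        ci_high=max(ci_high, value),
        alt_reads=alt_reads,
        total_reads=total_reads,
        method=method,
    )


def derive_het_thresholds(
    depth: int, alpha: float = 0.05, method: str = "normal"
) -> tuple[float, float]:
    """Symmetric AAF bounds outside which a true heterozygote is improbable.

    ``normal`` returns ``0.5 +/- z(1 - alpha/2) * 0.5 / sqrt(depth)``.
    ``exact`` returns the widest symmetric pair of read-count cutoffs whose
    combined binomial(depth, 0.5) tail mass stays at or below ``alpha``;
    discreteness makes the exact interval non-monotone at single-read depth
    increments, but it narrows over any doubling of depth.
    """
    if depth < 1:
        raise ValueError(f"depth must be >= 1, got {depth}")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if method == "normal":
        half_width = stats.norm.ppf(1 - alpha / 2) * 0.5 / math.sqrt(depth)
        lower = max(0.0, 0.5 - half_width)
        return lower, 1.0 - lower
    if method == "exact":
        # Largest k with P(X < k) + P(X > depth - k) <= alpha, X ~ Bin(d, 1/2).
        best = 0
        for k in range(1, depth // 2 + 1):
            if 2.0 * stats.binom.cdf(k - 1, depth, 0.5) <= alpha:
                best = k
            else:
                break
        lower = best / depth
        return lower, 1.0 - lower
    raise ValueError(f"unknown method {method!r}; expected 'normal' or 'exact'")


def classify_chrom(
    chrom: str,
    pos: int,
    par_regions: Sequence[tuple[int, int]] = GRCH37_X_PAR,
) -> ChromClass:
    """Coarse locus class: autosome, non-PAR X, or other.

    Pseudoautosomal X positions are reported as ``autosome`` because they
    are diploid in both sexes.
    """
    name = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if name.isdigit() and 1 <= int(name) <= 22:
        return ChromClass.AUTOSOME
    if name.upper() == "X":
        for start, end in par_regions:
            if start <= pos <= end:
                return ChromClass.AUTOSOME
        return ChromClass.X_NONPAR
    return ChromClass.OTHER


def classify_observation(
    alt_reads: int,
    total_reads: int,
    sex: Sex,
    chrom_class: ChromClass,
    policy: ThresholdPolicy = ThresholdPolicy(),
) -> MosaicCall:
    """Classify one sample's read support at one site against ``policy``.

    Pure in its inputs: the verdict depends only on the read counts, the
    carrier sex, and the locus class. Strict inequalities are used at the
    diploid thresholds (an AAF exactly at ``het_lower`` is still consistent
    with heterozygosity); the hemizygous band is inclusive at both ends.
    """
    aaf = compute_aaf(alt_reads, total_reads, alpha=policy.alpha)
    hemizygous = chrom_class is ChromClass.X_NONPAR and sex is Sex.MALE
    context = PloidyContext.HEMIZYGOUS if hemizygous else PloidyContext.DIPLOID

    if total_reads < policy.min_depth:
        return MosaicCall(CallStatus.INSUFFICIENT_DEPTH, aaf, context)
    if chrom_class is ChromClass.X_NONPAR and sex is Sex.UNKNOWN:
        return MosaicCall(CallStatus.UNCALLABLE, aaf, PloidyContext.DIPLOID)

    if hemizygous:
        if aaf.value < policy.hemi_min:
            status = CallStatus.BELOW_DETECTION
        elif aaf.value > policy.hemi_upper:
            status = CallStatus.CONSISTENT_HEMI
        else:
            status = CallStatus.CANDIDATE_MOSAIC_HEMI
        return MosaicCall(status, aaf, context)

    lower, upper = policy.het_lower, policy.het_upper
    if policy.mode is ThresholdMode.DEPTH_ADAPTIVE:
        lower, upper = derive_het_thresholds(total_reads, policy.alpha, "exact")
    if aaf.value < lower:
        status = CallStatus.CANDIDATE_MOSAIC_LOW
    elif aaf.value > upper:
        status = CallStatus.CANDIDATE_MOSAIC_HIGH
    else:
        status = CallStatus.CONSISTENT_HET
    return MosaicCall(status, aaf, context)


def concordance(
    aaf_primary: Sequence[float], aaf_orthogonal: Sequence[float]
) -> float:
    """Spearman rank correlation between paired AAF measurements."""
    if len(aaf_primary) != len(aaf_orthogonal):
        raise ValueError("paired AAF lists must have equal length")
    if len(aaf_primary) < 3:
        raise ValueError("need at least 3 paired observations")
    rho = stats.spearmanr(aaf_primary, aaf_orthogonal).statistic
    return float(rho)


def filter_common(
    records: Iterable,
    population_af: Mapping,
    threshold: float = 0.01,
    locus_key=lambda record: record.locus,
) -> Iterator:
    """Drop records whose population allele frequency reaches ``threshold``.

    Records absent from the frequency map are kept (and logged); the
    classifier should not discard a variant merely for lacking annotation.
    """
    import logging

    log = logging.getLogger(__name__)
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    for record in records:
        locus = locus_key(record)
        frequency = population_af.get(locus)
        if frequency is None:
            log.info("no population frequency for %s; keeping record", locus)
            yield record
        elif frequency < threshold:
            yield record
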