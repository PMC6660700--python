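"""Cohort-level summary statistics over reported mosaic variant records.

Group conventions: ``male_X`` collects records carried by males in the
X-linked category (hemizygous context, where mosaic AAFs run higher);
``diploid`` is everyone else. The printed category labels of the bundled
tables are authoritative for grouping. Records without an AAF are excluded
from means and their exclusion is logged.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats as scipy_stats

from .cohort import (
    Carrier,
    Classification,
    CohortRecord,
    ConsequenceClass,
    Inheritance,
    SequenceContext,
    Sex,
    Table,
    classify_consequence,
    is_cpg_site,
    is_substitution,
    substitution_alleles,
)

log = logging.getLogger(__name__)

__all__ = [
    "round_percent",
    "GroupStats",
    "GroupComparison",
    "SummaryReport",
    "RAS_PI3K_AKT_MTOR_GENES",
    "DEFAULT_COHORT_SIZE",
    "DEFAULT_DIAGNOSTIC_YIELD",
    "summarize",
    "recurrent_genes",
    "pathway_burden",
    "compare_groups",
    "attribution_rates",
]

# Six genes of the Ras / PI3K-AKT-mTOR signaling pathway hit in probands.
RAS_PI3K_AKT_MTOR_GENES = frozenset(
    {"BRAF", "NF1", "HRAS", "KRAS", "PIK3CA", "MTOR"}
)

DEFAULT_COHORT_SIZE = 11_992
DEFAULT_DIAGNOSTIC_YIELD = 0.25


def round_percent(value: float, ndigits: int = 1) -> float:
    """Display rounding for percentages: half-to-even at ``ndigits`` decimals.

    Uses decimal arithmetic so that exact halves (e.g. 34.85) round
    predictably instead of following binary floating-point noise.
    """
    from decimal import ROUND_HALF_EVEN, Decimal

    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_EVEN))


@dataclass(frozen=True)
class GroupStats:
    mean: float
    sd: float
    minimum: float
    maximum: float
    n: int


@dataclass(frozen=True)
class GroupComparison:
    group_a_mean: float
    group_b_mean: float
    statistic: float
    p_value: float
    method: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value outside [0, 1]: {self.p_value}")


@dataclass
class SummaryReport:
    n_total: int
    n_proband: int
    n_parental: int
    n_genes: int
    counts_by_inheritance: dict[str, int]
    counts_by_classification: dict[str, int]
    counts_by_consequence: dict[str, int]
    n_substitutions: int
    n_cpg: Optional[int]
    recurrent_genes: dict[str, int]
    recurrent_variant_total: int
    mean_aaf_by_group: dict[str, GroupStats]
    pathway_burden: tuple[int, int, float]
    rates: dict[str, float]
    excluded_from_means: list[str] = field(default_factory=list)


def _is_male_x(record: CohortRecord) -> bool:
    return (
        record.carrier_sex is Sex.MALE
        and record.inheritance_category is Inheritance.XL
    )


def _group_stats(values: Sequence[float]) -> GroupStats:
    arr = np.asarray(values, dtype=float)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return GroupStats(
        mean=float(arr.mean()),
        sd=sd,
        minimum=float(arr.min()),
        maximum=float(arr.max()),
        n=int(arr.size),
    )


def summarize(
    records: Sequence[CohortRecord],
    contexts: Optional[Mapping[str, SequenceContext]] = None,
) -> SummaryReport:
    """Compute every cohort aggregate from a list of records.

    ``contexts`` optionally maps ``record_id`` to the sequence context of a
    substitution record, enabling the CpG-site count; without it ``n_cpg``
    is ``None``.
    """
    if not records:
        raise ValueError("records must be non-empty")

    by_inheritance = Counter(r.inheritance_category.value for r in records)
    by_classification = Counter(r.classification.value for r in records)
    by_consequence = Counter(
        classify_consequence(r.cdna_hgvs, r.protein_hgvs).value for r in records
    )
    n_substitutions = sum(1 for r in records if is_substitution(r.cdna_hgvs))

    n_cpg: Optional[int] = None
    if contexts is not None:
        n_cpg = 0
        for record in records:
            context = contexts.get(record.record_id)
            alleles = substitution_alleles(record.cdna_hgvs)
            if context is None or alleles is None:
                continue
            if is_cpg_site(context, alleles[1]):
                n_cpg += 1

    recurrent, recurrent_total = recurrent_genes(records)

    excluded = [r.record_id for r in records if r.aaf_percent is None]
    if excluded:
        log.info(
            "excluding %d record(s) without AAF from group means: %s",
            len(excluded),
            ", ".join(excluded),
        )

    groups: dict[str, list[float]] = {
        "male_X": [],
        "diploid": [],
        "proband_male_X": [],
        "proband_diploid": [],
        "parental_diploid": [],
    }
    for record in records:
        aaf = record.aaf_percent
        if aaf is None:
            continue
        proband = record.table is Table.PROBAND
        if _is_male_x(record):
            groups["male_X"].append(aaf)
            if proband:
                groups["proband_male_X"].append(aaf)
        else:
            groups["diploid"].append(aaf)
            groups["proband_diploid" if proband else "parental_diploid"].append(aaf)
    mean_aaf_by_group = {
        name: _group_stats(values) for name, values in groups.items() if values
    }

    probands = [r for r in records if r.table is Table.PROBAND]
    burden = (
        pathway_burden(records)
        if probands
        else (0, 0, 0.0)
    )

    return SummaryReport(
        n_total=len(records),
        n_proband=len(probands),
        n_parental=sum(1 for r in records if r.table is Table.PARENTAL),
        n_genes=len({r.gene for r in records}),
        counts_by_inheritance=dict(by_inheritance),
        counts_by_classification=dict(by_classification),
        counts_by_consequence=dict(by_consequence),
        n_substitutions=n_substitutions,
        n_cpg=n_cpg,
        recurrent_genes=recurrent,
        recurrent_variant_total=recurrent_total,
        mean_aaf_by_group=mean_aaf_by_group,
        pathway_burden=burden,
        rates=attribution_rates(records),
        excluded_from_means=excluded,
    )


def recurrent_genes(
    records: Iterable[CohortRecord],
) -> tuple[dict[str, int], int]:
    """Genes with two or more mosaic events, and the variant total they cover."""
    counts = Counter(record.gene for record in records)
    recurrent = {gene: n for gene, n in counts.items() if n >= 2}
    return recurrent, sum(recurrent.values())


def pathway_burden(
    records: Sequence[CohortRecord],
    gene_set: frozenset[str] | set[str] = RAS_PI3K_AKT_MTOR_GENES,
    denominator_group: Callable[[CohortRecord], bool] = (
        lambda record: record.table is Table.PROBAND
    ),
) -> tuple[int, int, float]:
    """Fraction of a record group falling in a gene set."""
    if not gene_set:
        raise ValueError("gene_set must be non-empty")
    group = [record for record in records if denominator_group(record)]
    if not group:
        raise ValueError("denominator group is empty")
    hits = sum(1 for record in group if record.gene in gene_set)
    return hits, len(group), hits / len(group)


def compare_groups(
    a: Sequence[float], b: Sequence[float], method: str = "welch"
) -> GroupComparison:
    """Two-sample, two-sided t-test on AAF groups (Welch by default)."""
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if method not in ("welch", "student"):
        raise ValueError(f"unknown method {method!r}")
    arr_a = np.asarray(a, dtype=float)
    arr_b = np.asarray(b, dtype=float)
    constant_a = bool(np.ptp(arr_a) == 0.0)
    constant_b = bool(np.ptp(arr_b) == 0.0)
    if constant_a and constant_b:
        if arr_a[0] == arr_b[0]:
            raise ValueError(
                "both groups are constant with equal means; t-test undefined"
            )
        # Perfect separation between two constant groups.
        return GroupComparison(
            group_a_mean=float(arr_a.mean()),
            group_b_mean=float(arr_b.mean()),
            statistic=math.inf if arr_a.mean() > arr_b.mean() else -math.inf,
            p_value=0.0,
            method=method,
        )
    result = scipy_stats.ttest_ind(arr_a, arr_b, equal_var=(method == "student"))
    return GroupComparison(
        group_a_mean=float(arr_a.mean()),
        group_b_mean=float(arr_b.mean()),
        statistic=float(result.statistic),
        p_value=float(result.pvalue),
        method=method,
    )


def attribution_rates(
    records: Sequence[CohortRecord],
    cohort_size: int = DEFAULT_COHORT_SIZE,
    diagnostic_yield: float = DEFAULT_DIAGNOSTIC_YIELD,
) -> dict[str, float]:
    """Cohort-level attribution fractions.

    ``parental_rate`` is the share of referred families in which a parental
    mosaic variant was reported; ``diagnosis_fraction`` is the share of all
    molecular diagnoses (cohort size times diagnostic yield) attributable
    to a proband mosaic P/LP variant.
    """
    if cohort_size < 1:
        raise ValueError("cohort_size must be >= 1")
    if not 0.0 < diagnostic_yield <= 1.0:
        raise ValueError("diagnostic_yield must lie in (0, 1]")
    n_parental = sum(1 for r in records if r.table is Table.PARENTAL)
    n_proband_plp = sum(
        1
        for r in records
        if r.table is Table.PROBAND and r.classification is not Classification.VOUS
    )
    return {
        "parental_rate": n_parental / cohort_size,
        "diagnosis_fraction": n_proband_plp / (diagnostic_yield * cohort_size),
    }
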