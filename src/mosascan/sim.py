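"""Read-count-level simulation: AAF sampling, threshold operating
characteristics, and synthetic trio cohorts with planted truth.

Alternate read counts are binomial draws at an error-adjusted success
probability ``f' = f(1-e) + (1-f)e/3`` (a wrong base call lands on the
specific alternate allele one third of the time). Per-sample depths follow
a negative binomial around the configured mean, truncated at the minimum.
Alignment bias against particular mutation classes is represented by a
parametric per-class read-dropout probability (zero by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .caller import (
    CANDIDATE_STATUSES,
    ChromClass,
    ThresholdPolicy,
    classify_observation,
)
from .cohort import Sex

log = logging.getLogger(__name__)

__all__ = [
    "DepthModel",
    "SimulationConfig",
    "OperatingPoint",
    "PlantedVariant",
    "SimulatedCohort",
    "effective_fraction",
    "sample_read_counts",
    "sample_depths",
    "operating_characteristics",
    "het_aaf_distribution",
    "aaf_histogram",
    "generate_trio_cohort",
    "random_planted_cohort",
    "TRIO_SAMPLES",
]

ROLES = ("proband", "mother", "father")
TRIO_SAMPLES = {"proband": "SIM-P1", "mother": "SIM-M1", "father": "SIM-F1"}


@dataclass(frozen=True)
class DepthModel:
    """Negative-binomial per-sample depth around ``mean``, floored at ``minimum``."""

    mean: int = 130
    minimum: int = 20
    dispersion: float = 30.0

    def __post_init__(self) -> None:
        if self.mean < 1 or self.minimum < 1:
            raise ValueError("depth mean and minimum must be >= 1")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    depth: DepthModel = DepthModel()
    error_rate: float = 0.001
    n_variants: int = 1000
    true_fractions: tuple[float, ...] = (0.05, 0.10, 0.18, 0.30, 0.40, 0.50)
    seed: int = 1
    dropout_bias: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must lie in [0, 1)")
        for label, bias in self.dropout_bias.items():
            if not 0.0 <= bias <= 1.0:
                raise ValueError(f"dropout_bias[{label!r}] outside [0, 1]")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def effective_fraction(true_fraction: float, error_rate: float) -> float:
    """Success probability of an alternate read given the true cell fraction."""
    return true_fraction * (1 - error_rate) + (1 - true_fraction) * error_rate / 3


def sample_read_counts(
    true_fraction: float,
    depth: int,
    error_rate: float,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """One binomial draw of (alt_reads, total_reads) at the given site."""
    if not 0.0 <= true_fraction <= 1.0:
        raise ValueError("true_fraction must lie in [0, 1]")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    p = effective_fraction(true_fraction, error_rate)
    return int(rng.binomial(depth, p)), depth


def sample_depths(
    rng: np.random.Generator, n: int, model: DepthModel = DepthModel()
) -> np.ndarray:
    """Draw ``n`` per-sample depths; values below the floor are clamped up."""
    p = model.dispersion / (model.dispersion + model.mean)
    depths = rng.negative_binomial(model.dispersion, p, size=n)
    return np.maximum(depths, model.minimum)


@dataclass(frozen=True)
class OperatingPoint:
    true_fraction: float
    depth: int
    n_reps: int
    p_flagged: float
    mc_stderr: float


def operating_characteristics(
    config: SimulationConfig,
    policy: ThresholdPolicy = ThresholdPolicy(),
    context: str = "diploid",
    depths: Sequence[int] = (20, 40, 130),
    n_reps: int = 10_000,
) -> list[OperatingPoint]:
    """Monte-Carlo flag probability on a (true fraction x depth) grid.

    Each replicate is classified through :func:`classify_observation`, so
    the estimate reflects the production classification path exactly; the
    per-cell work is linear in depth because replicates sharing an
    alternate read count share a verdict.
    """
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100")
    if context == "diploid":
        sex, chrom_class = Sex.FEMALE, ChromClass.AUTOSOME
    elif context == "hemizygous":
        sex, chrom_class = Sex.MALE, ChromClass.X_NONPAR
    else:
        raise ValueError(f"unknown context {context!r}")
    rng = config.rng()
    points: list[OperatingPoint] = []
    for fraction in config.true_fractions:
        p_eff = effective_fraction(fraction, config.error_rate)
        for depth in depths:
            alts = rng.binomial(depth, p_eff, size=n_reps)
            counts = np.bincount(alts, minlength=depth + 1)
            flagged = 0
            for alt in np.flatnonzero(counts):
                call = classify_observation(
                    int(alt), depth, sex, chrom_class, policy
                )
                if call.status in CANDIDATE_STATUSES:
                    flagged += int(counts[alt])
            p_hat = flagged / n_reps
            points.append(
                OperatingPoint(
                    true_fraction=fraction,
                    depth=int(depth),
                    n_reps=n_reps,
                    p_flagged=p_hat,
                    mc_stderr=float(np.sqrt(p_hat * (1 - p_hat) / n_reps)),
                )
            )
    return points


def het_aaf_distribution(
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> dict[str, np.ndarray]:
    """Simulated AAF draws for heterozygous sites, per mutation class.

    The baseline class ``snv`` has no dropout; every entry of
    ``config.dropout_bias`` adds a class whose alternate-supporting reads
    are each lost with the given probability, thinning the observed AAF to
    an expectation of ``f(1-b) / (1-fb)``.
    """
    if rng is None:
        rng = config.rng()
    classes = {"snv": 0.0}
    classes.update(config.dropout_bias)
    out: dict[str, np.ndarray] = {}
    for label, bias in classes.items():
        n = config.n_variants
        if n == 0:
            out[label] = np.empty(0)
            continue
        depths = sample_depths(rng, n, config.depth)
        alts = rng.binomial(depths, effective_fraction(0.5, config.error_rate))
        if bias > 0.0:
            kept = rng.binomial(alts, 1.0 - bias)
            totals = depths - (alts - kept)
            alts = kept
        else:
            totals = depths
        out[label] = alts / totals
    return out


def aaf_histogram(
    values: np.ndarray, bin_width: float = 0.02
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of AAF values over [0, 1] with the given bin width."""
    n_bins = int(round(1.0 / bin_width))
    return np.histogram(values, bins=n_bins, range=(0.0, 1.0))


# --- synthetic trio cohorts -------------------------------------------------


@dataclass(frozen=True)
class PlantedVariant:
    """Ground truth for one simulated site.

    ``fractions`` maps roles (proband/mother/father) to planted true cell
    fractions; roles left out carry only sequencing error.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    context: str = "diploid"  # diploid | hemizygous
    fractions: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for role, fraction in self.fractions.items():
            if role not in ROLES:
                raise ValueError(f"unknown role {role!r}")
            if not 0.0 <= fraction <= 1.0:
                raise ValueError(f"fraction for {role} outside [0, 1]")
        if self.context not in ("diploid", "hemizygous"):
            raise ValueError(f"unknown context {self.context!r}")

    @property
    def locus(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


@dataclass(frozen=True)
class SimulatedCohort:
    vcf: Path
    ped: Path
    truth: Path


def _expected_origin(
    planted: PlantedVariant, policy: ThresholdPolicy
) -> tuple[str, bool]:
    """Origin and UPD-suspicion implied by the planted fractions."""
    mother = planted.fractions.get("mother", 0.0)
    father = planted.fractions.get("father", 0.0)
    proband = planted.fractions.get("proband", 0.0)
    if mother > 0.0 and father > 0.0:
        return "ambiguous", False
    if mother == 0.0 and father == 0.0:
        return "de_novo", False
    parent_label = "maternal" if mother > 0.0 else "paternal"
    parent_fraction = mother if mother > 0.0 else father
    if planted.context == "hemizygous" and parent_label == "paternal":
        constitutional = parent_fraction > policy.hemi_upper
    else:
        constitutional = policy.het_lower <= parent_fraction <= policy.het_upper
    if not constitutional:
        return f"parental_mosaic_{parent_label}", False
    upd = 0.0 < proband < policy.het_lower or proband > policy.het_upper
    return f"inherited_{parent_label}", upd


_VCF_HEADER = """##fileformat=VCFv4.2
##source=mosascan-simulator
##INFO=<ID=SIM,Number=0,Type=Flag,Description="Simulated site">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""


def generate_trio_cohort(
    config: SimulationConfig,
    planted: Sequence[PlantedVariant],
    out_dir: Path | str,
    policy: ThresholdPolicy = ThresholdPolicy(),
) -> SimulatedCohort:
    """Write a synthetic single-trio cohort: VCF 4.2, PED, and truth TSV.

    One trio (male proband) observed at every planted locus; read counts
    are drawn via :func:`sample_read_counts` at per-individual depths.
    The truth table records the planted fractions and the origin verdict
    they imply, for end-to-end recovery checks. Deterministic for a fixed
    ``config.seed``.
    """
    loci = [variant.locus for variant in planted]
    if len(set(loci)) != len(loci):
        raise ValueError("planted loci must be unique")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = config.rng()
    log.info("simulating trio cohort: %d sites, seed=%d", len(planted), config.seed)

    contigs = sorted(
        {variant.chrom for variant in planted},
        key=lambda c: (len(c), c),
    )
    vcf_path = out / "cohort.vcf"
    truth_path = out / "truth.tsv"
    ped_path = out / "cohort.ped"

    sample_order = [TRIO_SAMPLES[role] for role in ROLES]
    truth_rows = []
    with open(vcf_path, "w", encoding="utf-8") as vcf:
        vcf.write(_VCF_HEADER)
        for contig in contigs:
            vcf.write(f"##contig=<ID={contig}>\n")
        vcf.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_order)
            + "\n"
        )
        ordered = sorted(planted, key=lambda v: (contigs.index(v.chrom), v.pos))
        for variant in ordered:
            calls = []
            drawn: dict[str, tuple[int, int]] = {}
            for role in ROLES:
                depth = int(sample_depths(rng, 1, config.depth)[0])
                fraction = variant.fractions.get(role, 0.0)
                alt, total = sample_read_counts(
                    fraction, depth, config.error_rate, rng
                )
                drawn[role] = (alt, total)
                gt = "0/1" if alt > 0 else "0/0"
                calls.append(f"{gt}:{total - alt},{alt}:{total}")
            vcf.write(
                f"{variant.chrom}\t{variant.pos}\t.\t{variant.ref}\t"
                f"{variant.alt}\t.\tPASS\tSIM\tGT:AD:DP\t" + "\t".join(calls) + "\n"
            )
            origin, upd = _expected_origin(variant, policy)
            truth_rows.append(
                {
                    "chrom": variant.chrom,
                    "pos": variant.pos,
                    "ref": variant.ref,
                    "alt": variant.alt,
                    "context": variant.context,
                    "f_proband": variant.fractions.get("proband", 0.0),
                    "f_mother": variant.fractions.get("mother", 0.0),
                    "f_father": variant.fractions.get("father", 0.0),
                    "expected_origin": origin,
                    "expected_upd": upd,
                }
            )

    pd.DataFrame(truth_rows).to_csv(truth_path, sep="\t", index=False)

    proband, mother, father = (TRIO_SAMPLES[r] for r in ROLES)
    with open(ped_path, "w", encoding="utf-8") as ped:
        ped.write(f"SIMFAM\t{father}\t0\t0\t1\t1\n")
        ped.write(f"SIMFAM\t{mother}\t0\t0\t2\t1\n")
        ped.write(f"SIMFAM\t{proband}\t{father}\t{mother}\t1\t2\n")

    return SimulatedCohort(vcf=vcf_path, ped=ped_path, truth=truth_path)


_SCENARIOS = ("de_novo", "parental_mosaic", "inherited", "inherited_upd")


def random_planted_cohort(
    n_variants: int,
    rng: np.random.Generator,
    weights: Mapping[str, float] | None = None,
    mosaic_fraction_range: tuple[float, float] = (0.10, 0.35),
    upd_proband_range: tuple[float, float] = (0.10, 0.16),
) -> list[PlantedVariant]:
    """Random autosomal scenario mix for end-to-end recovery experiments.

    Scenarios: proband-only mosaic (de novo), low-fraction parental mosaic
    transmitted as heterozygous, constitutionally inherited heterozygote,
    and an inherited heterozygote whose proband fraction is planted in the
    mosaic range (the UPD/AOH signature).
    """
    if weights is None:
        weights = {
            "de_novo": 0.50,
            "parental_mosaic": 0.25,
            "inherited": 0.13,
            "inherited_upd": 0.12,
        }
    labels = list(_SCENARIOS)
    probs = np.array([weights.get(label, 0.0) for label in labels], dtype=float)
    probs /= probs.sum()
    lo, hi = mosaic_fraction_range
    planted: list[PlantedVariant] = []
    for index in range(n_variants):
        chrom = str(index % 22 + 1)
        pos = 100_000 + (index // 22 + 1) * 150
        scenario = labels[int(rng.choice(len(labels), p=probs))]
        parent = "mother" if rng.random() < 0.5 else "father"
        if scenario == "de_novo":
            fractions = {"proband": float(rng.uniform(lo, hi))}
        elif scenario == "parental_mosaic":
            fractions = {"proband": 0.5, parent: float(rng.uniform(lo, hi))}
        elif scenario == "inherited":
            fractions = {"proband": 0.5, parent: 0.5}
        else:  # inherited_upd
            fractions = {
                "proband": float(rng.uniform(*upd_proband_range)),
                parent: 0.5,
            }
        planted.append(
            PlantedVariant(
                chrom=chrom, pos=pos, ref="A", alt="G", fractions=fractions
            )
        )
    return planted
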