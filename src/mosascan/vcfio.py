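"""VCF/PED readers, call/report writers.

Coordinates are 1-based inclusive throughout (VCF convention).
Multi-allelic sites are decomposed into one observation per alternate
allele, each carrying that alternate's AD against the site's total depth.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Union

import pysam

from .cohort import Sex
from .stats import GroupStats, SummaryReport
from .trio import SampleCounts, TrioObservation
from .caller import ChromClass, MosaicCall, classify_chrom

log = logging.getLogger(__name__)

__all__ = [
    "PedRecord",
    "VariantObservation",
    "read_ped",
    "read_vcf_observations",
    "build_trios",
    "write_calls_tsv",
    "write_report",
    "read_report",
]

_PED_SEX = {"1": Sex.MALE, "2": Sex.FEMALE}


@dataclass(frozen=True)
class PedRecord:
    family_id: str
    sample_id: str
    father_id: Optional[str]
    mother_id: Optional[str]
    sex: Sex
    phenotype: str


@dataclass(frozen=True)
class VariantObservation:
    """One sample's read support for one alternate allele at one site."""

    sample: str
    chrom: str
    pos: int
    ref: str
    alt: str
    alt_reads: int
    total_reads: int
    sex: Sex
    family_id: str
    father_id: Optional[str] = None
    mother_id: Optional[str] = None

    @property
    def locus(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def chrom_class(self) -> ChromClass:
        return classify_chrom(self.chrom, self.pos)


def read_ped(path: Union[str, Path]) -> dict[str, PedRecord]:
    """Parse a 6-column PED file into records keyed by sample id."""
    records: dict[str, PedRecord] = {}
    with open(path, encoding="utf-8") as handle:
        for line_number, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ValueError(
                    f"{path}: line {line_number}: expected 6 PED columns, "
                    f"found {len(fields)}"
                )
            family, sample, father, mother, sex_code, phenotype = fields[:6]
            records[sample] = PedRecord(
                family_id=family,
                sample_id=sample,
                father_id=None if father == "0" else father,
                mother_id=None if mother == "0" else mother,
                sex=_PED_SEX.get(sex_code, Sex.UNKNOWN),
                phenotype=phenotype,
            )
    return records


def read_vcf_observations(
    vcf_path: Union[str, Path],
    ped_path: Union[str, Path],
) -> list[VariantObservation]:
    """Per-sample, per-alternate observations from a VCF plus pedigree.

    Every VCF sample must appear in the PED file; a mismatch is fatal and
    names the offending samples. Sites where a sample lacks AD are skipped
    for that sample with a log line, unless the AD can be reconstructed
    from DP and a single-ALT AF (logged as inferred).
    """
    ped = read_ped(ped_path)
    observations: list[VariantObservation] = []
    with pysam.VariantFile(str(vcf_path)) as vcf:
        samples = list(vcf.header.samples)
        missing = sorted(set(samples) - set(ped))
        if missing:
            raise ValueError(
                "VCF samples absent from PED file: " + ", ".join(missing)
            )
        for record in vcf:
            alts = record.alts or ()
            for sample in samples:
                call = record.samples[sample]
                ad = call.get("AD")
                if ad is None or any(depth is None for depth in ad):
                    ad = _reconstruct_ad(record, call, alts)
                    if ad is None:
                        log.info(
                            "skipping %s at %s:%d (no AD)",
                            sample,
                            record.chrom,
                            record.pos,
                        )
                        continue
                total = int(sum(ad))
                if total == 0:
                    log.info(
                        "skipping %s at %s:%d (zero depth)",
                        sample,
                        record.chrom,
                        record.pos,
                    )
                    continue
                info = ped[sample]
                for alt_index, alt in enumerate(alts, start=1):
                    observations.append(
                        VariantObservation(
                            sample=sample,
                            chrom=record.chrom,
                            pos=record.pos,
                            ref=record.ref,
                            alt=alt,
                            alt_reads=int(ad[alt_index]),
                            total_reads=total,
                            sex=info.sex,
                            family_id=info.family_id,
                            father_id=info.father_id,
                            mother_id=info.mother_id,
                        )
                    )
    return observations


def _reconstruct_ad(record, call, alts) -> Optional[tuple[int, ...]]:
    """Infer (ref, alt) depths from DP and a single-ALT AF when AD is absent."""
    dp = call.get("DP")
    af = record.info.get("AF") if "AF" in record.info else None
    if dp is None or af is None or len(alts) != 1:
        return None
    frequency = af[0] if isinstance(af, tuple) else af
    alt_reads = int(round(float(frequency) * int(dp)))
    log.info(
        "inferred AD from DP*AF at %s:%d (DP=%d, AF=%.4f)",
        record.chrom,
        record.pos,
        int(dp),
        float(frequency),
    )
    return (int(dp) - alt_reads, alt_reads)


def build_trios(
    observations: Iterable[VariantObservation],
) -> list[tuple[VariantObservation, TrioObservation]]:
    """Group observations into per-proband trio observations by locus.

    A proband is any sample with at least one parent id in the pedigree.
    A parent without an observation at a locus is recorded as unavailable.
    """
    by_locus_sample: dict[tuple, dict[str, VariantObservation]] = {}
    probands: dict[str, VariantObservation] = {}
    for obs in observations:
        by_locus_sample.setdefault(obs.locus, {})[obs.sample] = obs
        if obs.father_id or obs.mother_id:
            probands[obs.sample] = obs
    trios: list[tuple[VariantObservation, TrioObservation]] = []
    for locus in sorted(by_locus_sample):
        per_sample = by_locus_sample[locus]
        for sample, proband_obs in per_sample.items():
            if sample not in probands:
                continue
            mother = per_sample.get(proband_obs.mother_id or "")
            father = per_sample.get(proband_obs.father_id or "")
            trios.append(
                (
                    proband_obs,
                    TrioObservation(
                        proband=SampleCounts(
                            proband_obs.alt_reads,
                            proband_obs.total_reads,
                            proband_obs.sex,
                        ),
                        mother=None
                        if mother is None
                        else SampleCounts(
                            mother.alt_reads, mother.total_reads, mother.sex
                        ),
                        father=None
                        if father is None
                        else SampleCounts(
                            father.alt_reads, father.total_reads, father.sex
                        ),
                        chrom_class=proband_obs.chrom_class,
                    ),
                )
            )
    return trios


_CALL_COLUMNS = [
    "sample",
    "chrom",
    "pos",
    "ref",
    "alt",
    "alt_reads",
    "total_reads",
    "aaf",
    "ci_low",
    "ci_high",
    "chrom_class",
    "status",
]


def write_calls_tsv(
    calls: Iterable[tuple[VariantObservation, MosaicCall]],
    path: Union[str, Path],
) -> None:
    with open(path, "w", encoding="utf-8") as out:
        out.write("\t".join(_CALL_COLUMNS) + "\n")
        for obs, call in calls:
            out.write(
                "\t".join(
                    str(value)
                    for value in (
                        obs.sample,
                        obs.chrom,
                        obs.pos,
                        obs.ref,
                        obs.alt,
                        obs.alt_reads,
                        obs.total_reads,
                        f"{call.aaf.value:.6f}",
                        f"{call.aaf.ci_low:.6f}",
                        f"{call.aaf.ci_high:.6f}",
                        obs.chrom_class.value,
                        call.status.value,
                    )
                )
                + "\n"
            )


def _report_to_dict(report: SummaryReport) -> dict:
    payload = dataclasses.asdict(report)
    payload["mean_aaf_by_group"] = {
        name: dataclasses.asdict(group)
        for name, group in report.mean_aaf_by_group.items()
    }
    payload["pathway_burden"] = list(report.pathway_burden)
    return payload


def write_report(
    report: SummaryReport, path: Union[str, Path], format: str = "json"
) -> None:
    """Serialize a summary report; the JSON form round-trips exactly."""
    payload = _report_to_dict(report)
    if format == "json":
        with open(path, "w", encoding="utf-8") as out:
            json.dump(payload, out, indent=2, sort_keys=True)
            out.write("\n")
    elif format == "tsv":
        with open(path, "w", encoding="utf-8") as out:
            out.write("key\tvalue\n")
            for key, value in sorted(payload.items()):
                out.write(f"{key}\t{json.dumps(value, sort_keys=True)}\n")
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report(path: Union[str, Path]) -> SummaryReport:
    """Inverse of :func:`write_report` for the JSON format."""
    with open(path, encoding="utf-8") as handle:
        payload = json.load(handle)
    payload["mean_aaf_by_group"] = {
        name: GroupStats(**group)
        for name, group in payload["mean_aaf_by_group"].items()
    }
    payload["pathway_burden"] = tuple(payload["pathway_burden"])
    return SummaryReport(**payload)
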