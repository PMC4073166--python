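"""Reading and writing the standard formats the pipeline touches.

VCF positions are 1-based; structural-alteration intervals follow the BED
dialect (0-based, half-open). The single bridge between the two conventions
lives in :func:`overlaps`. Annotation values that a filter needs but a record
does not carry are kept as an explicit ``None`` — never silently defaulted —
so the filter engine can decide on missingness itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import pysam

#: site-level annotations consumed by the stringent filter
ANNOTATION_KEYS = ("QD", "MQ", "FS", "HaplotypeScore")

#: recognised structural event types
EVENT_TYPES = ("CNLOH", "deletion", "other")


class VcfParseError(ValueError):
    """Raised when a VCF cannot be parsed into variant records."""


class VcfFormatError(ValueError):
    """Raised when a VCF lacks the FORMAT fields the pipeline requires."""


@dataclass(frozen=True)
class SampleCall:
    """One sample's genotype call at one site.

    genotype
        Unordered pair of allele indices (0 = ref, 1 = first alt, ...) or
        ``None`` when the genotype is missing.
    allelic_depths
        One read count per allele, reference first, or ``None``.
    gq
        Genotype quality, or ``None``.
    """

    genotype: Optional[tuple[int, int]]
    allelic_depths: Optional[tuple[int, ...]]
    gq: Optional[int] = None

    def __post_init__(self) -> None:
        if self.genotype is not None and self.allelic_depths is not None:
            n = len(self.allelic_depths)
            if any(a < 0 or a >= n for a in self.genotype):
                raise ValueError(
                    f"genotype {self.genotype} addresses alleles outside "
                    f"AD of length {n}"
                )
        if self.allelic_depths is not None and any(d < 0 for d in self.allelic_depths):
            raise ValueError("allelic depths must be non-negative")

    @property
    def is_het(self) -> bool:
        if self.genotype is None:
            raise ValueError("genotype is missing")
        return self.genotype[0] != self.genotype[1]


@dataclass
class VariantRecord:
    """One VCF site with per-sample calls.

    ``info`` holds the hard-filter annotations (QD, MQ, FS, HaplotypeScore);
    a key mapped to ``None`` records that the annotation was absent.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    qual: Optional[float]
    info: dict[str, Optional[float]] = field(default_factory=dict)
    calls: dict[str, SampleCall] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or any(not a for a in self.alts):
            raise ValueError("ref and alt alleles must be non-empty")
        for key in ANNOTATION_KEYS:
            self.info.setdefault(key, None)

    @property
    def n_alleles(self) -> int:
        return 1 + len(self.alts)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and all(len(a) == 1 for a in self.alts)


@dataclass(frozen=True)
class GenomicInterval:
    """A structural-alteration region, 0-based half-open (BED dialect)."""

    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    event: str = "other"
    label: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval [{self.start}, {self.end})"
            )
        if self.event not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event!r}")

    @property
    def length_kb(self) -> float:
        return (self.end - self.start) / 1000.0


def overlaps(record: VariantRecord, interval: GenomicInterval) -> bool:
    """True iff the 1-based site falls inside the half-open interval.

    A 1-based position ``p`` occupies 0-based base ``p - 1``, so the test is
    ``start < p <= end``.
    """
    return (
        record.chrom == interval.chrom
        and interval.start < record.pos <= interval.end
    )


def chrom_sort_key(chrom: str) -> tuple[int, int, str]:
    """Karyotype ordering: chr1..chr22, chrX, chrY, chrM, then others."""
    name = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if name.isdigit():
        return (0, int(name), "")
    special = {"X": 23, "Y": 24, "M": 25, "MT": 25}
    if name.upper() in special:
        return (0, special[name.upper()], "")
    return (1, 0, name)


# ---------------------------------------------------------------------------
# VCF

def _build_header(
    records: Sequence[VariantRecord], extra_header_lines: Iterable[str]
) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for line in extra_header_lines:
        header.add_line(line)
    seen: dict[str, None] = {}
    samples: dict[str, None] = {}
    for rec in records:
        seen.setdefault(rec.chrom)
        for name in rec.calls:
            samples.setdefault(name)
    for chrom in seen:
        header.contigs.add(chrom)
    header.info.add("QD", 1, "Float", "Variant confidence by depth")
    header.info.add("MQ", 1, "Float", "RMS mapping quality")
    header.info.add("FS", 1, "Float", "Phred-scaled strand-bias Fisher p")
    header.info.add("HaplotypeScore", 1, "Float", "Haplotype consistency score")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref first)")
    header.formats.add("GQ", 1, "Integer", "Genotype quality")
    for name in samples:
        header.add_sample(name)
    return header


def write_vcf(
    records: Sequence[VariantRecord],
    path: str,
    extra_header_lines: Iterable[str] = (),
) -> None:
    """Write records as uncompressed VCF 4.2."""
    header = _build_header(records, extra_header_lines)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec in records:
            vrec = out.new_record(
                contig=rec.chrom,
                start=rec.pos - 1,
                alleles=(rec.ref, *rec.alts),
                qual=rec.qual,
            )
            for key, value in rec.info.items():
                if value is not None:
                    vrec.info[key] = value
            for name, call in rec.calls.items():
                fmt = vrec.samples[name]
                fmt["GT"] = call.genotype if call.genotype is not None else (None, None)
                fmt.phased = False
                if call.allelic_depths is not None:
                    fmt["AD"] = call.allelic_depths
                if call.gq is not None:
                    fmt["GQ"] = call.gq
            out.write(vrec)


def read_vcf(path: str) -> list[VariantRecord]:
    """Read a VCF 4.x with FORMAT fields GT and AD into variant records.

    Missing annotations are recorded as ``None``. A file whose FORMAT
    declarations lack GT or AD is rejected up front.
    """
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise VcfParseError(f"cannot parse VCF {path!r}: {exc}") from exc
    with vf:
        for required in ("GT", "AD"):
            if required not in vf.header.formats:
                raise VcfFormatError(
                    f"VCF {path!r} does not declare FORMAT field {required}"
                )
        sample_names = list(vf.header.samples)
        records: list[VariantRecord] = []
        index = 0
        try:
            for vrec in vf:
                index += 1
                records.append(_convert_record(vrec, sample_names))
        except (OSError, ValueError) as exc:
            raise VcfParseError(
                f"malformed VCF record near data line {index + 1} "
                f"of {path!r}: {exc}"
            ) from exc
    return records


def _convert_record(
    vrec: "pysam.VariantRecord", sample_names: Sequence[str]
) -> VariantRecord:
    info: dict[str, Optional[float]] = {}
    for key in ANNOTATION_KEYS:
        if key in vrec.info:
            value = vrec.info[key]
            if isinstance(value, tuple):
                value = value[0]
            info[key] = float(value)
        else:
            info[key] = None
    calls: dict[str, SampleCall] = {}
    for name in sample_names:
        fmt = vrec.samples[name]
        gt = fmt.get("GT")
        if gt is None or any(a is None for a in gt):
            genotype = None
        else:
            genotype = (int(gt[0]), int(gt[1]))
        ad = fmt.get("AD")
        if ad is None or all(d is None for d in ad):
            depths = None
        else:
            depths = tuple(int(d) if d is not None else 0 for d in ad)
        gq = fmt.get("GQ")
        calls[name] = SampleCall(
            genotype=genotype,
            allelic_depths=depths,
            gq=int(gq) if gq is not None else None,
        )
    return VariantRecord(
        chrom=vrec.chrom,
        pos=vrec.pos,
        ref=vrec.ref,
        alts=tuple(vrec.alts or ()),
        qual=float(vrec.qual) if vrec.qual is not None else None,
        info=info,
        calls=calls,
    )


# ---------------------------------------------------------------------------
# BED-like intervals

def _classify_event(token: str) -> str:
    lowered = token.lower()
    if lowered.startswith("cnloh"):
        return "CNLOH"
    if lowered.startswith("del"):
        return "deletion"
    return "other"


def read_intervals(path: str) -> list[GenomicInterval]:
    """Read a BED-like file (chrom, start, end[, label]) of structural regions.

    The optional fourth column is kept verbatim as the label; the event type
    is derived from its prefix (``CNLOH*`` / ``del*``), defaulting to
    ``other``.
    """
    frame = pd.read_csv(
        path, sep=r"\s+", header=None, comment="#", dtype={0: str}
    )
    if frame.shape[1] < 3:
        raise ValueError(f"BED file {path!r} has fewer than 3 columns")
    intervals: list[GenomicInterval] = []
    for row in frame.itertuples(index=False):
        chrom, start, end = str(row[0]), int(row[1]), int(row[2])
        label = str(row[3]) if frame.shape[1] > 3 else ""
        intervals.append(
            GenomicInterval(
                chrom=chrom,
                start=start,
                end=end,
                event=_classify_event(label) if label else "other",
                label=label,
            )
        )
    return intervals


def write_intervals(intervals: Sequence[GenomicInterval], path: str) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label or iv.event}\n")
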