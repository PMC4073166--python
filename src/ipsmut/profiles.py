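"""Mutation summaries: annotation-category tallies, base-change spectra and
the per-population-doubling substitution rate.

Effect categories follow SnpEff-style labels. When an SNV carries several
labels (e.g. downstream of one gene, non-synonymous in another) a single
category is resolved by fixed precedence:

    coding > splice site > UTR > intron > up/downstream > non-coding exon
    > intergenic

The spectrum is reported both as the 12 ordered ref>alt classes and as the
6 pyrimidine-collapsed classes (a purine ref is complemented together with
its alt, so G>A counts as C>T). The transition/transversion ratio counts
A<->G and C<->T changes as transitions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .io import VariantRecord

#: categories in precedence order (highest first)
CATEGORY_PRECEDENCE = (
    "stop_gained",
    "stop_lost",
    "start_lost",
    "non_synonymous_coding",
    "synonymous_coding",
    "splice_site",
    "utr_5",
    "utr_3",
    "intron",
    "upstream",
    "downstream",
    "non_coding_exon",
    "intergenic",
)

CATEGORIES = frozenset(CATEGORY_PRECEDENCE)

_BASES = ("A", "C", "G", "T")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: the 12 ordered single-base changes
CHANGE_CLASSES_12 = tuple(
    f"{r}>{a}" for r in _BASES for a in _BASES if r != a
)
#: the 6 pyrimidine-context classes
CHANGE_CLASSES_6 = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_TRANSITIONS = frozenset({"A>G", "G>A", "C>T", "T>C"})


@dataclass(frozen=True)
class AnnotatedSNV:
    """A final somatic SNV with its derived line and resolved category."""

    record: VariantRecord
    sample: str
    category: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


@dataclass(frozen=True)
class Spectrum:
    """Base-change spectrum in 12-class and collapsed 6-class form."""

    counts12: Mapping[str, int]
    counts6: Mapping[str, int]
    titv: float  # inf when no transversions; nan when empty

    @property
    def n(self) -> int:
        return sum(self.counts12.values())


@dataclass(frozen=True)
class RateEstimate:
    """SNVs per population doubling, pooled over derived lines."""

    total_snvs: int
    total_pd: float
    rate: float


def resolve_category(effect_labels: Iterable[str]) -> str:
    """Collapse one SNV's annotation labels to a single category."""
    labels = list(effect_labels)
    if not labels:
        raise ValueError("at least one effect label is required")
    for label in labels:
        if label not in CATEGORIES:
            raise ValueError(f"unknown category label {label!r}")
    return min(labels, key=CATEGORY_PRECEDENCE.index)


def tally_categories(snvs: Iterable[AnnotatedSNV]) -> dict[str, int]:
    """Count SNVs per category; zero categories are reported explicitly."""
    counts = {c: 0 for c in CATEGORY_PRECEDENCE}
    for snv in snvs:
        counts[snv.category] += 1
    return counts


def _change_of(record: VariantRecord) -> str:
    if not record.is_snv or len(record.alts) != 1:
        raise ValueError(
            f"{record.chrom}:{record.pos} is not a biallelic single-base "
            "substitution"
        )
    ref, alt = record.ref.upper(), record.alts[0].upper()
    if ref not in _BASES or alt not in _BASES or ref == alt:
        raise ValueError(f"invalid substitution {ref}>{alt}")
    return f"{ref}>{alt}"


def collapse_to_pyrimidine(change: str) -> str:
    """Map an ordered change to its pyrimidine-reference equivalent."""
    ref, alt = change.split(">")
    if ref in ("A", "G"):
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return f"{ref}>{alt}"


def spectrum(snvs: Iterable[AnnotatedSNV]) -> Spectrum:
    """Tally the single-base-change pattern of a set of somatic SNVs."""
    counts12 = {c: 0 for c in CHANGE_CLASSES_12}
    for snv in snvs:
        counts12[_change_of(snv.record)] += 1
    counts6 = {c: 0 for c in CHANGE_CLASSES_6}
    for change, n in counts12.items():
        counts6[collapse_to_pyrimidine(change)] += n
    ti = sum(n for c, n in counts12.items() if c in _TRANSITIONS)
    tv = sum(n for c, n in counts12.items() if c not in _TRANSITIONS)
    if ti == 0 and tv == 0:
        titv = math.nan
    elif tv == 0:
        titv = math.inf
    else:
        titv = ti / tv
    return Spectrum(counts12=counts12, counts6=counts6, titv=titv)


def mutation_rate_per_pd(
    per_line: Mapping[str, tuple[int, int]],
    pd_per_passage: float = 3.70,
) -> RateEstimate:
    """Pooled substitution rate per population doubling.

    ``per_line`` maps each derived line to (SNV count, passages in culture);
    the denominator is the summed passages times ``pd_per_passage``. The
    default 3.70 doublings per passage is an assumption of this package
    (typical clump-passaged human iPS cultures gain 3-4 doublings per
    passage); see the methods note.
    """
    if not per_line:
        raise ValueError("per_line mapping is empty")
    if pd_per_passage <= 0:
        raise ValueError("pd_per_passage must be positive")
    total_snvs = 0
    total_passages = 0
    for line, (count, passages) in per_line.items():
        if count < 0:
            raise ValueError(f"negative SNV count for {line!r}")
        if passages <= 0:
            raise ValueError(f"non-positive passages for {line!r}")
        total_snvs += count
        total_passages += passages
    total_pd = total_passages * pd_per_passage
    return RateEstimate(
        total_snvs=total_snvs, total_pd=total_pd, rate=total_snvs / total_pd
    )


def read_annotation_table(path: str) -> dict[tuple[str, int, str], list[str]]:
    """Read a TSV (chrom, pos, sample, effects semicolon-joined) of labels."""
    import pandas as pd

    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "sample", "effects"}
    if not required.issubset(frame.columns):
        raise ValueError(f"annotation table must have columns {sorted(required)}")
    out: dict[tuple[str, int, str], list[str]] = {}
    for row in frame.itertuples(index=False):
        out[(row.chrom, int(row.pos), row.sample)] = str(row.effects).split(";")
    return out
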