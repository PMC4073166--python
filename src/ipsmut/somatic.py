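"""Derived-line somatic SNV extraction and the exclusion accounting.

A site is somatic for a derived line when the parental sample is homozygous
reference and the derived genotype carries at least one allele absent from
the parental genotype — i.e. a de novo substitution. Genotype changes caused
by large-scale events (copy-neutral LOH, deletions) are handled by the
structural-region exclusion channel instead, and a short manual exclusion
list removes ambiguous calls that escaped the filters. The accounting
records every stage: called -> region-excluded -> manually-excluded -> final.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .filtering import apply_stringent_filter, full_verdict
from .io import GenomicInterval, VariantRecord, chrom_sort_key, overlaps


@dataclass(frozen=True)
class SomaticAccounting:
    """Counts at every stage of the somatic-SNV selection."""

    called: int
    removed_by_region: Mapping[str, int]
    removed_manual: int

    def __post_init__(self) -> None:
        if self.called < 0 or self.removed_manual < 0:
            raise ValueError("counts must be non-negative")
        if any(v < 0 for v in self.removed_by_region.values()):
            raise ValueError("counts must be non-negative")
        if self.final < 0:
            raise ValueError(
                f"exclusions exceed called count ({self.called} called, "
                f"{sum(self.removed_by_region.values())} in regions, "
                f"{self.removed_manual} manual)"
            )

    @property
    def final(self) -> int:
        return self.called - sum(self.removed_by_region.values()) - self.removed_manual


def accounting(
    called: int,
    removed_by_region: Mapping[str, int],
    removed_manual: int,
) -> SomaticAccounting:
    """Build the stage accounting; raises if the final count would be negative."""
    return SomaticAccounting(
        called=called,
        removed_by_region=dict(removed_by_region),
        removed_manual=removed_manual,
    )


def call_somatic(
    records: Sequence[VariantRecord],
    parental: str,
    derived: str,
    require_parental_pass: bool = True,
    permissive_missing: bool = False,
) -> list[VariantRecord]:
    """Return de novo SNV sites of ``derived`` versus ``parental``.

    Both samples must pass the stringent filter at the site (the parental
    requirement can be relaxed with ``require_parental_pass=False``); the
    parental genotype must be 0/0 and the derived genotype must carry a
    non-reference allele. Output is sorted by (karyotype chrom order, pos).
    """
    for rec in records:
        for name in (parental, derived):
            if name not in rec.calls:
                raise KeyError(
                    f"sample {name!r} absent at {rec.chrom}:{rec.pos}"
                )
    out: list[VariantRecord] = []
    for rec in records:
        if not full_verdict(rec, derived, permissive_missing).kept:
            continue
        if require_parental_pass and not full_verdict(
            rec, parental, permissive_missing
        ).kept:
            continue
        pgt = rec.calls[parental].genotype
        dgt = rec.calls[derived].genotype
        if pgt is None or dgt is None:
            continue
        if set(pgt) != {0}:
            continue
        if any(allele != 0 for allele in dgt):
            out.append(rec)
    out.sort(key=lambda r: (chrom_sort_key(r.chrom), r.pos))
    return out


def exclude_structural(
    snvs: Sequence[VariantRecord],
    regions: Sequence[GenomicInterval],
) -> tuple[list[VariantRecord], dict[str, list[VariantRecord]]]:
    """Partition SNVs into (kept, removed-grouped-by-region-label).

    An SNV is removed iff it overlaps any region; one overlapping several
    regions is attributed to the left-most (then lexicographically first
    label). kept plus all removed groups is the input.
    """
    trees: dict[str, IntervalTree] = {}
    for iv in regions:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    kept: list[VariantRecord] = []
    removed: dict[str, list[VariantRecord]] = {}
    for snv in snvs:
        tree = trees.get(snv.chrom)
        hits = sorted(
            (h.data for h in tree.at(snv.pos - 1)) if tree else (),
            key=lambda iv: (iv.start, iv.label),
        )
        if hits:
            label = hits[0].label or hits[0].event
            removed.setdefault(label, []).append(snv)
        else:
            kept.append(snv)
    return kept, removed


def apply_exclusion_list(
    snvs: Sequence[VariantRecord],
    excluded: Iterable[tuple[str, int, str]],
    sample: str,
) -> tuple[list[VariantRecord], int]:
    """Remove exact (chrom, pos, sample) matches from a line's SNV list.

    ``sample`` names the derived line the SNVs belong to; entries for other
    samples are ignored. Duplicate entries count once; entries matching no
    SNV raise a warning, never an error. Returns (kept, number removed).
    """
    entries = list(excluded)
    unique = set()
    for entry in entries:
        key = (str(entry[0]), int(entry[1]), str(entry[2]))
        if key in unique:
            warnings.warn(f"duplicate exclusion-list entry {key}", stacklevel=2)
        unique.add(key)
    relevant = {(c, p) for c, p, s in unique if s == sample}
    present = {(s.chrom, s.pos) for s in snvs}
    for miss in sorted(relevant - present):
        warnings.warn(
            f"exclusion-list entry {miss + (sample,)} matched no SNV",
            stacklevel=2,
        )
    kept = [s for s in snvs if (s.chrom, s.pos) not in relevant]
    return kept, len(snvs) - len(kept)


def somatic_pipeline(
    records: Sequence[VariantRecord],
    parental: str,
    derived_lines: Sequence[str],
    regions: Sequence[GenomicInterval] = (),
    exclusion: Iterable[tuple[str, int, str]] = (),
    require_parental_pass: bool = True,
) -> tuple[dict[str, list[VariantRecord]], SomaticAccounting]:
    """Run the full selection for every derived line and pool the accounting.

    Returns (final SNVs per line, pooled SomaticAccounting).
    """
    exclusion = list(exclusion)
    per_line: dict[str, list[VariantRecord]] = {}
    called = 0
    removed_by_region: Counter[str] = Counter()
    removed_manual = 0
    for line in derived_lines:
        snvs = call_somatic(
            records, parental, line, require_parental_pass=require_parental_pass
        )
        called += len(snvs)
        kept, removed = exclude_structural(snvs, regions)
        for label, group in removed.items():
            removed_by_region[label] += len(group)
        line_entries = [e for e in exclusion if e[2] == line]
        kept, n_manual = apply_exclusion_list(kept, line_entries, sample=line)
        removed_manual += n_manual
        per_line[line] = kept
    return per_line, accounting(called, dict(removed_by_region), removed_manual)


__all__ = [
    "SomaticAccounting",
    "accounting",
    "call_somatic",
    "exclude_structural",
    "apply_exclusion_list",
    "somatic_pipeline",
    "overlaps",
]
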