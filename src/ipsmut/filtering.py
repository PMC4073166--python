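"""The stringent post-calling SNV filter.

Two layers are applied to every candidate site, for a named focal sample:

1. *Site-quality elimination* — a record is eliminated when any clause of

   ``QUAL < 400 || QD < 2.0 || MQ < 40.0 || FS > 60.0 ||
   HaplotypeScore > 13.0 || GQ <= 60``

   holds (GQ is the focal sample's genotype quality; the other annotations
   are site-level INFO values).

2. *Genotype-class allelic-depth selection* — for heterozygous calls
   (0/1, 0/2, 1/2) the two depths addressed by the genotype must both be
   >= 8 and differ by at most twofold (ratio <= 2, boundary passing).
   For homozygous calls (0/0, 1/1, 2/2) the depth ``a`` of the genotype's
   allele is compared against the largest depth ``b`` among all other
   alleles, and the call is selected when ``a/b >= 32`` (b > 0), or
   ``b == 1 and a >= 16``, or ``b == 0 and a >= 8``.

"Within twofold" / "no less than 32-fold" are fold-ratios, not arithmetic
differences: the (1, >=16) and (0, >=8) carve-outs are exceptions for a
degenerate denominator, which only makes sense for a ratio rule.

A record missing a required annotation is eliminated with ``MISSING_FIELD``
unless ``permissive_missing`` is set (in which case absent annotations are
simply not evaluated).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .io import SampleCall, VariantRecord

# failure codes, one per clause of the printed filter plus the AD rules
QUAL_LT_400 = "QUAL_LT_400"
QD_LT_2 = "QD_LT_2"
MQ_LT_40 = "MQ_LT_40"
FS_GT_60 = "FS_GT_60"
HS_GT_13 = "HS_GT_13"
GQ_LE_60 = "GQ_LE_60"
AD_HET_FAIL = "AD_HET_FAIL"
AD_HOM_FAIL = "AD_HOM_FAIL"
MISSING_FIELD = "MISSING_FIELD"

ALL_REASONS = (
    QUAL_LT_400,
    QD_LT_2,
    MQ_LT_40,
    FS_GT_60,
    HS_GT_13,
    GQ_LE_60,
    AD_HET_FAIL,
    AD_HOM_FAIL,
    MISSING_FIELD,
)


@dataclass(frozen=True)
class FilterVerdict:
    """Outcome of the stringent filter for one record and one sample."""

    kept: bool
    reasons: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kept != (len(self.reasons) == 0):
            raise ValueError("kept must hold exactly when reasons is empty")


def _verdict(reasons: list[str]) -> FilterVerdict:
    return FilterVerdict(kept=not reasons, reasons=tuple(reasons))


def site_quality_filter(
    record: VariantRecord,
    sample: str,
    permissive_missing: bool = False,
) -> FilterVerdict:
    """Evaluate the site-quality clauses (plus the focal sample's GQ)."""
    if sample not in record.calls:
        raise KeyError(f"sample {sample!r} absent at {record.chrom}:{record.pos}")
    call = record.calls[sample]
    clauses = (
        (record.qual, lambda v: v < 400.0, QUAL_LT_400),
        (record.info.get("QD"), lambda v: v < 2.0, QD_LT_2),
        (record.info.get("MQ"), lambda v: v < 40.0, MQ_LT_40),
        (record.info.get("FS"), lambda v: v > 60.0, FS_GT_60),
        (record.info.get("HaplotypeScore"), lambda v: v > 13.0, HS_GT_13),
        (call.gq, lambda v: v <= 60, GQ_LE_60),
    )
    reasons: list[str] = []
    missing = False
    for value, fails, code in clauses:
        if value is None:
            missing = missing or not permissive_missing
        elif fails(value):
            reasons.append(code)
    if missing:
        reasons.append(MISSING_FIELD)
    return _verdict(reasons)


def het_ad_filter(call: SampleCall) -> bool:
    """Allelic-depth selection rule for heterozygous genotypes.

    Inspects only the two depths addressed by the genotype; passes when both
    are >= 8 and the larger is at most twice the smaller (8/16 passes).
    """
    if call.genotype is None:
        raise ValueError("genotype is missing")
    i, j = call.genotype
    if i == j:
        raise ValueError("het_ad_filter called on a homozygous genotype")
    if call.allelic_depths is None:
        raise ValueError("allelic depths are missing")
    a, b = call.allelic_depths[i], call.allelic_depths[j]
    return a >= 8 and b >= 8 and max(a, b) <= 2 * min(a, b)


def hom_ad_filter(call: SampleCall) -> bool:
    """Allelic-depth selection rule for homozygous genotypes.

    ``a`` is the depth of the genotype's allele, ``b`` the largest depth among
    every other allele (the most conservative possible contaminant).
    """
    if call.genotype is None:
        raise ValueError("genotype is missing")
    i, j = call.genotype
    if i != j:
        raise ValueError("hom_ad_filter called on a heterozygous genotype")
    if call.allelic_depths is None:
        raise ValueError("allelic depths are missing")
    depths = call.allelic_depths
    a = depths[i]
    b = max(d for k, d in enumerate(depths) if k != i)
    if b == 0:
        return a >= 8
    if b == 1:
        return a >= 16
    return a >= 32 * b


def full_verdict(
    record: VariantRecord,
    sample: str,
    permissive_missing: bool = False,
) -> FilterVerdict:
    """Site-quality clauses plus the genotype-appropriate AD rule."""
    site = site_quality_filter(record, sample, permissive_missing)
    reasons = list(site.reasons)
    call = record.calls[sample]
    if call.genotype is None or call.allelic_depths is None:
        if not permissive_missing and MISSING_FIELD not in reasons:
            reasons.append(MISSING_FIELD)
    elif call.is_het:
        if not het_ad_filter(call):
            reasons.append(AD_HET_FAIL)
    else:
        if not hom_ad_filter(call):
            reasons.append(AD_HOM_FAIL)
    return _verdict(reasons)


def apply_stringent_filter(
    records: Sequence[VariantRecord],
    sample: str,
    permissive_missing: bool = False,
) -> tuple[list[VariantRecord], pd.DataFrame]:
    """Filter records for one sample; return (kept, verdict table).

    The verdict table has one row per input record with columns
    chrom, pos, ref, alt, kept, reasons (comma-joined codes).
    """
    kept: list[VariantRecord] = []
    rows: list[dict[str, object]] = []
    for rec in records:
        verdict = full_verdict(rec, sample, permissive_missing)
        if verdict.kept:
            kept.append(rec)
        rows.append(
            {
                "chrom": rec.chrom,
                "pos": rec.pos,
                "ref": rec.ref,
                "alt": ",".join(rec.alts),
                "kept": verdict.kept,
                "reasons": ",".join(verdict.reasons),
            }
        )
    table = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "kept", "reasons"]
    )
    return kept, table
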