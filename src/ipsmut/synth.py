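"""Synthetic inputs with the statistical structure the analysis assumes.

The generators emulate a multi-sample exome call set for a parental
fibroblast line plus derived iPS-cell lines: inherited variants shared by
every sample, planted de novo (somatic) SNVs per derived line, structural
regions (copy-neutral LOH, deletions) containing some of those SNVs, an
ambiguous-call subset destined for a manual exclusion list, and Q-FISH
telomere-intensity tables targeting a chosen TFI ratio. Every generator is
a pure function of its config plus seed; truth tables score every
downstream stage.

The synthetic genome assigns each derived line its own artificial
chromosome, sized to hold all structural regions, so pooled region
exclusion affects exactly the intended line.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io import GenomicInterval, SampleCall, VariantRecord, chrom_sort_key
from .profiles import CATEGORY_PRECEDENCE, CHANGE_CLASSES_12

PARENTAL_NAME = "AT1OS"
DEFAULT_LINE_NAMES = ("ATiPS-262", "ATiPS-263", "ATiPS-264", "ATiPS-024")
#: passages at which each derived line was profiled
DEFAULT_PASSAGES = {
    "ATiPS-262": 17,
    "ATiPS-263": 27,
    "ATiPS-264": 25,
    "ATiPS-024": 25,
}
#: assumed population doublings per passage (see methods note)
DEFAULT_PD_PER_PASSAGE = 3.70

_QUALITY_CLAUSES = ("QUAL", "QD", "MQ", "FS", "HaplotypeScore", "GQ")
_MAX_SEED = 2**31 - 1


def _check_probs(name: str, probs: Mapping[str, float], keys: Sequence[str]) -> None:
    unknown = set(probs) - set(keys)
    if unknown:
        raise ValueError(f"{name} has unknown keys {sorted(unknown)}")
    total = sum(probs.values())
    if not math.isclose(total, 1.0, abs_tol=1e-9):
        raise ValueError(f"{name} probabilities sum to {total}, expected 1")
    if any(p < 0 for p in probs.values()):
        raise ValueError(f"{name} probabilities must be non-negative")


def _draw_from(rng: np.random.Generator, probs: Mapping[str, float],
               keys: Sequence[str]) -> str:
    p = np.array([probs.get(k, 0.0) for k in keys])
    return keys[rng.choice(len(keys), p=p / p.sum())]


@dataclass
class CohortConfig:
    """Configuration of one synthetic multi-sample call set.

    ``somatic_per_line`` and ``ambiguous_per_line`` accept either a single
    integer (applied to every line) or one value per line. Quality and
    depth defaults follow the study conditions: ~90x mean depth, four
    derived lines plus parent, no clause failures unless requested.
    """

    n_sites: int = 120  # inherited background sites
    n_lines: int = 4
    somatic_per_line: int | Sequence[int] = 25
    depth_mean: float = 90.0
    spectrum_probs: Optional[Mapping[str, float]] = None  # uniform if None
    category_probs: Optional[Mapping[str, float]] = None  # uniform if None
    quality_fail_fracs: Optional[Mapping[str, float]] = None  # all 0 if None
    ambiguous_per_line: int | Sequence[int] = 0
    ad_noise: float = 0.0  # 0 -> deterministic expected depths
    het_background_frac: float = 0.7
    chrom_length: int = 50_000_000
    seed: int = 0
    parental: str = PARENTAL_NAME
    line_names: Optional[Sequence[str]] = None
    planted_regions: Optional[
        Mapping[str, Sequence[tuple[GenomicInterval, int]]]
    ] = None

    def resolved_lines(self) -> tuple[str, ...]:
        if self.line_names is not None:
            if len(self.line_names) != self.n_lines:
                raise ValueError("line_names length must equal n_lines")
            return tuple(self.line_names)
        if self.n_lines <= len(DEFAULT_LINE_NAMES):
            return DEFAULT_LINE_NAMES[: self.n_lines]
        extra = tuple(
            f"LINE-{i + 1}" for i in range(len(DEFAULT_LINE_NAMES), self.n_lines)
        )
        return DEFAULT_LINE_NAMES + extra

    def _per_line(self, value: int | Sequence[int], name: str) -> tuple[int, ...]:
        if isinstance(value, int):
            return (value,) * self.n_lines
        if len(value) != self.n_lines:
            raise ValueError(f"{name} must have one entry per line")
        return tuple(int(v) for v in value)

    def validate(self) -> None:
        if self.n_sites < 0 or self.n_lines < 1:
            raise ValueError("n_sites must be >= 0 and n_lines >= 1")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if not 0 <= self.ad_noise < 0.5:
            raise ValueError("ad_noise must be in [0, 0.5)")
        if self.spectrum_probs is not None:
            _check_probs("spectrum_probs", self.spectrum_probs, CHANGE_CLASSES_12)
        if self.category_probs is not None:
            _check_probs("category_probs", self.category_probs, CATEGORY_PRECEDENCE)
        if self.quality_fail_fracs is not None:
            unknown = set(self.quality_fail_fracs) - set(_QUALITY_CLAUSES)
            if unknown:
                raise ValueError(f"unknown quality clauses {sorted(unknown)}")
            if any(not 0 <= f <= 1 for f in self.quality_fail_fracs.values()):
                raise ValueError("quality_fail_fracs must be in [0, 1]")


@dataclass
class RegionConfig:
    """Structural-region layout: (length_kb, event, n_planted_snvs) tuples."""

    regions: Sequence[tuple[float, str, int]]
    chrom: str = "chr1"
    chrom_length: int = 50_000_000
    min_gap: int = 10_000
    seed: int = 0


# ---------------------------------------------------------------------------
# helpers

def _unique_positions(
    rng: np.random.Generator,
    n: int,
    lo: int,
    hi: int,
    used: set[int],
    forbidden: Sequence[GenomicInterval] = (),
) -> list[int]:
    """Draw n distinct 1-based positions in [lo, hi], outside forbidden."""
    out: list[int] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 1000 * max(n, 1):
            raise ValueError("cannot place positions: region too crowded")
        pos = int(rng.integers(lo, hi + 1))
        if pos in used:
            continue
        if any(iv.start < pos <= iv.end for iv in forbidden):
            continue
        used.add(pos)
        out.append(pos)
    return out


def _split_change(change: str) -> tuple[str, str]:
    ref, alt = change.split(">")
    return ref, alt


def _het_ad(rng: np.random.Generator, depth: int, n_alleles: int,
            i: int, j: int, noise: float) -> tuple[int, ...]:
    ad = [0] * n_alleles
    if noise == 0:
        ad[i] = (depth + 1) // 2
        ad[j] = depth // 2
    else:
        a = int(rng.binomial(depth, 0.5))
        ad[i], ad[j] = a, depth - a
    return tuple(ad)


def _hom_ad(rng: np.random.Generator, depth: int, n_alleles: int,
            i: int, noise: float) -> tuple[int, ...]:
    ad = [0] * n_alleles
    if noise == 0:
        ad[i] = depth
    else:
        contam = int(rng.binomial(depth, noise))
        ad[i] = depth - contam
        other = 0 if i != 0 else (1 if n_alleles > 1 else 0)
        ad[other] += contam
    return tuple(ad)


# ---------------------------------------------------------------------------
# cohort

def generate_cohort(
    config: CohortConfig,
) -> tuple[list[VariantRecord], pd.DataFrame]:
    """Generate a multi-sample call set plus a truth table.

    Returns (records sorted by position, truth table). The truth table has
    one row per planted somatic SNV with columns chrom, pos, sample, ref,
    alt, change12, category, region_label, ambiguous, quality_ok.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lines = config.resolved_lines()
    samples = (config.parental, *lines)
    somatic_counts = config._per_line(config.somatic_per_line, "somatic_per_line")
    ambiguous_counts = config._per_line(
        config.ambiguous_per_line, "ambiguous_per_line"
    )
    fail_fracs = dict(config.quality_fail_fracs or {})
    planted_regions = dict(config.planted_regions or {})

    chrom_of = {line: f"chr{i + 1}" for i, line in enumerate(lines)}
    used: dict[str, set[int]] = {c: set() for c in chrom_of.values()}

    records: list[VariantRecord] = []
    truth_rows: list[dict[str, object]] = []

    def draw_depth() -> int:
        return max(16, int(rng.poisson(config.depth_mean)))

    def draw_quality() -> tuple[dict[str, float], float, int, bool]:
        """Site annotations; configured fractions fail each clause."""
        fails = {c: rng.random() < fail_fracs.get(c, 0.0) for c in _QUALITY_CLAUSES}
        qual = float(round(rng.uniform(50, 399), 1)) if fails["QUAL"] else float(
            round(rng.uniform(500, 3000), 1)
        )
        info = {
            "QD": float(round(rng.uniform(0.1, 1.9), 2)) if fails["QD"] else float(
                round(rng.uniform(5, 30), 2)
            ),
            "MQ": float(round(rng.uniform(10, 39), 2)) if fails["MQ"] else float(
                round(rng.uniform(45, 60), 2)
            ),
            "FS": float(round(rng.uniform(61, 200), 2)) if fails["FS"] else float(
                round(rng.uniform(0, 10), 2)
            ),
            "HaplotypeScore": float(round(rng.uniform(13.5, 40), 2))
            if fails["HaplotypeScore"]
            else float(round(rng.uniform(0, 5), 2)),
        }
        gq = int(rng.integers(0, 61)) if fails["GQ"] else 99
        ok = not any(fails.values())
        return info, qual, gq, ok

    def draw_change(probs: Optional[Mapping[str, float]]) -> str:
        if probs is None:
            return CHANGE_CLASSES_12[rng.integers(0, 12)]
        return _draw_from(rng, probs, CHANGE_CLASSES_12)

    # --- inherited background sites (never somatic: all samples share gt)
    background_chroms = list(chrom_of.values())
    for k in range(config.n_sites):
        chrom = background_chroms[int(rng.integers(0, len(background_chroms)))]
        pos = _unique_positions(rng, 1, 1, config.chrom_length, used[chrom])[0]
        ref, alt = _split_change(draw_change(None))
        info, qual, gq, _ = draw_quality()
        depth = draw_depth()
        if rng.random() < config.het_background_frac:
            gt = (0, 1)
            ad = _het_ad(rng, depth, 2, 0, 1, config.ad_noise)
        else:
            gt = (1, 1)
            ad = _hom_ad(rng, depth, 2, 1, config.ad_noise)
        calls = {
            name: SampleCall(genotype=gt, allelic_depths=ad, gq=gq)
            for name in samples
        }
        records.append(
            VariantRecord(
                chrom=chrom, pos=pos, ref=ref, alts=(alt,), qual=qual,
                info=dict(info), calls=calls,
            )
        )

    # --- planted somatic SNVs, one derived line at a time
    for idx, line in enumerate(lines):
        chrom = chrom_of[line]
        n_total = somatic_counts[idx]
        n_ambig = ambiguous_counts[idx]
        plants = list(planted_regions.get(line, ()))
        n_in_regions = sum(n for _, n in plants)
        if n_in_regions > n_total:
            raise ValueError(
                f"{line}: {n_in_regions} region-planted SNVs exceed "
                f"somatic_per_line {n_total}"
            )
        region_intervals = [iv for iv, _ in plants]
        for iv, _ in plants:
            if iv.chrom != chrom:
                raise ValueError(
                    f"region {iv.label!r} on {iv.chrom} cannot hold SNVs of "
                    f"{line} (its chromosome is {chrom})"
                )
            if iv.end > config.chrom_length:
                raise ValueError(f"region {iv.label!r} exceeds chromosome length")

        site_plan: list[tuple[int, str]] = []  # (pos, region_label)
        for iv, n in plants:
            for pos in _unique_positions(
                rng, n, iv.start + 1, iv.end, used[chrom]
            ):
                site_plan.append((pos, iv.label or iv.event))
        n_free = n_total - n_in_regions
        if n_ambig > n_free:
            raise ValueError(
                f"{line}: {n_ambig} ambiguous SNVs exceed the {n_free} "
                "outside structural regions"
            )
        free_positions = _unique_positions(
            rng, n_free, 1, config.chrom_length, used[chrom], region_intervals
        )
        site_plan.extend((pos, "") for pos in free_positions)
        # ambiguity assignment follows draw order within the free set
        ambiguous_set = set(free_positions[:n_ambig])

        for pos, region_label in site_plan:
            change = draw_change(config.spectrum_probs)
            ref, alt = _split_change(change)
            if config.category_probs is None:
                category = CATEGORY_PRECEDENCE[
                    int(rng.integers(0, len(CATEGORY_PRECEDENCE)))
                ]
            else:
                category = _draw_from(
                    rng, config.category_probs, CATEGORY_PRECEDENCE
                )
            info, qual, gq, quality_ok = draw_quality()
            is_ambig = pos in ambiguous_set
            calls: dict[str, SampleCall] = {}
            for name in samples:
                depth = draw_depth()
                if name == line:
                    if is_ambig:
                        # boundary-legal depths: passes the twofold rule
                        # exactly, mimicking a call that escaped filtering
                        ad = (8, 16)
                    else:
                        ad = _het_ad(rng, depth, 2, 0, 1, config.ad_noise)
                    calls[name] = SampleCall(genotype=(0, 1),
                                             allelic_depths=ad, gq=gq)
                else:
                    ad = _hom_ad(rng, depth, 2, 0, config.ad_noise)
                    calls[name] = SampleCall(genotype=(0, 0),
                                             allelic_depths=ad, gq=gq)
            records.append(
                VariantRecord(
                    chrom=chrom, pos=pos, ref=ref, alts=(alt,), qual=qual,
                    info=dict(info), calls=calls,
                )
            )
            truth_rows.append(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "sample": line,
                    "ref": ref,
                    "alt": alt,
                    "change12": change,
                    "category": category,
                    "region_label": region_label,
                    "ambiguous": is_ambig,
                    "quality_ok": quality_ok,
                }
            )

    records.sort(key=lambda r: (chrom_sort_key(r.chrom), r.pos))
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "chrom", "pos", "sample", "ref", "alt", "change12", "category",
            "region_label", "ambiguous", "quality_ok",
        ],
    ).sort_values(["sample", "chrom", "pos"], kind="stable").reset_index(drop=True)
    return records, truth


# ---------------------------------------------------------------------------
# structural regions

def generate_structural_regions(
    config: RegionConfig,
) -> tuple[list[GenomicInterval], list[tuple[str, int]]]:
    """Place non-overlapping regions on one chromosome and plant SNVs inside.

    Returns (intervals, planted (chrom, 1-based pos) pairs, all strictly
    inside their interval).
    """
    rng = np.random.default_rng(config.seed)
    total = sum(int(round(length_kb * 1000)) for length_kb, _, _ in config.regions)
    if total + config.min_gap * (len(config.regions) + 1) > config.chrom_length:
        raise ValueError("regions exceed chromosome length")
    intervals: list[GenomicInterval] = []
    planted: list[tuple[str, int]] = []
    cursor = 0
    for idx, (length_kb, event, n_snvs) in enumerate(config.regions):
        length = int(round(length_kb * 1000))
        start = cursor + int(rng.integers(config.min_gap, 2 * config.min_gap))
        end = start + length
        if end > config.chrom_length:
            raise ValueError("regions exceed chromosome length")
        label = f"{event}.{config.chrom}.{idx + 1}"
        iv = GenomicInterval(
            chrom=config.chrom, start=start, end=end, event=event, label=label
        )
        intervals.append(iv)
        if n_snvs > 0:
            offsets = rng.choice(length, size=n_snvs, replace=False)
            planted.extend((config.chrom, start + 1 + int(o)) for o in offsets)
        cursor = end
    return intervals, planted


# ---------------------------------------------------------------------------
# Q-FISH

def generate_qfish(
    sample_ratio: float,
    n_spreads: int,
    signals_per_spread: int = 92,
    dispersion: float = 0.45,
    seed: int = 0,
    sample_name: str = "sample",
    control_name: str = "control",
    n_control_spreads: Optional[int] = None,
    control_median: float = 8671.0,
) -> pd.DataFrame:
    """Lognormal telomere-intensity tables targeting a TFI ratio.

    Sample intensities have median ``control_median * sample_ratio``;
    control intensities have median ``control_median``. ``dispersion`` is
    the lognormal sigma; 0 gives degenerate (exact) intensities. Returns a
    long table with columns sample, spread_id, intensity.
    """
    if sample_ratio <= 0:
        raise ValueError("sample_ratio must be positive")
    if n_spreads < 1 or (n_control_spreads is not None and n_control_spreads < 1):
        raise ValueError("at least one spread per arm is required")
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    rng = np.random.default_rng(seed)
    n_control = n_control_spreads if n_control_spreads is not None else n_spreads
    rows: list[dict[str, object]] = []
    for name, n, median in (
        (sample_name, n_spreads, control_median * sample_ratio),
        (control_name, n_control, control_median),
    ):
        for k in range(n):
            if dispersion == 0:
                values = np.full(signals_per_spread, median)
            else:
                values = median * np.exp(
                    rng.normal(0.0, dispersion, size=signals_per_spread)
                )
            rows.extend(
                {"sample": name, "spread_id": f"{name}_{k + 1}",
                 "intensity": float(v)}
                for v in values
            )
    return pd.DataFrame(rows, columns=["sample", "spread_id", "intensity"])


# ---------------------------------------------------------------------------
# the fixed study-like scenario

@dataclass
class ScenarioBundle:
    """Every input of the full pipeline for the fixed study-like scenario."""

    records: list[VariantRecord]
    truth: pd.DataFrame
    regions: list[GenomicInterval]
    exclusion: list[tuple[str, int, str]]
    parental: str
    lines: tuple[str, ...]
    passages: dict[str, int]
    pd_per_passage: float
    qfish: dict[str, dict[str, object]]
    control_length_kbp: float = 6.91
    seed: int = 0


#: Table-1-like Q-FISH layout: sample -> (n spreads, target ratio,
#: control batch median, n control spreads)
_QFISH_LAYOUT = {
    "AT1OS": (4, 0.598, 8671.0, 5),
    "ATiPS-262": (8, 1.902, 8671.0, 5),
    "ATiPS-264": (12, 2.263, 7751.0, 7),
    "ATiPS-024": (14, 2.393, 7378.0, 10),
}


def scenario_paper(seed: int = 0) -> ScenarioBundle:
    """Fixed-seed bundle reproducing the study's accounting structure.

    212 candidate de novo SNVs across 4 derived lines, of which 2 fall in a
    23,314-kb CNLOH region and 37 in a 3,586-kb deletion (line ATiPS-262),
    1 in a 234-kb deletion (line ATiPS-024), and 5 are ambiguous calls on
    the manual exclusion list — so the pipeline ends at 167 SNVs split
    43/48/35/41. Also carries Q-FISH fixtures targeting the measured TFI
    ratios.
    """
    rng = np.random.default_rng(seed)
    sub = [int(s) for s in rng.integers(0, _MAX_SEED, size=8)]

    lines = DEFAULT_LINE_NAMES
    regions_262, _ = generate_structural_regions(
        RegionConfig(
            regions=[(23314.0, "CNLOH", 0), (3586.0, "deletion", 0)],
            chrom="chr1",
            chrom_length=50_000_000,
            seed=sub[0],
        )
    )
    regions_024, _ = generate_structural_regions(
        RegionConfig(
            regions=[(234.0, "deletion", 0)],
            chrom="chr4",
            chrom_length=50_000_000,
            seed=sub[1],
        )
    )
    regions = regions_262 + regions_024
    cnloh, del_262 = regions_262

    config = CohortConfig(
        n_sites=120,
        n_lines=4,
        # per-line candidates: clean + in-region + ambiguous
        somatic_per_line=(43 + 2 + 37 + 2, 48 + 1, 35 + 1, 41 + 1 + 1),
        ambiguous_per_line=(2, 1, 1, 1),
        depth_mean=90.0,
        ad_noise=0.0,
        seed=sub[2],
        planted_regions={
            "ATiPS-262": ((cnloh, 2), (del_262, 37)),
            "ATiPS-024": ((regions_024[0], 1),),
        },
    )
    records, truth = generate_cohort(config)
    exclusion = [
        (row.chrom, int(row.pos), row.sample)
        for row in truth[truth["ambiguous"]].itertuples(index=False)
    ]

    qfish: dict[str, dict[str, object]] = {}
    for i, (sample, (n_spreads, ratio, ctrl_median, n_ctrl)) in enumerate(
        _QFISH_LAYOUT.items()
    ):
        frame = generate_qfish(
            sample_ratio=ratio,
            n_spreads=n_spreads,
            n_control_spreads=n_ctrl,
            control_median=ctrl_median,
            sample_name=sample,
            control_name="TIG-1",
            seed=sub[3 + i],
        )
        qfish[sample] = {
            "frame": frame,
            "control": "TIG-1",
            "target_ratio": ratio,
            "control_length_kbp": 6.91,
        }

    return ScenarioBundle(
        records=records,
        truth=truth,
        regions=regions,
        exclusion=exclusion,
        parental=PARENTAL_NAME,
        lines=lines,
        passages=dict(DEFAULT_PASSAGES),
        pd_per_passage=DEFAULT_PD_PER_PASSAGE,
        qfish=qfish,
        seed=seed,
    )
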