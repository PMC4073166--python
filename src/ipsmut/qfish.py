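"""Q-FISH telomere-length quantification.

Telomere fluorescence intensities (TFI, arbitrary units) are scored for the
p- and q-arm telomeres of every chromosome in a metaphase spread. A spread
is summarised by its median TFI; a sample by the mean of its per-spread
medians. Telomere length follows by scaling a control line of known length:

    ratio  = sample TFI / control TFI        (reported at 3 decimals)
    length = ratio x control length in kbp   (reported at 2 decimals)

The reported length is computed from the 3-decimal ratio, matching the
arithmetic of the reference table this package reproduces; the unrounded
ratio is kept alongside. Each sample pairs with its own control batch —
control batches differ in TFI and the pairing is part of the input, never
inferred.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class MetaphaseSpread:
    """Per-telomere fluorescence intensities of one metaphase spread."""

    sample: str
    intensities: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.intensities) == 0:
            raise ValueError("a spread must carry at least one telomere signal")
        if any(v < 0 for v in self.intensities):
            raise ValueError("intensities must be non-negative")


@dataclass(frozen=True)
class TelomereResult:
    """Sample summary mirroring a telomere-length table row."""

    n_spreads: Optional[int]
    mean_median_tfi: float
    ratio: float  # sample/control TFI, rounded to 3 decimals
    length_kbp: float  # ratio x control length, rounded to 2 decimals
    raw_ratio: float  # unrounded sample/control TFI


def median_tfi(spread: MetaphaseSpread) -> float:
    """Median telomere fluorescent unit value of one spread."""
    return float(np.median(spread.intensities))


def sample_tfi(spreads: Sequence[MetaphaseSpread]) -> tuple[int, float]:
    """(number of spreads, mean over spreads of the per-spread median TFI)."""
    if len(spreads) == 0:
        raise ValueError("at least one metaphase spread is required")
    medians = [median_tfi(s) for s in spreads]
    return len(spreads), float(np.mean(medians))


def telomere_length(
    sample_tfi_value: float,
    control_tfi_value: float,
    control_length_kbp: float = 6.91,
    n_spreads: Optional[int] = None,
) -> TelomereResult:
    """Telomere length of a sample relative to a control of known length.

    The default control length, 6.91 kbp, is that of TIG-1 fibroblasts at
    34 population doublings.
    """
    if control_tfi_value <= 0:
        raise ValueError("control TFI must be positive")
    raw = sample_tfi_value / control_tfi_value
    ratio = round(raw, 3)
    length = round(ratio * control_length_kbp, 2)
    return TelomereResult(
        n_spreads=n_spreads,
        mean_median_tfi=sample_tfi_value,
        ratio=ratio,
        length_kbp=length,
        raw_ratio=raw,
    )


def quantify_telomeres(
    sample_spreads: Sequence[MetaphaseSpread],
    control_spreads: Sequence[MetaphaseSpread],
    control_length_kbp: float = 6.91,
) -> TelomereResult:
    """Full pipeline from intensity tables to a telomere length."""
    n, s_tfi = sample_tfi(sample_spreads)
    _, c_tfi = sample_tfi(control_spreads)
    return telomere_length(s_tfi, c_tfi, control_length_kbp, n_spreads=n)


def read_intensity_table(path: str) -> dict[str, list[MetaphaseSpread]]:
    """Read a TSV with columns sample, spread_id, intensity."""
    frame = pd.read_csv(path, sep="\t")
    required = {"sample", "spread_id", "intensity"}
    if not required.issubset(frame.columns):
        raise ValueError(f"intensity table must have columns {sorted(required)}")
    return spreads_from_frame(frame)


def spreads_from_frame(frame: pd.DataFrame) -> dict[str, list[MetaphaseSpread]]:
    """Group an intensity table into per-sample metaphase spreads."""
    out: dict[str, list[MetaphaseSpread]] = {}
    for (sample, _), group in frame.groupby(["sample", "spread_id"], sort=True):
        out.setdefault(str(sample), []).append(
            MetaphaseSpread(
                sample=str(sample),
                intensities=tuple(float(v) for v in group["intensity"]),
            )
        )
    return out
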