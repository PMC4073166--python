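"""Reprogramming efficiency and post-irradiation survival fractions."""

import numpy as np

from ipsmut import (
    efficiency_ratio,
    reprogramming_efficiency,
    survival_fraction,
)

# 10 colonies from 2.0e5 transduced ATM-deficient fibroblasts, versus an
# intact control line reprogrammed at 0.5% with the same protocol
at = reprogramming_efficiency(colonies=10, cells_plated=200_000)
control = reprogramming_efficiency(colonies=1000, cells_plated=200_000)
print(f"AT-line efficiency      : {at.efficiency_percent:g}%")
print(f"control-line efficiency : {control.efficiency_percent:g}%")
print(f"fold difference         : {efficiency_ratio(at, control):g}")

# survival two days after X-ray irradiation, quadruplicate counts
# normalised so non-irradiated cultures sit at 100%
rng = np.random.default_rng(5)
control_counts = 1e5 * (1 + 0.08 * rng.standard_normal(4))
for dose, true_survival in [(0.5, 0.8), (1.0, 0.45), (2.0, 0.2)]:
    irradiated = true_survival * 1e5 * (1 + 0.08 * rng.standard_normal(4))
    point = survival_fraction(irradiated.tolist(), control_counts.tolist(),
                              dose_gy=dose)
    print(f"{dose:>4} Gy: {point.percent_mean:5.1f}% +/- {point.percent_sd:.1f}%")
# each replicate is expressed relative to the mean non-irradiated count,
# so the numbers are comparable across clones and counting units.
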