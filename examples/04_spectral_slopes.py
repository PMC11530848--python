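"""Per-pixel PSD fits: passive vs active dynamics by log-log slope.

Each retained cell pixel's floor-subtracted PSD is fitted to
S(f) = A f^-m + B.  Passive (thermal) pixels show slopes near 1 + beta;
pixels inside motor-driven hotspots approach 2 (1 + beta).  The slope map
therefore separates the two regimes spatially.
"""

import numpy as np

from qpifluct import (
    AnalysisConfig, SimulationConfig, decorrelate_movie, default_region_mask,
    intracellular_power_map, psd_floor, slope_amplitude_maps, synthesize_movie,
)

config = SimulationConfig(seed=4)
movie, truth = synthesize_movie(config)
mask = default_region_mask(config)

dec = decorrelate_movie(movie, mask)
_, active = intracellular_power_map(dec.residual, dec.noise_power, mask.cell_mask())
floor = psd_floor(dec.residual, mask)
m_map, amp_map, fitted = slope_amplitude_maps(
    dec.residual, mask.cell_mask() & active, floor, AnalysisConfig()
)

hot = truth.class_map == 2
passive = truth.class_map == 1
print(f"fitted pixels: {fitted.sum()}")
print(f"mean slope in hotspots:        {np.nanmean(m_map[hot]):.2f}  "
      f"(active target 2(1+beta) = 2.3)")
print(f"mean slope in passive regions: {np.nanmean(m_map[passive]):.2f}  "
      f"(passive target 1+beta = 1.15)")
print(f"cell-mean amplitude at 0.01 Hz: {np.nanmean(amp_map):.1f} nm^2/Hz")
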