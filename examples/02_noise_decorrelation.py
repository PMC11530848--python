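"""Remove spatially correlated phase noise with background references.

Simulates a movie, extracts the three background reference signals, solves
the per-pixel linear model s = u + sum_i c_i r_i, and shows how far the
Pearson correlation with the references drops — and how the white-noise
power and the whole-cell dry-mass trace emerge after decorrelation.
"""

import numpy as np

from qpifluct import (
    SimulationConfig, cell_mass_series, decorrelate_movie, default_region_mask,
    pcc_map, synthesize_movie,
)

config = SimulationConfig(seed=2)
movie, truth = synthesize_movie(config)
mask = default_region_mask(config)

result = decorrelate_movie(movie, mask)

for i, lab in enumerate(result.references.labels):
    raw = np.nanmean(np.abs(pcc_map(movie, result.references.series[i])))
    done = np.nanmean(np.abs(pcc_map(result.residual, result.references.series[i])))
    print(f"reference {lab}: mean |PCC| raw {raw:.3f} -> processed {done:.2e}")
# in-sample least squares makes the residual orthogonal to the references,
# so the PCC collapses by many orders of magnitude

print(f"white-noise power from background residuals: {result.noise_power:.2f} nm^2")

cell = mask.cell_mask()
raw_trace = cell_mass_series(movie, cell)
clean_trace = cell_mass_series(result.residual, cell)
print(f"cell dry-mass variation sd: raw {raw_trace.variation.std():.3f} pg "
      f"-> decorrelated {clean_trace.variation.std():.3f} pg")
print("the raw trace is vibration noise; the decorrelated one is the cell")
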