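# qpifluct

Intracellular dry-mass fluctuation analysis for quantitative phase imaging
(QPI) time series.

Quantitative phase microscopy maps the optical path distance (OPD) through a
living cell, which is proportional to the dry-mass surface density of its
non-aqueous content. On the millisecond-to-second timescale, intracellular
dry-mass fluctuations carry information about the cell's metabolic state:
thermally driven (*passive*) fluctuations coexist with localized,
ATP-hydrolysis-driven (*active*) regions. Observing them is normally blocked
by temporal phase noise — chiefly mechanical vibrations that reach the whole
field of view with a smooth spatial footprint. `qpifluct` implements:

1. **Reference-signal noise decorrelation.** The OPD fluctuation at each
   pixel is modelled as
   `s(x,y,t) = u(x,y,t) + Σᵢ cᵢ(x,y) rᵢ(t)`,
   where `rᵢ(t)` are the spatially averaged OPD series of a few background
   regions far from any cell and `u` is the cell-intrinsic signal. Because
   `u` and the instrument noise are temporally uncorrelated, the covariances
   `⟨s rⱼ⟩ = Σᵢ cᵢ ⟨rᵢ rⱼ⟩` give a per-pixel linear system with a single
   shared Gram matrix; subtracting the fitted combination leaves the
   cell-intrinsic movie and a white residual background.
2. **Dry-mass conversion.** `σ = OPD/α` with the specific refractive index
   increment `α = 1.9×10⁻⁴ m³/kg` (1 nm OPD ≈ 5.26 fg/µm²); whole-cell mass
   traces in pg, with per-second drift re-centering of the cell mask.
3. **Fluctuation mapping.** Noise-corrected mean-square (MS) maps of the
   dry-mass density over the acquisition window; *hotspots* isolated as the
   connected clusters among the pixels that jointly carry 68.2 % of the
   cell's total MS; accumulation curves of MS vs area.
4. **Spectral analysis.** Per-pixel one-sided periodograms (exact Parseval
   normalization), a background PSD floor with a retention filter
   (PSD > 1.25 × floor at ≥ 70 % of frequencies), and the fit
   `S(f) = A f⁻ᵐ + B`: slopes `m` near `1+β` indicate passive dynamics,
   near `2(1+β)` active dynamics (β ≈ 0.1–0.2 is the viscoelastic
   power-law exponent of the cytoplasm).
5. **Phenotyping.** The five-parameter cell phenotype (RMS, hotspot count,
   mean hotspot area, power amplitude at 0.01 Hz, log slope), Tukey-fence
   outlier exclusion, 2-D kernel densities with 20 %-of-max contours, and
   split-train multinomial logistic classification.
6. **A synthetic-movie generator** with full ground truth — passive/active
   spectral models, round soft-edged hotspots, smooth correlated-noise
   coefficient maps, band-limited reference signals, white pixel noise —
   so the whole pipeline can be exercised and validated on generated data.

## Worked example

`examples/` holds one short script per capability. Decorrelation
(`examples/02_noise_decorrelation.py`) on a default synthetic movie
(64×64 pixels of 0.28 µm, 2000 frames at 20 fps, three correlated
reference-noise components, ~2.7 nm raw background pixel noise) prints:

```
reference 2: mean |PCC| raw 0.659 -> processed 1.35e-15
reference 3: mean |PCC| raw 0.626 -> processed 1.47e-15
reference 4: mean |PCC| raw 0.663 -> processed 1.39e-15
white-noise power from background residuals: 0.99 nm^2
cell dry-mass variation sd: raw 1.439 pg -> decorrelated 0.550 pg
```

The Pearson correlation of pixel series with the reference signals
collapses by many orders of magnitude, the residual background noise is
white at the configured 1 nm² power, and the whole-cell mass trace drops
from vibration-dominated to cell-intrinsic. Hotspot morphology
(`examples/03_hotspot_morphology.py`, strong-hotspot configuration):

```
cell RMS: 53.5 fg/um^2
7 hotspots (ground truth: 7), mean area 1.04 um^2
hotspots cover 6.4% of the cell area but carry 68.2% of its fluctuation power
50% of the MS is reached by the top 3.5% of pixels
```

and the spectral classification (`examples/04_spectral_slopes.py`):

```
mean slope in hotspots:        2.35  (active target 2(1+beta) = 2.3)
mean slope in passive regions: 1.23  (passive target 1+beta = 1.15)
```

A thin CLI wraps the same pipeline:

```bash
qpifluct simulate --seed 1 --out movie.h5 --truth truth.h5
qpifluct run --seed 1 --outdir results/run1   # simulate + decorrelate + analyze
```

## Layout

```
src/qpifluct/
  core_io.py      movie/mask data model, TIFF+HDF5 I/O, configs
  simulate.py     synthetic movies with ground truth
  decorrelate.py  reference extraction, PCC maps, the Gram solve
  drymass.py      OPD <-> dry mass, mass traces, drift correction
  fluctmap.py     MS maps, hotspot selection and labelling
  spectral.py     periodograms, PSD floor/filter, A f^-m + B fits
  phenotype.py    per-cell features, Tukey fences, 2-D PDFs, classification
  pipeline.py     end-to-end driver; cli.py: the qpifluct command
```

See `docs/methods.md` for the models, parameter choices, and limitations.
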