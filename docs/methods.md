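# Methods

## The measurement model

A quantitative phase movie records the optical path distance
`OPD(x, y, t)` (in nm; a phase map converts as `OPD = λφ/2π`). The
measured fluctuation at each pixel is modelled as

    s(x, y, t) = u(x, y, t) + Σᵢ cᵢ(x, y) rᵢ(t) + w(x, y, t)

* `u` — the cell-intrinsic dry-mass fluctuation, the signal of interest;
* `Σᵢ cᵢ rᵢ` — spatially correlated instrument noise: a few shared
  vibration signals `rᵢ(t)` entering every pixel with smooth coefficient
  maps `cᵢ(x, y)` set by the mechanics of the instrument;
* `w` — white, spatially uncorrelated sensor noise.

The references `rᵢ` are estimated as the spatially averaged OPD over
background regions far from any cell (three or four well-distributed
regions work best; collinear references are flagged at Gram condition
number > 10⁸ and solved by pseudo-inverse). Assuming `u`, `w` and the
vibrations are mutually uncorrelated in time,

    ⟨s rⱼ⟩ = Σᵢ cᵢ ⟨rᵢ rⱼ⟩

is an N×N system per pixel whose Gram matrix `⟨rᵢ rⱼ⟩` is shared across
the image: one factorization plus one covariance per pixel per reference.
Means are removed from `s` and `r` before forming covariances, which makes
the solve exactly per-pixel ordinary least squares with an intercept; the
residual movie is therefore orthogonal in-sample to every reference (the
PCC of residual vs reference is at numerical precision), and each pixel's
temporal mean — the static dry mass — is preserved.

The white-noise power is the mean temporal variance of the decorrelated
background pixels, a single scalar because the decorrelated background is
white and spatially uncorrelated (its n-pixel spatial averages scale as
1/n; a per-pixel variant is available behind `per_pixel_noise`). The
intracellular fluctuation power per pixel is the residual temporal
variance minus this noise power, clipped at zero; pixels count as *active*
when their raw variance exceeds `activity_threshold_factor` (default 2.0,
a design choice — "well above the noise" has no canonical value) times the
noise power.

## Dry-mass units

`σ = OPD/α` with `α = 1.9×10⁻⁴ m³/kg`, i.e. σ[fg/µm²] = OPD[nm] × 10⁻³/α
≈ 5.263 × OPD[nm]. MS maps are OPD power (nm²) times the squared factor;
whole-cell mass is σ summed over the mask times the pixel area, reported
in pg both absolutely and as variation about the temporal mean. Drift
correction re-registers 1 s window means against the first window by
integer-pixel cross-correlation inside the cell's padded bounding box; the
mask shape never changes, only its centre, and sub-pixel drift rounds to
zero (fluctuation metrics operate per fixed pixel, so sub-pixel
registration would resample the very signal being measured).

## Hotspots

Cell pixels are ranked by noise-corrected MS; the smallest prefix whose
cumulative MS reaches `hotspot_fraction` (default 0.682) of the total is
selected, with all pixels tied at the boundary value included so the
selection is deterministic and order-independent. Connected components
(default 8-connectivity; 4 is available) of the selection are the
hotspots, each reporting pixel count, area and MS share.

## Spectra

Per-pixel PSDs are one-sided boxcar periodograms with constant detrend and
density scaling — the combination for which the discrete Parseval identity
`Σ S(fₖ) Δf = Var(s)` is exact — over `[1/T_total, 1/(2Δt)]` (0.01–10 Hz
at the default 100 s / 20 fps), DC excluded. The PSD floor is the mean
periodogram over background pixels of the decorrelated movie. A cell
pixel is retained for fitting when its PSD exceeds `psd_floor_ratio`
(default 1.25) times the floor at a fraction of at least `psd_min_frac`
(default 0.70) of the frequency bins; the ratio reading "exceeds the floor
by 25 %" was chosen over "exceeds 0.25 × the floor" because the latter
would retain pixels below the noise floor, and both are configurable.

The floor-subtracted PSD is fitted to `S(f) = A f⁻ᵐ + B` by nonlinear
least squares in the log domain (`log S` vs `log(A f⁻ᵐ + B)` via
`logaddexp`, so A and B stay positive), initialized from the log-log
linear regression with B started at the median of the top frequency
decade. Non-positive differential bins are excluded rather than clipped,
to avoid log-domain bias; their count is a diagnostic. On non-convergence
the pure log-log line (B = 0) is returned with a flag. Frequencies are in
Hz throughout; the simulator uses the same convention, so slope targets
are self-consistent. The reported amplitude is the power-law component at
`amplitude_eval_freq` (default 0.01 Hz, the lowest resolved frequency),
`A·f⁻ᵐ` — the full model value including B is available behind
`amp_includes_offset`. `m > 0` is reported for decaying spectra.

Interpretation: passive (thermal) fluctuations in a viscoelastic medium
with complex stiffness ∝ (iω)^β give PSD slope `1+β`, with β ≈ 0.1–0.2 in
cells; motor-driven active fluctuations give `2(1+β)` well above the
crossover `1/(2πτ)` and `2β` well below it, τ = 5–10 s being the motor
processivity time. Fitted slopes therefore run from ≈1 (passive) to ≈2+
(active), scaling with ATP-dependent activity.

## Phenotype

Per cell: RMS = √(mean corrected MS over active pixels), hotspot count and
mean area, and the fitted-pixel means of amplitude and slope. Outliers are
excluded per feature by Tukey fences (Q1 − 1.5·IQR, Q3 + 1.5·IQR) with
linear-interpolation (type-7) quartiles. 2-D summaries use a Gaussian KDE
with Silverman's bandwidth and the conventional 20 %-of-maximum contour.
Classification is a stratified 50/50 split, feature standardization, and
multinomial logistic regression; the reported per-class score is the
within-class accuracy on the held-out half (the screening literature
sometimes calls this "specificity"; the conventional true-negative rate is
reported alongside to avoid ambiguity).

## The synthetic-data generator

All stochastic series come from spectral synthesis: the target one-sided
amplitude spectrum with i.i.d. uniform phases, inverse-transformed and
rescaled to an exact sample RMS. The per-bin modulus is deterministic, so
a single series' periodogram reproduces the target spectrum exactly; the
generator's contract is matching PSDs, not simulating the microrheological
force balance (no Langevin dynamics, no optical PSF).

Default study conditions: 64×64 pixels of 0.28 µm, 2000 frames at 20 fps
(100 s); a round cell of radius 6 µm on a smooth static OPD template
(peak 40 nm) so masks and dry-mass maps are meaningful; three reference
signals, band-limited below 0.5 Hz (building vibrations are
low-frequency-weighted; the exact instrument spectrum is a simulator
choice, not a claim), each of 1.3 nm RMS, entering through smooth
order-unity coefficient maps (Gaussian-filtered fields, 6 µm correlation
length, mean 1, fluctuation 0.5); plus 1.0 nm white pixel noise. Together
these put the raw background per-pixel temporal sd near 2.7 nm, the level
of a vibration-limited holographic microscope. The passive background uses
β = 0.15 and 25 fg/µm² RMS; seven active hotspots of radius 0.65 µm use
β = 0.15, τ = 7.5 s (mid-range of the stated 5–10 s) and 90 fg/µm² RMS,
which makes the hotspots carry roughly half the cell's total MS on a few
percent of its area — the regime observed in moderately active cancer
cells. Hotspot disks share one common active series (plus 15 % per-pixel
jitter) under a soft radial envelope `exp(−(d/r)²)`: coherent, round,
soft-edged structures. Cell pixels are otherwise temporally independent —
no spatial covariance of `u` is modelled, since none is specified by the
fluctuation theory; tests of cluster *morphology* beyond disk recovery
would not transfer to real data. Everything is reproducible bit-for-bit
from one seed (per-component child streams in fixed order).

What passing on synthetic data does **not** show: performance under
non-white sensor noise, under reference regions contaminated by cell
debris, under cell migration beyond integer-pixel drift, or for the
absolute cohort statistics of real cell lines — those depend on the
instrument and sample and are out of scope here.

## Numerical choices and problem sizes

* Coefficient-map solve: `np.linalg.solve` on the shared Gram matrix;
  pseudo-inverse with a warning above condition number 10⁸.
* Negative corrected powers clip to zero.
* Hotspot tie-break: all pixels tied at the boundary MS value enter.
* PSD fit bounds: m ∈ [−2, 8], A and B positive via log parametrization;
  at least 8 positive bins required.
* Reference-estimation leak: references averaged over small background
  regions carry ~1/√(region size) of the white noise, which leaves a small
  shared residual after decorrelation; large regions (or the generator's
  exact signals, in validation) remove it.
* Validation ensembles run at reduced sizes chosen to keep the whole suite
  in a few minutes — 100-series slope ensembles, 100-seed unbiasedness at
  32×32, 20-seed cluster recovery at the full 64×64×2000 scale — which are
  the scales at which the checked tolerances (±0.1 slope, 10 % power bias)
  are already well resolved.

## Known limitations

* The decorrelation assumes the correlated noise lies in the span of the
  references; unsampled vibration modes leak into the residual.
* Noise power is a spatial scalar by default; strong shading of the white
  noise across the field would bias corrected MS locally.
* The PSD fit assumes a single power law plus a constant; genuinely broken
  spectra (observable crossovers inside the band) are summarized by an
  intermediate slope.
* Whole-cell specificity numbers on real cohorts are not reproduced here;
  the classification machinery is validated on simulated cohorts only.
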