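"""Spatial decorrelation of temporal phase noise via background references.

Mechanical vibrations reach the sample with a smooth spatial footprint, so
the dominant temporal phase noise is *spatially correlated*: every pixel
sees a linear combination of a few shared vibration signals.  Averaging the
OPD over background regions far from any cell yields reference series
r_i(t) that sample those shared signals.  The measured OPD fluctuation at a
pixel is modelled as

    s(x, y, t) = u(x, y, t) + sum_i c_i(x, y) r_i(t)

with u the cell-intrinsic fluctuation.  Because u and the instrument noise
are uncorrelated in time, covariances with the references give, per pixel,
the N x N normal-equation system

    <s r_j> = sum_i c_i <r_i r_j>

whose Gram matrix G_ij = cov(r_i, r_j) is shared by every pixel — one
factorization, then one dot product per pixel per reference.  Subtracting
the fitted combination leaves the residual u*(x, y, t), which is exactly
the per-pixel ordinary-least-squares residual of s on (r_1..r_N, intercept)
and is therefore orthogonal in-sample to every reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core_io import OPDMovie, RegionMask

__all__ = [
    "ReferenceSet",
    "DecorrelationModel",
    "DecorrelationResult",
    "extract_references",
    "pcc_map",
    "fit_decorrelation",
    "apply_decorrelation",
    "estimate_noise_power",
    "intracellular_power_map",
    "decorrelate_movie",
    "spatial_averaging_variance",
]

COND_THRESHOLD = 1e8


@dataclass
class ReferenceSet:
    """Zero-mean reference series r_i(t) in nm, one per background region."""

    series: np.ndarray  # (N, T)
    labels: list[int]

    def __post_init__(self) -> None:
        self.series = np.atleast_2d(np.asarray(self.series, dtype=float))
        # zero-mean by construction; enforce to numerical precision
        self.series = self.series - self.series.mean(axis=1, keepdims=True)

    @property
    def n_refs(self) -> int:
        return self.series.shape[0]

    @property
    def n_frames(self) -> int:
        return self.series.shape[1]

    def gram(self) -> np.ndarray:
        """Sample covariance matrix <r_i r_j>, symmetric PSD."""
        return self.series @ self.series.T / self.n_frames


@dataclass
class DecorrelationModel:
    """Per-pixel coefficient maps c_i(x, y), one H x W map per reference."""

    coefficient_maps: np.ndarray  # (N, H, W)
    gram: np.ndarray  # (N, N)
    condition_number: float


@dataclass
class DecorrelationResult:
    """Residual movie plus the noise summary used downstream."""

    residual: OPDMovie  # cell-intrinsic movie u*(x, y, t)
    model: DecorrelationModel
    references: ReferenceSet
    noise_power: float  # nm^2, white-noise power from background residuals
    noise_power_map: np.ndarray | None = None  # optional per-pixel variant


def extract_references(movie: OPDMovie, mask: RegionMask) -> ReferenceSet:
    """Spatially averaged OPD over each background region, temporal mean removed."""
    labels = mask.background_labels()
    if not labels:
        raise ValueError("mask defines no background regions")
    series = []
    for lab in labels:
        region = mask.mask(lab)
        if not region.any():
            raise ValueError(f"background region {lab} is empty")
        r = movie.data[:, region].mean(axis=1)
        series.append(r - r.mean())
    return ReferenceSet(series=np.array(series), labels=labels)


def pcc_map(movie: OPDMovie, reference: np.ndarray) -> np.ndarray:
    """Per-pixel Pearson correlation of the pixel time series with a reference.

    Zero-variance pixels (no temporal signal at all) are undefined and
    returned as NaN; they are excluded rather than propagated by downstream
    summaries.
    """
    r = np.asarray(reference, dtype=float)
    if r.shape[0] != movie.n_frames:
        raise ValueError("reference length does not match the movie")
    r = r - r.mean()
    r_norm = np.sqrt((r**2).sum())
    data = movie.data - movie.data.mean(axis=0)
    num = np.einsum("t,thw->hw", r, data)
    denom = np.sqrt((data**2).sum(axis=0)) * r_norm
    out = np.full(movie.frame_shape, np.nan)
    ok = denom > 0
    out[ok] = num[ok] / denom[ok]
    return np.clip(out, -1.0, 1.0, out=out)


def fit_decorrelation(
    movie: OPDMovie, refs: ReferenceSet, cond_threshold: float = COND_THRESHOLD
) -> DecorrelationModel:
    """Solve the shared-Gram normal equations G c = b at every pixel.

    G_ij = cov(r_i, r_j) is computed once; b_j(x, y) = cov(s(x, y, .), r_j)
    varies per pixel.  Equivalent to per-pixel OLS of the pixel series on
    the references with an intercept (means are removed first).  A
    near-singular Gram matrix (collinear references) falls back to the
    pseudo-inverse with a warning naming the condition number.
    """
    T = movie.n_frames
    if refs.n_frames != T:
        raise ValueError("reference length does not match the movie")
    if T <= refs.n_refs:
        raise ValueError(f"need more frames ({T}) than references ({refs.n_refs})")
    G = refs.gram()
    cond = float(np.linalg.cond(G))
    data = movie.data - movie.data.mean(axis=0)
    b = np.einsum("nt,thw->nhw", refs.series, data) / T  # (N, H, W)
    b_flat = b.reshape(refs.n_refs, -1)
    if cond > cond_threshold:
        warnings.warn(
            f"reference Gram matrix is ill-conditioned (cond = {cond:.3g} > "
            f"{cond_threshold:.3g}); references are nearly collinear, using a "
            "pseudo-inverse solve",
            stacklevel=2,
        )
        c_flat = np.linalg.pinv(G) @ b_flat
    else:
        c_flat = np.linalg.solve(G, b_flat)
    maps = c_flat.reshape(refs.n_refs, *movie.frame_shape)
    return DecorrelationModel(coefficient_maps=maps, gram=G, condition_number=cond)


def apply_decorrelation(
    movie: OPDMovie, refs: ReferenceSet, model: DecorrelationModel
) -> OPDMovie:
    """Subtract the fitted correlated noise: u* = s - sum_i c_i r_i.

    The references are zero-mean, so each pixel's temporal mean (the static
    OPD, i.e. the dry mass) is preserved.  The residual's sample covariance
    with every reference is zero to numerical precision.
    """
    if model.coefficient_maps.shape[1:] != movie.frame_shape:
        raise ValueError("coefficient maps do not match the movie frame shape")
    if refs.n_frames != movie.n_frames:
        raise ValueError("reference length does not match the movie")
    fitted = np.einsum("nt,nhw->thw", refs.series, model.coefficient_maps)
    return movie.with_data(movie.data - fitted)


def estimate_noise_power(
    residual: OPDMovie, mask: RegionMask, per_pixel: bool = False
) -> float | np.ndarray:
    """White-noise power (nm^2) from the decorrelated background residual.

    After decorrelation the background noise is white and spatially
    uncorrelated, so a single scalar — the mean temporal variance over all
    background pixels — summarises it.  ``per_pixel=True`` instead returns
    the per-pixel variance map restricted to background pixels.
    """
    bg = mask.background_mask()
    if not bg.any():
        raise ValueError("mask defines no background pixels")
    var = residual.data[:, bg].var(axis=0)
    if per_pixel:
        out = np.full(residual.frame_shape, np.nan)
        out[bg] = var
        return out
    return float(var.mean())


def intracellular_power_map(
    residual: OPDMovie,
    noise_power: float,
    cell_mask: np.ndarray,
    threshold_factor: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-corrected fluctuation power per cell pixel, plus the active mask.

    power = max(temporal variance - noise_power, 0) inside the cell;
    a pixel is *active* (well above background noise) when its raw variance
    exceeds ``threshold_factor`` x noise_power.  Outside the cell the power
    map is NaN.
    """
    if noise_power < 0:
        raise ValueError("noise_power must be >= 0")
    cell_mask = np.asarray(cell_mask, bool)
    var = residual.data.var(axis=0)
    power = np.full(residual.frame_shape, np.nan)
    power[cell_mask] = np.clip(var[cell_mask] - noise_power, 0.0, None)
    active = cell_mask & (var > threshold_factor * noise_power)
    return power, active


def decorrelate_movie(
    movie: OPDMovie,
    mask: RegionMask,
    cond_threshold: float = COND_THRESHOLD,
    per_pixel_noise: bool = False,
) -> DecorrelationResult:
    """Full decorrelation pass: references, fit, subtract, noise power."""
    refs = extract_references(movie, mask)
    model = fit_decorrelation(movie, refs, cond_threshold=cond_threshold)
    residual = apply_decorrelation(movie, refs, model)
    noise_map = estimate_noise_power(residual, mask, per_pixel=True) if per_pixel_noise else None
    noise = estimate_noise_power(residual, mask)
    return DecorrelationResult(
        residual=residual,
        model=model,
        references=refs,
        noise_power=noise,
        noise_power_map=noise_map,
    )


def spatial_averaging_variance(
    residual: OPDMovie, region_mask: np.ndarray, n_pixels: list[int] | np.ndarray, seed: int = 0
) -> np.ndarray:
    """Temporal variance of the mean over random n-pixel subsets of a region.

    For white spatially uncorrelated residual noise the variance of an
    n-pixel spatial average falls as 1/n; correlated noise flattens this
    curve, which is how the benefit of decorrelation shows up in spatial
    averaging.  Returns one variance per entry of ``n_pixels``.
    """
    rng = np.random.default_rng(seed)
    idx = np.flatnonzero(np.asarray(region_mask, bool).ravel())
    flat = residual.data.reshape(residual.n_frames, -1)
    out = np.empty(len(n_pixels))
    for k, n in enumerate(n_pixels):
        if n > idx.size:
            raise ValueError(f"requested {n} pixels but region has only {idx.size}")
        pick = rng.choice(idx, size=n, replace=False)
        out[k] = flat[:, pick].mean(axis=1).var()
    return out
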