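"""Synthetic OPD movie generator with full ground truth.

Produces movies with the statistical structure the fluctuation-mapping
method assumes:

* a **passive** intracellular background whose one-sided PSD falls as
  ``f^-(1+beta)`` (thermal fluctuations in a viscoelastic medium with
  complex stiffness ~ (i w)^beta, beta typically 0.1-0.2);
* round **active** hotspots driven by molecular-motor force kicks, with
  PSD ~ ``f^-2beta / (1 + (2 pi f tau)^2)`` — log slope 2 beta well below
  the crossover 1/(2 pi tau) and 2 (1 + beta) well above it, tau being the
  motor processivity time (5-10 s);
* spatially **correlated instrument noise**: smooth coefficient maps
  c_i(x, y) multiplying shared band-limited reference series r_i(t),
  emulating building vibrations reaching the sample;
* white per-pixel sensor noise.

All stochastic series are built by spectral synthesis: the target one-sided
amplitude spectrum with i.i.d. uniform random phases, inverse-transformed
and rescaled to the requested RMS.  The per-bin modulus is deterministic,
so a single series' periodogram reproduces the target spectrum exactly —
the contract here is matching PSDs, not simulating the underlying force
balance.  Everything is reproducible bit-for-bit from the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import h5py
from scipy.ndimage import gaussian_filter

from .core_io import AcquisitionMeta, OPDMovie, RegionMask
from .drymass import dry_mass_to_opd

__all__ = [
    "FluctuationModel",
    "Hotspot",
    "SimulationConfig",
    "GroundTruth",
    "gen_powerlaw_series",
    "gen_active_series",
    "gen_reference_signals",
    "gen_coefficient_maps",
    "synthesize_movie",
    "default_region_mask",
    "write_ground_truth",
    "read_ground_truth",
]

CLASS_OUTSIDE = 0
CLASS_PASSIVE = 1
CLASS_ACTIVE = 2


@dataclass(frozen=True)
class FluctuationModel:
    """Spectral model of one fluctuation class.

    ``beta`` is the viscoelastic power-law exponent (in [0, 1)); ``tau``
    the motor processivity time in s (active kind only); ``amp`` the RMS
    amplitude in fg/um^2 of dry-mass surface density.
    """

    kind: str  # "passive" | "active"
    beta: float = 0.15
    tau: float = 7.5
    amp: float = 25.0

    def __post_init__(self) -> None:
        if self.kind not in ("passive", "active"):
            raise ValueError(f"kind must be 'passive' or 'active', got {self.kind!r}")
        if not 0 <= self.beta < 1:
            raise ValueError(f"beta must be in [0, 1), got {self.beta}")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.amp < 0:
            raise ValueError("amp must be >= 0")


@dataclass(frozen=True)
class Hotspot:
    """A round active region: centre in pixels (row, col), radius in um."""

    center: tuple[int, int]
    radius_um: float = 0.65
    model: FluctuationModel = field(
        default_factory=lambda: FluctuationModel("active", beta=0.15, tau=7.5, amp=90.0)
    )

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise ValueError("hotspot radius must be > 0")


@dataclass
class SimulationConfig:
    """Geometry, noise and fluctuation parameters of a synthetic movie.

    Defaults emulate the study conditions of the imaging experiments:
    2000 frames at 20 fps (100 s), 0.28 um pixels, three spatially
    correlated reference-noise components plus white pixel noise chosen so
    the background per-pixel temporal sd is ~2.7 nm, a passive background
    with beta = 0.15 and seven ~0.65 um active hotspots with tau = 7.5 s.
    """

    n_frames: int = 2000
    height: int = 64
    width: int = 64
    frame_interval: float = 0.05  # s
    pixel_size: float = 0.28  # um
    n_references: int = 3
    coeff_smoothness_um: float = 6.0
    correlated_noise_nm: float = 1.3  # RMS of each reference series; with 3
    # references and order-unity coefficient maps this puts the background
    # per-pixel sd near 2.7 nm together with the white component
    white_noise_nm: float = 1.0  # per-pixel white sd
    reference_cutoff_hz: float = 0.5
    cell_center: tuple[int, int] | None = None  # defaults to the frame centre
    cell_radius_um: float = 6.0
    template_peak_nm: float = 40.0
    background: FluctuationModel = field(
        default_factory=lambda: FluctuationModel("passive", beta=0.15, amp=25.0)
    )
    hotspots: list[Hotspot] | None = None  # None -> auto-place n_hotspots
    n_hotspots: int = 7
    hotspot_radius_um: float = 0.65
    hotspot_model: FluctuationModel = field(
        default_factory=lambda: FluctuationModel("active", beta=0.15, tau=7.5, amp=90.0)
    )
    hotspot_jitter_frac: float = 0.15
    hotspot_profile: str = "gaussian"  # "gaussian": amplitude ~ exp(-(d/r)^2),
    # a soft-edged round structure; "flat": uniform amplitude over the disk
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_references < 1:
            raise ValueError("n_references must be >= 1")
        if min(self.correlated_noise_nm, self.white_noise_nm) < 0:
            raise ValueError("noise amplitudes must be >= 0")
        if self.cell_center is None:
            self.cell_center = (self.height // 2, self.width // 2)

    @property
    def meta(self) -> AcquisitionMeta:
        return AcquisitionMeta(
            frame_interval=self.frame_interval,
            pixel_size=self.pixel_size,
            n_frames=self.n_frames,
        )


@dataclass
class GroundTruth:
    """Everything the generator knows that an analysis must recover."""

    coefficient_maps: np.ndarray  # (N, H, W)
    references: np.ndarray  # (N, T)
    clean_movie: np.ndarray  # (T, H, W) u(x, y, t), intracellular only
    white_noise: np.ndarray  # (T, H, W) realized sensor noise
    class_map: np.ndarray  # (H, W) 0 outside / 1 passive / 2 active
    hotspot_labels: np.ndarray  # (H, W) 0 or hotspot index (1-based)
    template: np.ndarray  # (H, W) static OPD offset
    cell_mask: np.ndarray  # (H, W) bool


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _spectral_synthesis(
    amplitude: np.ndarray, n: int, rms: float, rng: np.random.Generator, size: int | None
) -> np.ndarray:
    """Inverse-transform a one-sided amplitude spectrum with random phases.

    ``amplitude`` has length n//2 + 1 with the DC entry ignored (forced to
    zero).  Returns shape (n,) or (size, n); each series is rescaled to an
    exact sample RMS of ``rms``.
    """
    m = amplitude.shape[-1]
    shape = (m,) if size is None else (size, m)
    phase = rng.uniform(0.0, 2.0 * np.pi, size=shape)
    coeffs = amplitude * np.exp(1j * phase)
    coeffs[..., 0] = 0.0
    if n % 2 == 0:  # Nyquist bin of a real series must be real: random sign
        coeffs[..., -1] = amplitude[-1] * np.where(phase[..., -1] < np.pi, 1.0, -1.0)
    x = np.fft.irfft(coeffs, n=n, axis=-1)
    if rms == 0:
        return np.zeros_like(x)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x * (rms / sd)


def gen_powerlaw_series(
    n: int,
    dt: float,
    gamma: float,
    rms: float,
    seed: int | np.random.Generator = 0,
    size: int | None = None,
) -> np.ndarray:
    """Zero-mean series whose one-sided PSD falls as f^-gamma.

    Covers the band (1/(n dt), 1/(2 dt)).  gamma = 1 + beta is the passive
    intracellular spectrum; gamma = 0 gives white noise.  Deterministic for
    a given seed; ``size`` draws that many independent series at once
    (shape (size, n)).
    """
    if n < 16:
        raise ValueError(f"need n >= 16 to resolve a spectral band, got {n}")
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    f = np.fft.rfftfreq(n, dt)
    amp = np.zeros_like(f)
    amp[1:] = f[1:] ** (-gamma / 2.0)
    return _spectral_synthesis(amp, n, rms, _rng(seed), size)


def gen_active_series(
    n: int,
    dt: float,
    beta: float,
    tau: float,
    rms: float,
    seed: int | np.random.Generator = 0,
    size: int | None = None,
) -> np.ndarray:
    """Motor-driven series: one-sided PSD ~ f^-2beta / (1 + (2 pi f tau)^2).

    Asymptotic log-log slopes are 2 beta for f << 1/(2 pi tau) and
    2 (1 + beta) for f >> 1/(2 pi tau).  Warns if the crossover frequency
    falls outside the resolvable band, in which case only one regime is
    observable.
    """
    if n < 16:
        raise ValueError(f"need n >= 16 to resolve a spectral band, got {n}")
    if tau <= 0:
        raise ValueError("tau must be > 0")
    f_cross = 1.0 / (2.0 * np.pi * tau)
    f_lo, f_hi = 1.0 / (n * dt), 1.0 / (2.0 * dt)
    if not (f_lo <= f_cross <= f_hi):
        warnings.warn(
            f"active-spectrum crossover {f_cross:.3g} Hz lies outside the "
            f"resolved band [{f_lo:.3g}, {f_hi:.3g}] Hz; only one slope "
            "regime will be observable",
            stacklevel=2,
        )
    f = np.fft.rfftfreq(n, dt)
    amp = np.zeros_like(f)
    fi = f[1:]
    amp[1:] = fi ** (-beta) / np.sqrt(1.0 + (2.0 * np.pi * fi * tau) ** 2)
    return _spectral_synthesis(amp, n, rms, _rng(seed), size)


def gen_reference_signals(
    n_refs: int,
    n: int,
    dt: float,
    rms: float,
    cutoff_hz: float = 0.5,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """N mutually independent band-limited reference series, shape (N, T).

    Emulates building-vibration OPD picked up at background regions: zero
    mean, energy concentrated below ``cutoff_hz`` (second-order Lorentzian
    low-pass amplitude spectrum).  Independent draws, so pairwise sample
    correlations are small but not exactly zero.
    """
    if n_refs < 1:
        raise ValueError("n_refs must be >= 1")
    f = np.fft.rfftfreq(n, dt)
    amp = np.zeros_like(f)
    amp[1:] = 1.0 / (1.0 + (f[1:] / cutoff_hz) ** 2)
    return _spectral_synthesis(amp, n, rms, _rng(seed), size=n_refs)


def gen_coefficient_maps(
    height: int,
    width: int,
    n_refs: int,
    smoothness_um: float,
    pixel_size: float = 0.28,
    seed: int | np.random.Generator = 0,
    mean: float = 1.0,
    rel_amp: float = 0.5,
) -> np.ndarray:
    """Smooth order-unity coefficient maps c_i(x, y), shape (N, H, W).

    Gaussian-filtered random fields mimicking the smooth spatial footprint
    of mechanical vibration modes.  ``smoothness_um`` is the 1/e spatial
    autocorrelation length of the fluctuating part; in the limit where it
    far exceeds the frame, the maps are spatially constant.
    """
    if smoothness_um <= pixel_size:
        raise ValueError("smoothness must exceed the pixel size")
    rng = _rng(seed)
    sigma_px = smoothness_um / pixel_size / 2.0  # 1/e autocorr length = smoothness
    if sigma_px >= 4 * max(height, width):
        return np.full((n_refs, height, width), mean, dtype=float)
    maps = np.empty((n_refs, height, width))
    gain = 2.0 * np.sqrt(np.pi) * sigma_px  # unit-variance normalization in 2-D
    for i in range(n_refs):
        field_ = gaussian_filter(rng.standard_normal((height, width)), sigma_px, mode="wrap")
        maps[i] = mean + rel_amp * gain * field_
    return maps


def _cell_geometry(config: SimulationConfig):
    rr, cc = np.mgrid[0 : config.height, 0 : config.width]
    cy, cx = config.cell_center
    d_um = np.hypot(rr - cy, cc - cx) * config.pixel_size
    cell_mask = d_um <= config.cell_radius_um
    template = config.template_peak_nm * np.exp(-3.0 * (d_um / config.cell_radius_um) ** 2)
    template[~cell_mask] = 0.0
    return cell_mask, template


def _place_hotspots(config: SimulationConfig, cell_mask: np.ndarray, rng) -> list[Hotspot]:
    """Non-overlapping hotspot placement within the inner 70% of the cell."""
    if config.hotspots is not None:
        return list(config.hotspots)
    cy, cx = config.cell_center
    r_max_px = 0.7 * config.cell_radius_um / config.pixel_size
    rad_px = config.hotspot_radius_um / config.pixel_size
    centers: list[tuple[int, int]] = []
    attempts = 0
    while len(centers) < config.n_hotspots:
        attempts += 1
        if attempts > 10_000:
            raise RuntimeError("could not place hotspots without overlap; frame too small")
        ang = rng.uniform(0, 2 * np.pi)
        rad = r_max_px * np.sqrt(rng.uniform())
        p = (int(round(cy + rad * np.sin(ang))), int(round(cx + rad * np.cos(ang))))
        if all(np.hypot(p[0] - q[0], p[1] - q[1]) > 2.0 * (rad_px + 1.0) for q in centers):
            centers.append(p)
    return [
        Hotspot(center=c, radius_um=config.hotspot_radius_um, model=config.hotspot_model)
        for c in centers
    ]


def synthesize_movie(config: SimulationConfig) -> tuple[OPDMovie, GroundTruth]:
    """Assemble a synthetic movie: s = template + u + sum_i c_i r_i + white.

    ``u`` is the clean intracellular field — independent passive series on
    cell pixels plus, inside each hotspot disk, a shared active series with
    small per-pixel active jitter so clusters are coherent yet detectable.
    Bitwise reproducible for a fixed config (seed streams are spawned per
    component in a fixed order).
    """
    T, H, W = config.n_frames, config.height, config.width
    ss = np.random.SeedSequence(config.seed)
    rng_place, rng_coeff, rng_refs, rng_pass, rng_act, rng_white = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )

    cell_mask, template = _cell_geometry(config)
    hotspots = _place_hotspots(config, cell_mask, rng_place)

    rr, cc = np.mgrid[0:H, 0:W]
    hotspot_labels = np.zeros((H, W), dtype=np.int32)
    for k, h in enumerate(hotspots, start=1):
        if not (0 <= h.center[0] < H and 0 <= h.center[1] < W):
            raise ValueError(f"hotspot {k} centre {h.center} lies outside the frame")
        disk = np.hypot(rr - h.center[0], cc - h.center[1]) * config.pixel_size <= h.radius_um
        hotspot_labels[disk] = k

    class_map = np.zeros((H, W), dtype=np.int32)
    class_map[cell_mask] = CLASS_PASSIVE
    class_map[(hotspot_labels > 0) & cell_mask] = CLASS_ACTIVE

    # clean intracellular field u
    u = np.zeros((T, H, W))
    passive_px = class_map == CLASS_PASSIVE
    npass = int(passive_px.sum())
    if npass and config.background.amp > 0:
        rms_nm = float(dry_mass_to_opd(config.background.amp))
        series = gen_powerlaw_series(
            T, config.frame_interval, 1.0 + config.background.beta, rms_nm,
            seed=rng_pass, size=npass,
        )
        u[:, passive_px] = series.T
    if config.hotspot_profile not in ("gaussian", "flat"):
        raise ValueError(f"unknown hotspot_profile {config.hotspot_profile!r}")
    for k, h in enumerate(hotspots, start=1):
        disk = (hotspot_labels == k) & cell_mask
        ndisk = int(disk.sum())
        if ndisk == 0 or h.model.amp == 0:
            continue
        rms_nm = float(dry_mass_to_opd(h.model.amp))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # crossover band warning handled at config level
            common = gen_active_series(
                T, config.frame_interval, h.model.beta, h.model.tau, rms_nm, seed=rng_act
            )
            jitter = gen_active_series(
                T, config.frame_interval, h.model.beta, h.model.tau,
                config.hotspot_jitter_frac * rms_nm, seed=rng_act, size=ndisk,
            )
        if config.hotspot_profile == "gaussian":
            d_um = np.hypot(rr - h.center[0], cc - h.center[1])[disk] * config.pixel_size
            envelope = np.exp(-((d_um / h.radius_um) ** 2))
        else:
            envelope = np.ones(ndisk)
        u[:, disk] = (common[:, None] + jitter.T) * envelope

    refs = gen_reference_signals(
        config.n_references, T, config.frame_interval, config.correlated_noise_nm,
        cutoff_hz=config.reference_cutoff_hz, seed=rng_refs,
    )
    coeff_maps = gen_coefficient_maps(
        H, W, config.n_references, config.coeff_smoothness_um, config.pixel_size,
        seed=rng_coeff,
    )
    correlated = np.einsum("nt,nhw->thw", refs, coeff_maps)

    white = (
        rng_white.normal(0.0, config.white_noise_nm, size=(T, H, W))
        if config.white_noise_nm > 0
        else np.zeros((T, H, W))
    )

    data = template[None] + u + correlated + white
    movie = OPDMovie(data, config.meta)
    truth = GroundTruth(
        coefficient_maps=coeff_maps,
        references=refs,
        clean_movie=u,
        white_noise=white,
        class_map=class_map,
        hotspot_labels=hotspot_labels,
        template=template,
        cell_mask=cell_mask,
    )
    return movie, truth


def default_region_mask(
    config: SimulationConfig, n_background: int = 3, bg_size: int = 8, margin: int = 2
) -> RegionMask:
    """Label mask matching the simulated geometry: cell = 1, backgrounds 2+.

    Square background regions are placed in frame corners, well separated
    from the cell, mirroring the practice of picking distinct background
    patches far from any cell.  The square size shrinks automatically if
    the requested size would touch the cell.
    """
    H, W = config.height, config.width
    cell_mask, _ = _cell_geometry(config)
    for size in range(bg_size, 1, -1):
        img = np.zeros((H, W), dtype=np.int32)
        img[cell_mask] = 1
        corners = [
            (margin, margin),
            (margin, W - margin - size),
            (H - margin - size, margin),
            (H - margin - size, W - margin - size),
        ]
        roles = {1: "cell"}
        for i, (r0, c0) in enumerate(corners[:n_background], start=2):
            img[r0 : r0 + size, c0 : c0 + size] = i
            roles[i] = "background"
        try:
            return RegionMask(img, roles)
        except ValueError:
            continue
    raise ValueError("no room for background regions; cell fills the frame")


# ---------------------------------------------------------------------------
# ground-truth persistence

_GT_FIELDS = (
    "coefficient_maps", "references", "clean_movie", "white_noise",
    "class_map", "hotspot_labels", "template", "cell_mask",
)


def write_ground_truth(truth: GroundTruth, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w", track_order=True) as f:
        for name in _GT_FIELDS:
            arr = np.asarray(getattr(truth, name))
            f.create_dataset(name, data=arr, track_times=False)
    return path


def read_ground_truth(path: str | Path) -> GroundTruth:
    with h5py.File(path, "r") as f:
        kw = {name: np.asarray(f[name]) for name in _GT_FIELDS}
    kw["cell_mask"] = kw["cell_mask"].astype(bool)
    return GroundTruth(**kw)
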