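"""OPD <-> dry-mass conversion, whole-cell mass traces, and drift re-centering.

The dry-mass surface density follows sigma = OPD / alpha with alpha the
specific refractive index increment (default 1.9e-4 m^3/kg, a near-universal
constant for proteins, nucleic acids, carbohydrates and lipids).  With OPD
in nm and sigma in fg/um^2 the conversion is sigma = OPD * 1e-3 / alpha,
i.e. 1 nm of OPD corresponds to ~5.263 fg/um^2 at the default alpha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.registration import phase_cross_correlation

from .core_io import AcquisitionMeta, OPDMovie

__all__ = [
    "ALPHA_RI",
    "opd_to_dry_mass",
    "dry_mass_to_opd",
    "nm_to_sigma_factor",
    "MassSeries",
    "cell_mass_series",
    "correct_drift",
]

#: Specific refractive index increment, m^3/kg.
ALPHA_RI = 1.9e-4


def nm_to_sigma_factor(alpha_ri: float = ALPHA_RI) -> float:
    """Multiplicative factor converting OPD in nm to sigma in fg/um^2.

    1 nm = 1e-9 m of OPD gives sigma = 1e-9/alpha kg/m^2; 1 kg/m^2 is
    1e6 fg/um^2, hence the factor 1e-3/alpha.
    """
    if alpha_ri <= 0:
        raise ValueError(f"alpha_ri must be > 0, got {alpha_ri}")
    return 1e-3 / alpha_ri


def opd_to_dry_mass(opd_nm: np.ndarray | float, alpha_ri: float = ALPHA_RI):
    """Dry-mass surface density (fg/um^2) from OPD (nm): sigma = OPD/alpha."""
    return np.asarray(opd_nm, dtype=float) * nm_to_sigma_factor(alpha_ri)


def dry_mass_to_opd(sigma: np.ndarray | float, alpha_ri: float = ALPHA_RI):
    """Inverse conversion: OPD in nm from surface density in fg/um^2."""
    return np.asarray(sigma, dtype=float) / nm_to_sigma_factor(alpha_ri)


@dataclass
class MassSeries:
    """Whole-cell dry-mass time series.

    ``mass`` is the absolute integrated dry mass in pg; ``variation`` is the
    same trace re-centred on its temporal mean, which is how fluctuation
    traces are normally displayed.
    """

    t: np.ndarray
    mass: np.ndarray

    @property
    def variation(self) -> np.ndarray:
        return self.mass - self.mass.mean()


def cell_mass_series(
    movie: OPDMovie, cell_mask: np.ndarray, alpha_ri: float = ALPHA_RI
) -> MassSeries:
    """Integrate dry mass over a cell mask for every frame.

    mass(t) = sum_pixels sigma(x, y, t) * pixel_area, in pg.  Works on raw
    or decorrelated movies; decorrelated input is recommended since the
    correlated phase noise otherwise dominates the trace.
    """
    cell_mask = np.asarray(cell_mask, bool)
    if not cell_mask.any():
        raise ValueError("cell mask is empty")
    sigma = opd_to_dry_mass(movie.data[:, cell_mask], alpha_ri)  # (T, npix) fg/um^2
    pixel_area = movie.meta.pixel_size**2  # um^2
    mass_pg = sigma.sum(axis=1) * pixel_area * 1e-3  # fg -> pg
    return MassSeries(t=movie.times, mass=mass_pg)


def correct_drift(
    movie: OPDMovie,
    cell_mask: np.ndarray,
    interval: float = 1.0,
    search_radius: int = 10,
) -> np.ndarray:
    """Integer-pixel mask-centre trajectory correcting slow thermal drift.

    Frames are averaged over consecutive windows of ``interval`` seconds;
    each window mean is registered (integer-pixel cross-correlation) against
    the first window within the cell's padded bounding box.  The mask shape
    is kept constant; only its centre moves.

    Returns
    -------
    shifts : (n_intervals, 2) int array
        (row, col) translation of the cell in each interval relative to the
        first.  Sub-pixel drift rounds to 0.
    """
    dt = movie.meta.frame_interval
    per = int(round(interval / dt))
    if per < 1 or abs(per * dt - interval) > 1e-9:
        raise ValueError(f"interval {interval} s is not a multiple of the frame interval {dt} s")
    cell_mask = np.asarray(cell_mask, bool)
    if not cell_mask.any():
        raise ValueError("cell mask is empty")
    rows, cols = np.nonzero(cell_mask)
    pad = search_radius
    r0, r1 = max(rows.min() - pad, 0), min(rows.max() + pad + 1, cell_mask.shape[0])
    c0, c1 = max(cols.min() - pad, 0), min(cols.max() + pad + 1, cell_mask.shape[1])

    n_int = movie.n_frames // per
    if n_int < 1:
        raise ValueError("movie shorter than one drift interval")
    windows = movie.data[: n_int * per].reshape(n_int, per, *movie.frame_shape).mean(axis=1)
    ref = windows[0, r0:r1, c0:c1]
    shifts = np.zeros((n_int, 2), dtype=int)
    for k in range(1, n_int):
        cur = windows[k, r0:r1, c0:c1]
        # shift that moves the current window onto the reference; the cell's
        # displacement is the negative of it
        shift, _, _ = phase_cross_correlation(ref, cur, upsample_factor=1)
        shifts[k] = -np.round(shift).astype(int)
        if np.any(np.abs(shifts[k]) > search_radius):
            warnings.warn(
                f"drift of {tuple(shifts[k])} px in interval {k} exceeds the "
                f"search radius {search_radius}",
                stacklevel=2,
            )
    return shifts
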