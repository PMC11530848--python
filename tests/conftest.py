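import numpy as np
import pytest
from scipy import signal

from qpifluct.core_io import AcquisitionMeta, OPDMovie
from qpifluct.simulate import SimulationConfig, default_region_mask, synthesize_movie


def periodogram_slope(series: np.ndarray, dt: float, band=None) -> float:
    """Independent log-log periodogram regression oracle (no package fit code)."""
    f, p = signal.periodogram(series, fs=1.0 / dt, window="boxcar", detrend="constant")
    f, p = f[1:], p[1:]
    if band is not None:
        sel = (f >= band[0]) & (f <= band[1])
        f, p = f[sel], p[sel]
    ok = p > 0
    coef = np.polyfit(np.log(f[ok]), np.log(p[ok]), 1)
    return -coef[0]


def make_movie(data: np.ndarray, dt: float = 0.05, pixel_size: float = 0.28) -> OPDMovie:
    meta = AcquisitionMeta(frame_interval=dt, pixel_size=pixel_size, n_frames=data.shape[0])
    return OPDMovie(np.asarray(data, float), meta)


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    """A fast 24x24, 20 s movie with two hotspots."""
    return SimulationConfig(
        seed=42, n_frames=400, height=24, width=24,
        cell_radius_um=2.2, n_hotspots=2, template_peak_nm=20.0,
    )


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    movie, truth = synthesize_movie(small_cfg)
    mask = default_region_mask(small_cfg, bg_size=4)
    return movie, truth, mask
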