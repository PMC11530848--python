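"""Data model and file I/O for OPD image stacks, region masks, and configuration.

The central object is :class:`OPDMovie`, a calibrated T x H x W stack of
optical-path-distance (OPD) frames in nanometres together with its
acquisition metadata.  Movies are stored either as multi-page float32 TIFF
(with a JSON metadata sidecar) or as HDF5 (dataset ``"opd"``, metadata in
attributes).  Region masks are integer label images in which each label is
assigned a role, ``"cell"`` or ``"background"``.

Conventions: pixel indexing is 0-based row-major ``(row, col)``; the time
axis comes first; OPD is always held in nm internally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import h5py
import tifffile
import yaml
from skimage.measure import label as _cc_label
from scipy.ndimage import binary_dilation

__all__ = [
    "AcquisitionMeta",
    "OPDMovie",
    "RegionMask",
    "AnalysisConfig",
    "read_opd_stack",
    "write_opd_stack",
    "phase_to_opd",
    "read_label_mask",
    "write_label_mask",
]


@dataclass(frozen=True)
class AcquisitionMeta:
    """Acquisition metadata for an OPD movie.

    Parameters
    ----------
    frame_interval : float
        Time between frames in seconds (> 0).
    pixel_size : float
        Lateral pixel size in micrometres (> 0).
    n_frames : int
        Number of frames in the movie.
    wavelength : float, optional
        Illumination wavelength in nm; required only for phase-to-OPD
        conversion.
    opd_units : str
        Units of the stored OPD values; only ``"nm"`` is supported.
    """

    frame_interval: float
    pixel_size: float
    n_frames: int
    wavelength: float | None = None
    opd_units: str = "nm"

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError(f"frame_interval must be > 0, got {self.frame_interval}")
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        if self.n_frames < 0:
            raise ValueError("n_frames must be non-negative")
        if self.opd_units != "nm":
            raise ValueError(f"unsupported opd_units {self.opd_units!r}; use 'nm'")
        if self.wavelength is not None and self.wavelength <= 0:
            raise ValueError("wavelength must be > 0 when given")

    @property
    def duration(self) -> float:
        """Total movie duration in seconds (n_frames x frame_interval)."""
        return self.n_frames * self.frame_interval

    @property
    def frame_rate(self) -> float:
        return 1.0 / self.frame_interval

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionMeta":
        return cls(**{k: d[k] for k in ("frame_interval", "pixel_size", "n_frames")},
                   wavelength=d.get("wavelength"),
                   opd_units=d.get("opd_units", "nm"))


@dataclass
class OPDMovie:
    """A validated T x H x W OPD stack in nanometres with its metadata."""

    data: np.ndarray
    meta: AcquisitionMeta

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"movie data must be 3-D (T, H, W), got shape {self.data.shape}")
        if self.data.shape[0] != self.meta.n_frames:
            raise ValueError(
                f"frame count mismatch: data has {self.data.shape[0]} frames, "
                f"metadata says {self.meta.n_frames}"
            )
        bad = ~np.isfinite(self.data)
        if bad.any():
            frames = np.unique(np.nonzero(bad)[0])
            raise ValueError(f"non-finite OPD values in frame(s) {frames.tolist()}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    @property
    def times(self) -> np.ndarray:
        """Frame acquisition times in seconds, starting at 0."""
        return np.arange(self.n_frames) * self.meta.frame_interval

    def with_data(self, data: np.ndarray) -> "OPDMovie":
        """A new movie sharing this movie's metadata (frame count re-checked)."""
        meta = replace(self.meta, n_frames=int(np.asarray(data).shape[0]))
        return OPDMovie(data, meta)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OPDMovie):
            return NotImplemented
        return self.meta == other.meta and np.array_equal(self.data, other.data)


ROLE_CELL = "cell"
ROLE_BACKGROUND = "background"


@dataclass
class RegionMask:
    """Integer label image with a role (cell / background) per label.

    Background regions must each be spatially connected and must not touch
    any cell label (8-connectivity); cell and background labels are disjoint
    by construction of the label image.
    """

    label_image: np.ndarray
    roles: dict[int, str]

    def __post_init__(self) -> None:
        self.label_image = np.asarray(self.label_image)
        if self.label_image.ndim != 2:
            raise ValueError("label_image must be 2-D")
        if not np.issubdtype(self.label_image.dtype, np.integer):
            raise ValueError("label_image must be integer-valued")
        present = set(np.unique(self.label_image)) - {0}
        unknown = present - set(self.roles)
        if unknown:
            raise ValueError(f"labels {sorted(unknown)} present in image but have no role")
        bad_roles = {r for r in self.roles.values() if r not in (ROLE_CELL, ROLE_BACKGROUND)}
        if bad_roles:
            raise ValueError(f"unknown roles {sorted(bad_roles)}; use 'cell' or 'background'")
        self._validate_background()

    def _validate_background(self) -> None:
        cell = self.cell_mask()
        cell_halo = binary_dilation(cell, structure=np.ones((3, 3), bool))
        for lab in self.background_labels():
            region = self.label_image == lab
            if not region.any():
                continue
            if _cc_label(region, connectivity=2).max() > 1:
                raise ValueError(f"background region {lab} is not spatially connected")
            if (region & cell_halo).any():
                raise ValueError(f"background region {lab} touches a cell label")

    def cell_labels(self) -> list[int]:
        return sorted(l for l, r in self.roles.items() if r == ROLE_CELL)

    def background_labels(self) -> list[int]:
        return sorted(l for l, r in self.roles.items() if r == ROLE_BACKGROUND)

    def mask(self, lab: int) -> np.ndarray:
        return self.label_image == lab

    def cell_mask(self) -> np.ndarray:
        """Union of all cell labels as a boolean image."""
        out = np.zeros(self.label_image.shape, bool)
        for lab in self.cell_labels():
            out |= self.label_image == lab
        return out

    def background_mask(self) -> np.ndarray:
        out = np.zeros(self.label_image.shape, bool)
        for lab in self.background_labels():
            out |= self.label_image == lab
        return out


@dataclass
class AnalysisConfig:
    """Tunable parameters of the fluctuation-analysis pipeline.

    ``hotspot_fraction`` is the cumulative mean-square (MS) share used to
    isolate high-activity pixels; ``psd_floor_ratio``/``psd_min_frac``
    define the spectral pixel-retention filter (keep a pixel if its PSD
    exceeds ``psd_floor_ratio`` x floor at >= ``psd_min_frac`` of the
    frequencies); ``amplitude_eval_freq`` is where the fitted power-law
    component is evaluated; ``drift_interval`` is the mask re-centering
    cadence; ``activity_threshold_factor`` sets "well above background
    noise" (raw pixel variance > factor x white-noise power).
    """

    hotspot_fraction: float = 0.682
    psd_floor_ratio: float = 1.25
    psd_min_frac: float = 0.70
    amplitude_eval_freq: float = 0.01
    drift_interval: float = 1.0
    activity_threshold_factor: float = 2.0
    connectivity: int = 8
    amp_includes_offset: bool = False
    per_pixel_noise: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("hotspot_fraction", "psd_min_frac"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.psd_floor_ratio <= 0:
            raise ValueError("psd_floor_ratio must be positive")
        if self.amplitude_eval_freq <= 0:
            raise ValueError("amplitude_eval_freq must be positive")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")

    def validate_against(self, meta: AcquisitionMeta) -> None:
        if meta.duration > 0 and self.amplitude_eval_freq < 1.0 / meta.duration:
            raise ValueError(
                f"amplitude_eval_freq {self.amplitude_eval_freq} Hz is below the "
                f"resolution limit 1/duration = {1.0 / meta.duration:.4g} Hz"
            )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def phase_to_opd(phase_map: np.ndarray, wavelength: float) -> np.ndarray:
    """Convert a phase map in radians to OPD in nm: OPD = lambda * phi / (2 pi).

    Parameters
    ----------
    phase_map : array
        Phase in radians.
    wavelength : float
        Illumination wavelength in nm, > 0.
    """
    if wavelength <= 0:
        raise ValueError(f"wavelength must be > 0, got {wavelength}")
    return np.asarray(phase_map, dtype=float) * (wavelength / (2.0 * np.pi))


# ---------------------------------------------------------------------------
# movie I/O

_H5_DATASET = "opd"


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_opd_stack(movie: OPDMovie, path: str | Path) -> Path:
    """Write a movie as float32 multi-page TIFF (+ JSON sidecar) or HDF5.

    The format is chosen from the suffix: ``.h5``/``.hdf5`` for HDF5,
    anything else is written as TIFF.  HDF5 datasets are created with
    ``track_times=False`` so identical movies produce byte-identical files.
    """
    path = Path(path)
    if movie.n_frames == 0:
        raise ValueError("refusing to write an empty movie (T=0)")
    data = movie.data.astype(np.float32)
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "w", track_order=True) as f:
            ds = f.create_dataset(_H5_DATASET, data=data, track_times=False)
            for k, v in movie.meta.to_dict().items():
                if v is not None:
                    ds.attrs[k] = v
    else:
        tifffile.imwrite(path, data, photometric="minisblack")
        _sidecar_path(path).write_text(
            json.dumps(movie.meta.to_dict(), indent=1, sort_keys=True)
        )
    return path


def read_opd_stack(path: str | Path, meta: AcquisitionMeta | None = None) -> OPDMovie:
    """Read a movie from TIFF (+ sidecar) or HDF5 and validate it.

    Explicitly supplied ``meta`` overrides embedded metadata.  Raises if the
    file is missing, the data are not numeric T x H x W, or the frame count
    disagrees with the metadata.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            if _H5_DATASET not in f:
                raise ValueError(f"HDF5 file {path} has no '{_H5_DATASET}' dataset")
            ds = f[_H5_DATASET]
            data = np.asarray(ds, dtype=float)
            if meta is None:
                attrs = {k: ds.attrs[k] for k in ds.attrs}
                if "frame_interval" not in attrs:
                    raise ValueError(f"{path}: no acquisition metadata embedded or supplied")
                meta = AcquisitionMeta.from_dict(
                    {k: (v.item() if hasattr(v, "item") else v) for k, v in attrs.items()}
                )
    else:
        data = np.asarray(tifffile.imread(path), dtype=float)
        if meta is None:
            sidecar = _sidecar_path(path)
            if not sidecar.exists():
                raise ValueError(f"{path}: no metadata sidecar found and none supplied")
            meta = AcquisitionMeta.from_dict(json.loads(sidecar.read_text()))
    if data.ndim == 2:
        data = data[None]
    return OPDMovie(data, meta)


# ---------------------------------------------------------------------------
# mask I/O


def write_label_mask(mask: RegionMask, path: str | Path) -> Path:
    """Write a label image as 16-bit TIFF/PNG with a JSON role sidecar."""
    path = Path(path)
    img = mask.label_image.astype(np.uint16)
    if path.suffix.lower() == ".png":
        import imageio.v3 as iio

        iio.imwrite(path, img)
    else:
        tifffile.imwrite(path, img)
    _sidecar_path(path).write_text(
        json.dumps({str(k): v for k, v in mask.roles.items()}, indent=1, sort_keys=True)
    )
    return path


def read_label_mask(path: str | Path, roles: dict[int, str] | None = None) -> RegionMask:
    """Read an integer label image plus its role table and validate it."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".png":
        import imageio.v3 as iio

        img = np.asarray(iio.imread(path))
    else:
        img = np.asarray(tifffile.imread(path))
    if roles is None:
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise ValueError(f"{path}: no role table sidecar found and none supplied")
        roles = {int(k): v for k, v in json.loads(sidecar.read_text()).items()}
    return RegionMask(img.astype(np.int32), roles)
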