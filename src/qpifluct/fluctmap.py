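"""Spatial analysis of fluctuation power: MS maps, hotspots, accumulation.

The mean-square (MS) map is the noise-corrected temporal variance of the
dry-mass surface density over an acquisition window, per pixel.  Hotspots —
the localized regions of intense ATP-driven activity — are isolated by
ranking cell pixels by MS and keeping the smallest set that carries a fixed
share (default 68.2%) of the cell's total MS, then labelling connected
components of that set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.measure import label as cc_label

from .core_io import AcquisitionMeta
from .drymass import ALPHA_RI, nm_to_sigma_factor

__all__ = ["MSMap", "HotspotSet", "ms_map", "select_hotspots", "label_clusters",
           "accumulation_curve"]


@dataclass
class MSMap:
    """Noise-corrected MS of dry-mass density, (fg/um^2)^2, NaN outside the cell."""

    ms: np.ndarray  # (H, W)
    window: float  # s
    pixel_size: float  # um

    def cell_pixels(self) -> np.ndarray:
        return np.isfinite(self.ms)

    @property
    def total(self) -> float:
        return float(np.nansum(self.ms))


@dataclass
class HotspotSet:
    """Connected high-activity clusters with their morphology table.

    ``table`` columns: cluster id, n_pixels, area_um2, ms_sum, ms_share.
    ``mean_area`` is NaN (flagged) when there are no clusters.
    """

    label_image: np.ndarray
    table: pd.DataFrame
    fraction: float
    pixel_size: float

    @property
    def n_clusters(self) -> int:
        return len(self.table)

    @property
    def mean_area(self) -> float:
        return float(self.table["area_um2"].mean()) if self.n_clusters else float("nan")


def ms_map(
    power_nm2: np.ndarray, meta: AcquisitionMeta, alpha_ri: float = ALPHA_RI
) -> MSMap:
    """Convert a corrected OPD power map (nm^2) to dry-mass MS units.

    ms = power * (nm -> fg/um^2 factor)^2, i.e. one nm^2 of OPD variance is
    ~27.7 (fg/um^2)^2 at the default refractive increment.
    """
    factor = nm_to_sigma_factor(alpha_ri) ** 2
    return MSMap(ms=np.asarray(power_nm2, float) * factor,
                 window=meta.duration, pixel_size=meta.pixel_size)


def select_hotspots(
    msmap: MSMap, cell_mask: np.ndarray | None = None, fraction: float = 0.682
) -> np.ndarray:
    """Pixels carrying the top ``fraction`` of the cell's total MS.

    Pixels are ranked by MS descending and accumulated until the cumulative
    MS first reaches ``fraction`` x total.  All pixels tied at the boundary
    MS value are included, making the selection deterministic and
    independent of sort order.  Zero-MS pixels are never selected.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    mask = msmap.cell_pixels() if cell_mask is None else np.asarray(cell_mask, bool)
    mask = mask & np.isfinite(msmap.ms) & (msmap.ms > 0)
    values = msmap.ms[mask]
    if values.size == 0:
        raise ValueError("no positive-MS cell pixels to select from")
    order = np.sort(values)[::-1]
    csum = np.cumsum(order)
    k = int(np.searchsorted(csum, fraction * csum[-1]))
    boundary = order[min(k, order.size - 1)]
    return mask & (msmap.ms >= boundary)


def label_clusters(
    selected: np.ndarray, msmap: MSMap, connectivity: int = 8, fraction: float = float("nan")
) -> HotspotSet:
    """Connected-component labelling of the selected pixel set.

    ``connectivity`` is 4 or 8 (2-D neighbourhood).  Cluster areas are
    pixel counts times pixel_size^2; MS shares are relative to the total
    cell MS.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    skimage_conn = 1 if connectivity == 4 else 2
    labels = cc_label(np.asarray(selected, bool), connectivity=skimage_conn)
    total = msmap.total
    rows = []
    for lab in range(1, labels.max() + 1):
        in_cluster = labels == lab
        n = int(in_cluster.sum())
        ms_sum = float(np.nansum(msmap.ms[in_cluster]))
        rows.append({
            "cluster": lab,
            "n_pixels": n,
            "area_um2": n * msmap.pixel_size**2,
            "ms_sum": ms_sum,
            "ms_share": ms_sum / total if total > 0 else np.nan,
        })
    table = pd.DataFrame(rows, columns=["cluster", "n_pixels", "area_um2", "ms_sum", "ms_share"])
    return HotspotSet(label_image=labels, table=table, fraction=fraction,
                      pixel_size=msmap.pixel_size)


def accumulation_curve(msmap: MSMap, cell_mask: np.ndarray | None = None):
    """Relative accumulated area vs relative accumulated MS, highest MS first.

    Both axes normalized to 1; the curve is non-decreasing and concave
    (each additional pixel adds no more MS than the previous one).  Returns
    (area_frac, ms_frac) arrays of length n_pixels.
    """
    mask = msmap.cell_pixels() if cell_mask is None else np.asarray(cell_mask, bool)
    values = msmap.ms[mask & np.isfinite(msmap.ms)]
    if values.size == 0:
        raise ValueError("empty MS map")
    order = np.sort(values)[::-1]
    ms_frac = np.cumsum(order)
    total = ms_frac[-1]
    if total > 0:
        ms_frac = ms_frac / total
    area_frac = np.arange(1, order.size + 1) / order.size
    return area_frac, ms_frac
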