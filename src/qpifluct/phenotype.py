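"""Per-cell phenotype features, outlier filtering, 2-D PDFs, classification.

Five numbers summarise one cell's fluctuation phenotype: the RMS of the
dry-mass density fluctuations, the number of high-activity clusters, their
mean area, the fitted power amplitude at 0.01 Hz, and the mean PSD log
slope.  A cohort of such rows supports Tukey-fence outlier removal,
kernel-density 2-D summaries with 20 %-of-max contours, and a 50/50
split-train multinomial logistic classification reporting per-class
recall (the accuracy within each true class) alongside the conventional
true-negative-rate specificity.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .fluctmap import MSMap, HotspotSet

__all__ = [
    "CellPhenotype",
    "FEATURES",
    "summarize_cell",
    "tukey_filter",
    "pdf2d",
    "classify",
]

FEATURES = ("rms", "n_hotspots", "mean_hotspot_area", "amp001", "slope")


@dataclass
class CellPhenotype:
    """Five-parameter fluctuation phenotype of a single cell.

    ``rms`` in fg/um^2 over the noise-corrected active pixels; areas in
    um^2; ``amp001`` is the fitted power-law amplitude at 0.01 Hz; spectral
    fields are NaN when no pixel survived the PSD filter.
    """

    cell_id: str
    rms: float
    n_hotspots: int
    mean_hotspot_area: float
    amp001: float
    slope: float
    condition: str = ""
    n_fitted_pixels: int = 0

    def to_row(self) -> dict:
        return asdict(self)


def summarize_cell(
    msmap: MSMap,
    hotspots: HotspotSet,
    m_map: np.ndarray,
    amp_map: np.ndarray,
    active_mask: np.ndarray | None = None,
    cell_id: str = "cell",
    condition: str = "",
) -> CellPhenotype:
    """Collapse one cell's maps into the five-parameter phenotype.

    rms = sqrt(mean corrected MS) over the active cell pixels (or all
    finite MS pixels when no activity mask is given); hotspot count and
    mean area come from the cluster table; spectral means ignore unfit
    (NaN) pixels.
    """
    if active_mask is not None:
        sel = np.asarray(active_mask, bool) & np.isfinite(msmap.ms)
    else:
        sel = np.isfinite(msmap.ms)
    rms = float(np.sqrt(msmap.ms[sel].mean())) if sel.any() else 0.0
    fitted = np.isfinite(m_map)
    n_fitted = int(fitted.sum())
    slope = float(np.nanmean(m_map)) if n_fitted else float("nan")
    amp = float(np.nanmean(amp_map)) if n_fitted else float("nan")
    return CellPhenotype(
        cell_id=cell_id,
        rms=rms,
        n_hotspots=hotspots.n_clusters,
        mean_hotspot_area=hotspots.mean_area,
        amp001=amp,
        slope=slope,
        condition=condition,
        n_fitted_pixels=n_fitted,
    )


def tukey_filter(values: np.ndarray, return_mask: bool = False):
    """Tukey-fence outlier exclusion: keep Q1 - 1.5 IQR <= v <= Q3 + 1.5 IQR.

    Quartiles use linear interpolation (numpy's default, the type-7
    estimator).  Requires at least 4 values.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError(f"need at least 4 values for Tukey fences, got {v.size}")
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    keep = (v >= q1 - 1.5 * iqr) & (v <= q3 + 1.5 * iqr)
    return (v[keep], keep) if return_mask else v[keep]


def pdf2d(
    x: np.ndarray,
    y: np.ndarray,
    gridsize: int = 128,
    bandwidth: float | str | None = None,
    pad: float = 0.25,
):
    """Gaussian-kernel 2-D density with its 20 %-of-maximum contour level.

    Returns (X, Y, density, level): meshgrid coordinates, the density
    evaluated on the grid, and the iso-level at 0.2 x max density — the
    contour conventionally drawn around a condition's data cloud.
    Bandwidth defaults to Silverman's rule.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 10:
        raise ValueError("need at least 10 points for a 2-D PDF")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("degenerate (zero-variance) axis")
    kde = gaussian_kde(np.vstack([x, y]), bw_method=bandwidth or "silverman")
    dx = x.max() - x.min()
    dy = y.max() - y.min()
    xs = np.linspace(x.min() - pad * dx, x.max() + pad * dx, gridsize)
    ys = np.linspace(y.min() - pad * dy, y.max() + pad * dy, gridsize)
    X, Y = np.meshgrid(xs, ys)
    density = kde(np.vstack([X.ravel(), Y.ravel()])).reshape(X.shape)
    level = 0.2 * density.max()
    return X, Y, density, level


def classify(
    cohort: pd.DataFrame,
    features: tuple[str, ...] = FEATURES,
    label_col: str = "condition",
    split: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Split-train multinomial logistic classification of cell phenotypes.

    The cohort is stratified-split (default 50/50) into train and
    evaluation halves; features are standardized; per class the returned
    table reports the within-class accuracy (``recall`` — the proportion
    of instances of that class predicted correctly, which is how the
    screening literature sometimes labels "specificity") and the
    conventional true-negative-rate ``specificity``.
    """
    labels = cohort[label_col].to_numpy()
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    counts = pd.Series(labels).value_counts()
    if (counts < 10).any():
        raise ValueError("need at least 10 cells per class")
    X = cohort.loc[:, list(features)].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values; filter the cohort first")
    X_tr, X_ev, y_tr, y_ev = train_test_split(
        X, labels, test_size=split, stratify=labels, random_state=seed
    )
    model = make_pipeline(StandardScaler(), LogisticRegression(max_iter=2000))
    model.fit(X_tr, y_tr)
    pred = model.predict(X_ev)
    rows = []
    for cls in classes:
        is_cls = y_ev == cls
        recall = float((pred[is_cls] == cls).mean())
        tn = float((pred[~is_cls] != cls).mean())
        rows.append({"class": cls, "n_eval": int(is_cls.sum()),
                     "recall": recall, "specificity": tn})
    return pd.DataFrame(rows)
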