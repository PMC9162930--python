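"""Aggregation of per-ROI thicknesses and correlation with performance data.

The measurement hierarchy mirrors the experimental design: ten ROIs per
z-image give an image mean, ten z-images per electrode give the electrode
mean with an SD that quantifies how homogeneously the biofilm covers the
electrode, and replicate electrodes per condition give the condition-level
mean ± SD. Thickness is finally correlated (Pearson) against performance
indicators such as the maximum current density of a microbial fuel cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ImageSummary",
    "ElectrodeSummary",
    "CorrelationResult",
    "summarize_image",
    "summarize_electrode",
    "summarize_condition",
    "pearson",
    "homogeneity_report",
]


@dataclass
class ImageSummary:
    """Descriptive statistics of the measured ROI thicknesses of one z-image."""

    image_id: str
    n_roi_measured: int
    mean_um: Optional[float] = None
    sd_um: Optional[float] = None
    median_um: Optional[float] = None
    q1_um: Optional[float] = None
    q3_um: Optional[float] = None
    min_um: Optional[float] = None
    max_um: Optional[float] = None

    def as_dict(self) -> dict:
        return {
            "image_id": self.image_id,
            "n_roi_measured": self.n_roi_measured,
            "mean_um": self.mean_um,
            "sd_um": self.sd_um,
            "median_um": self.median_um,
            "q1_um": self.q1_um,
            "q3_um": self.q3_um,
            "min_um": self.min_um,
            "max_um": self.max_um,
        }


@dataclass
class ElectrodeSummary:
    """Electrode-level mean of image means; SD across the z-images."""

    electrode_id: str
    n_images: int
    mean_um: Optional[float]
    sd_um: Optional[float]
    per_image: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "electrode_id": self.electrode_id,
            "n_images": self.n_images,
            "mean_um": self.mean_um,
            "sd_um": self.sd_um,
        }


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with a two-sided t-test p-value."""

    r: float
    p: float
    n: int

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError("r outside [-1, 1]")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p outside [0, 1]")
        if self.n < 3:
            raise ValueError("n must be >= 3")


def _thicknesses(results) -> np.ndarray:
    vals = [r.thickness_um for r in results if r.thickness_um is not None]
    return np.asarray(vals, dtype=float)


def summarize_image(results: Sequence) -> ImageSummary:
    """Summarise the ROI thicknesses of one z-image.

    Missing thicknesses (undetected boundaries) are excluded; quartiles use
    linear interpolation and the SD is the sample SD (n−1 denominator).
    """
    results = list(results)
    if not results:
        raise ValueError("need at least one result")
    image_ids = {r.image_id for r in results}
    if len(image_ids) != 1:
        raise ValueError(f"results span multiple images: {sorted(image_ids)}")
    image_id = results[0].image_id
    t = _thicknesses(results)
    if len(t) == 0:
        return ImageSummary(image_id=image_id, n_roi_measured=0)
    q1, med, q3 = np.percentile(t, [25, 50, 75])
    return ImageSummary(
        image_id=image_id,
        n_roi_measured=int(len(t)),
        mean_um=float(np.mean(t)),
        sd_um=float(np.std(t, ddof=1)) if len(t) >= 2 else None,
        median_um=float(med),
        q1_um=float(q1),
        q3_um=float(q3),
        min_um=float(np.min(t)),
        max_um=float(np.max(t)),
    )


def summarize_electrode(
    images: Sequence[ImageSummary],
    electrode_id: str = "electrode",
) -> ElectrodeSummary:
    """Aggregate image summaries to one electrode.

    The electrode mean is the unweighted mean of the image means; the SD is
    the sample SD across image means, i.e. the spread over the z-images
    scattered across the electrode surface, not the pooled ROI SD.
    """
    images = list(images)
    if not images:
        raise ValueError("need at least one image summary")
    means = [s.mean_um for s in images if s.mean_um is not None]
    if not means:
        return ElectrodeSummary(electrode_id, len(images), None, None, images)
    mean = float(np.mean(means))
    sd = float(np.std(means, ddof=1)) if len(means) >= 2 else None
    return ElectrodeSummary(electrode_id, len(images), mean, sd, images)


def summarize_condition(electrodes: Sequence[ElectrodeSummary]) -> dict:
    """Replicate-level mean ± SD across electrodes sharing one condition."""
    electrodes = list(electrodes)
    if not electrodes:
        raise ValueError("need at least one electrode summary")
    means = [e.mean_um for e in electrodes if e.mean_um is not None]
    if not means:
        return {"n_electrodes": len(electrodes), "mean_um": None, "sd_um": None}
    return {
        "n_electrodes": len(electrodes),
        "mean_um": float(np.mean(means)),
        "sd_um": float(np.std(means, ddof=1)) if len(means) >= 2 else None,
    }


def pearson(x: Iterable[float], y: Iterable[float]) -> CorrelationResult:
    """Pearson r with two-sided p from t = r·sqrt((n−2)/(1−r²)), df = n−2.

    This is the classical test used by correlation routines in statistical
    packages. Constant input raises, as r is then undefined.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D sequences of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    xd = x - x.mean()
    yd = y - y.mean()
    sx = math.sqrt(float(xd @ xd))
    sy = math.sqrt(float(yd @ yd))
    if sx == 0 or sy == 0:
        raise ValueError("correlation undefined for constant input")
    r = float(xd @ yd) / (sx * sy)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return CorrelationResult(r=r, p=p, n=n)


def homogeneity_report(images: Sequence[ImageSummary]) -> pd.DataFrame:
    """Per-position five-number summaries with a heterogeneity flag.

    Positions are the image order (z-images are taken at known locations on
    the electrode). A position is flagged when its median thickness lies
    outside the Tukey fences (Q1 − 1.5×IQR, Q3 + 1.5×IQR) of the pooled
    per-image medians — a descriptive outlier indicator in the boxplot
    tradition, not a hypothesis test.
    """
    images = list(images)
    if len(images) < 2:
        raise ValueError("need at least 2 image summaries")
    rows = []
    medians = np.asarray(
        [s.median_um for s in images if s.median_um is not None], dtype=float
    )
    if len(medians):
        q1, q3 = np.percentile(medians, [25, 75])
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    for pos, s in enumerate(images, start=1):
        flagged = (
            s.median_um is not None
            and len(medians) > 0
            and not (lo <= s.median_um <= hi)
        )
        rows.append(
            {
                "position": pos,
                "image_id": s.image_id,
                "n_roi_measured": s.n_roi_measured,
                "min_um": s.min_um,
                "q1_um": s.q1_um,
                "median_um": s.median_um,
                "q3_um": s.q3_um,
                "max_um": s.max_um,
                "heterogeneous": bool(flagged),
            }
        )
    return pd.DataFrame(rows)
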