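"""Tissue hydration, swelling-volume and AUC analyses.

Hydration is water mass over wet mass (the convention under which
healthy brain sits at 85-92%).  Swelling is tracked as the planar (XY)
area of a slice photographed from above; under the isotropic-swelling
assumption the volume ratio is the area ratio raised to 3/2.  Total
swelling over an experiment is compared via the trapezoidal area under
the volume-ratio time course.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as label_components

from .errors import DomainError, InvalidInputError, SegmentationError

__all__ = [
    "MassRecord",
    "AreaSeries",
    "hydration_percent",
    "segment_slice_area",
    "planar_to_volume_ratio",
    "swelling_timecourse",
    "auc_trapezoid",
    "summarize_group",
]


@dataclass(frozen=True)
class MassRecord:
    """Wet/dry mass of a pooled slice sample (mg)."""

    wet_mass: float
    dry_mass: float
    condition: str = ""
    time_h: float = 0.0
    animal_id: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.dry_mass <= self.wet_mass:
            raise InvalidInputError(
                f"need 0 < dry ({self.dry_mass}) <= wet ({self.wet_mass})"
            )


@dataclass
class AreaSeries:
    """Planar slice areas over time for one animal in one condition.

    The first timepoint (0.5 h, the earliest a slice can be mounted and
    photographed) serves as the swelling baseline.
    """

    time_h: np.ndarray
    planar_area: np.ndarray
    condition: str = ""
    animal_id: str = ""

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.planar_area = np.asarray(self.planar_area, dtype=float)
        if self.time_h.shape != self.planar_area.shape:
            raise InvalidInputError("time and area must have equal length")
        if self.time_h.size == 0:
            raise InvalidInputError("empty area series")
        if np.any(np.diff(self.time_h) <= 0):
            raise InvalidInputError("timepoints must be strictly increasing")
        if np.any(self.planar_area <= 0):
            raise InvalidInputError("areas must be positive")


def hydration_percent(record: MassRecord) -> float:
    """Water content as a percentage of wet mass: ``100 (wet - dry)/wet``."""
    return 100.0 * (record.wet_mass - record.dry_mass) / record.wet_mass


def segment_slice_area(
    image: np.ndarray,
    min_size: int = 50,
    foreground: str = "bright",
    scale_mm_per_px: float | None = None,
) -> float:
    """Planar area of a slice segmented from a grayscale photograph.

    Otsu global threshold, largest connected component, hole filling;
    the returned area is the component pixel count (or mm^2 when a
    scale is given).  ``foreground`` selects whether the slice is
    brighter or darker than the background.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise InvalidInputError("expected a single-channel 2-D image")
    if img.max() == img.min():
        raise SegmentationError("blank image: no intensity contrast to threshold")
    thresh = threshold_otsu(img)
    mask = img > thresh if foreground == "bright" else img < thresh
    labels = label_components(mask)
    if labels.max() == 0:
        raise SegmentationError("no foreground component found")
    sizes = np.bincount(labels.ravel())[1:]
    biggest = int(np.argmax(sizes)) + 1
    if sizes[biggest - 1] < min_size:
        raise SegmentationError(
            f"largest component ({sizes[biggest - 1]} px) below min_size={min_size}"
        )
    component = ndimage.binary_fill_holes(labels == biggest)
    area_px = float(component.sum())
    if scale_mm_per_px is not None:
        return area_px * scale_mm_per_px**2
    return area_px


def planar_to_volume_ratio(area_ratio: float | np.ndarray) -> float | np.ndarray:
    """Volumetric swelling factor from a planar area ratio: ``ratio^(3/2)``.

    Valid under isotropic swelling (a good approximation for the
    predominantly grey-matter mouse brain).
    """
    ratio = np.asarray(area_ratio, dtype=float)
    if np.any(ratio <= 0):
        raise DomainError("area ratio must be positive")
    out = ratio**1.5
    return float(out) if np.isscalar(area_ratio) else out


def swelling_timecourse(series: AreaSeries) -> np.ndarray:
    """Volume swelling ratio over time, referenced to the first timepoint."""
    area_ratio = series.planar_area / series.planar_area[0]
    return np.asarray(planar_to_volume_ratio(area_ratio))


def auc_trapezoid(time_h: np.ndarray, values: np.ndarray) -> float:
    """Composite-trapezoid area under a time course (value-hours).

    Integrates over the observed window only — no extrapolation to
    t = 0 or beyond the last sample.
    """
    t = np.asarray(time_h, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.shape != v.shape:
        raise InvalidInputError("time and values must have equal length")
    if t.size < 2:
        raise InvalidInputError("need at least two samples for an AUC")
    if np.any(np.diff(t) <= 0):
        raise InvalidInputError("timepoints must be strictly increasing")
    return float(np.trapezoid(v, t))


def summarize_group(
    records: pd.DataFrame,
    value_col: str = "value",
    by: tuple[str, ...] = ("condition", "time_h"),
) -> pd.DataFrame:
    """Mean/SD/SEM/n per condition-by-timepoint cell.

    SD and SEM use the n-1 denominator and are NaN (flagged undefined)
    for single-record cells.  Record order within a cell does not affect
    the output.  Empty input yields an empty table with a warning.
    """
    if records.empty:
        warnings.warn("summarize_group received no records")
        return pd.DataFrame(columns=[*by, "mean", "sd", "sem", "n"])
    grouped = records.groupby(list(by), sort=True)[value_col]
    out = grouped.agg(
        mean="mean",
        sd=lambda v: v.std(ddof=1),
        sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)),
        n="count",
    ).reset_index()
    out["n"] = out["n"].astype(int)
    return out
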