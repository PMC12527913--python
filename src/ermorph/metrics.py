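"""Fraction and polarity metrics built on the ER class mask.

- tubule fraction: tubular ER area over total (tubule + sheet) ER area in a
  region, the readout that separates convex (tubule-rich) from concave
  (sheet-rich) fronts;
- front intensity fraction: background-subtracted signal in the front band
  over the whole-cell signal (the Climp63-style sheet-marker readout);
- MDE (mean distribution from edge): intensity-weighted mean distance of a
  component's signal from the wound edge, in um — lower means the component
  is polarized toward the migrating edge;
- shape index: perimeter / sqrt(area) of a cell outline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import shapely
import shapely.geometry as sgeom
from scipy import stats

from .geometry import Contour, FrontROI, px_to_um, rasterize_polygon
from .image import MASK_SHEET, MASK_TUBULE, Image
from .segmentation import ClassMask


@dataclass
class FractionResult:
    f_tubule: float
    area_tubule: float
    area_sheet: float
    roi_id: object = None


@dataclass
class MDEResult:
    mde: float
    component: str = ""
    cell_id: object = None


def _roi_mask(roi, shape, pixel_size) -> np.ndarray:
    if isinstance(roi, np.ndarray):
        return roi.astype(bool)
    return rasterize_polygon(roi, shape, pixel_size)


def tubule_fraction(mask: ClassMask, roi=None, roi_id=None) -> FractionResult:
    """Tubule area / (tubule + sheet area) inside the ROI (whole image if None)."""
    where = None if roi is None else _roi_mask(roi, mask.labels.shape,
                                               mask.pixel_size)
    a_t = mask.area(MASK_TUBULE, where)
    a_s = mask.area(MASK_SHEET, where)
    if a_t + a_s == 0:
        raise ValueError("empty ER in ROI")
    return FractionResult(f_tubule=a_t / (a_t + a_s),
                          area_tubule=a_t, area_sheet=a_s, roi_id=roi_id)


def front_intensity_fraction(img: Image, front, cell_mask: np.ndarray,
                             background: Optional[float] = None) -> float:
    """Front-band signal over whole-cell signal, background subtracted.

    Background defaults to the median intensity of the extracellular region.
    """
    cell = cell_mask.astype(bool)
    if cell.sum() == 0:
        raise ValueError("empty cell mask")
    fmask = _roi_mask(front, img.shape, img.pixel_size) & cell
    if background is None:
        outside = ~cell
        background = float(np.median(img.data[outside])) if outside.any() else 0.0
    sig = np.clip(img.data - background, 0.0, None)
    total = float(sig[cell].sum())
    if total <= 0:
        raise ValueError("whole-cell intensity <= 0 after background subtraction")
    return float(np.clip(sig[fmask].sum() / total, 0.0, 1.0))


def distance_to_edge_map(shape: tuple[int, int], pixel_size: float,
                         wound_edge: Contour) -> np.ndarray:
    """Exact Euclidean distance (um) from every pixel centre to the edge polyline."""
    line = wound_edge.as_shapely()
    if isinstance(line, sgeom.Polygon):
        line = line.exterior
    h, w = shape
    cc, rr = np.meshgrid(np.arange(w), np.arange(h))
    pts = np.column_stack([px_to_um(cc.ravel(), pixel_size),
                           px_to_um(rr.ravel(), pixel_size)])
    return shapely.distance(shapely.points(pts), line).reshape(h, w)


def mde(signal: Union[Image, ClassMask, np.ndarray], cell_mask: np.ndarray,
        wound_edge: Contour, pixel_size: Optional[float] = None,
        component: str = "", cell_id=None) -> MDEResult:
    """Mean distribution from edge: sum_x p(x) d(x, edge) with p the signal
    normalized to a probability density over the cell."""
    if isinstance(signal, Image):
        data, pixel_size = signal.data, signal.pixel_size
    elif isinstance(signal, ClassMask):
        data, pixel_size = (signal.labels > 0).astype(float), signal.pixel_size
    else:
        data = np.asarray(signal, dtype=float)
        if pixel_size is None:
            raise ValueError("pixel_size required for a bare array")
    cell = cell_mask.astype(bool)
    weights = np.where(cell, data, 0.0)
    total = weights.sum()
    if total <= 0:
        raise ValueError("zero total signal within the cell")
    dmap = distance_to_edge_map(data.shape, pixel_size, wound_edge)
    return MDEResult(mde=float((weights * dmap).sum() / total),
                     component=component, cell_id=cell_id)


def shape_index(cell: Contour) -> float:
    """Perimeter / sqrt(area) of a simple closed cell outline."""
    if not cell.closed:
        raise ValueError("shape index requires a closed contour")
    poly = sgeom.Polygon(cell.vertices)
    if not poly.is_valid:
        raise ValueError("self-intersecting polygon")
    return cell.perimeter() / float(np.sqrt(poly.area))


def validate_fractions(estimates, truths) -> float:
    """Pearson correlation between estimated and reference tubule fractions."""
    x = np.asarray(estimates, dtype=float)
    y = np.asarray(truths, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >=3 paired values")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in one of the series")
    return float(stats.pearsonr(x, y).statistic)
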