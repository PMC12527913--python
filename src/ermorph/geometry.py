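"""Contour geometry: signed edge curvature, inclusion filter, front ROIs.

Curvature is quantified at two scales, matching how wound-edge experiments
are analysed: circles fitted to individual cell edges (algebraic Taubin fit,
stable on short arcs) and smoothing splines fitted to the whole wound
boundary, with kappa(s) = (x'y'' - y'x'') / (x'^2 + y'^2)^(3/2) sampled at
uniform arclength.

Sign convention: kappa > 0 where the edge bulges into the cell-free gap
(convex), kappa < 0 where it indents into the monolayer (concave).
|kappa| = 1/R for a circular arc of radius R.  Coordinates are continuous
micrometres in a y-down image frame; pixel index i maps to the pixel-centre
coordinate (i + 0.5) * pixel_size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import interpolate
import shapely
import shapely.geometry as sgeom


def px_to_um(idx: np.ndarray, pixel_size: float) -> np.ndarray:
    """Pixel index -> micrometre coordinate of the pixel centre."""
    return (np.asarray(idx, dtype=float) + 0.5) * pixel_size


def um_to_px(coord: np.ndarray, pixel_size: float) -> np.ndarray:
    """Micrometre coordinate -> fractional pixel index."""
    return np.asarray(coord, dtype=float) / pixel_size - 0.5


@dataclass
class Contour:
    """Ordered planar polyline/polygon in micrometres.

    ``vertices`` is an (N, 2) array of (x, y) points, y-down image
    convention.  Closed contours are simple polygons; consecutive
    duplicate vertices are rejected.
    """

    vertices: np.ndarray
    closed: bool = False
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("contour needs >=3 planar vertices")
        d = np.linalg.norm(np.diff(v, axis=0), axis=1)
        if np.any(d == 0):
            raise ValueError("consecutive duplicate vertices")
        if self.closed and np.allclose(v[0], v[-1]):
            v = v[:-1]
        self.vertices = v
        if self.closed and not sgeom.Polygon(v).is_valid:
            raise ValueError("closed contour is not a simple polygon")

    @property
    def n(self) -> int:
        return self.vertices.shape[0]

    def as_shapely(self):
        if self.closed:
            return sgeom.Polygon(self.vertices)
        return sgeom.LineString(self.vertices)

    def perimeter(self) -> float:
        v = self.vertices
        if self.closed:
            v = np.vstack([v, v[:1]])
        return float(np.sum(np.linalg.norm(np.diff(v, axis=0), axis=1)))

    def area(self) -> float:
        if not self.closed:
            raise ValueError("area undefined for open contour")
        return float(sgeom.Polygon(self.vertices).area)


@dataclass
class SignedCurvature:
    """Signed curvature in 1/um; +1 sign flag = convex (bulging into gap)."""

    kappa: float
    convention: str = "convex_positive"


@dataclass
class CurvatureProfile:
    """kappa(s) along a contour, uniform-arclength samples."""

    s: np.ndarray
    kappa: np.ndarray
    smoothing: float

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.kappa = np.asarray(self.kappa, dtype=float)
        if self.s.shape != self.kappa.shape:
            raise ValueError("s and kappa must have equal length")
        if np.any(np.diff(self.s) <= 0):
            raise ValueError("s must be strictly increasing")

    def arc_mean(self, s1: Optional[float] = None, s2: Optional[float] = None) -> float:
        """Arclength-weighted mean of kappa over [s1, s2] (whole arc by default)."""
        s1 = self.s[0] if s1 is None else s1
        s2 = self.s[-1] if s2 is None else s2
        if s2 <= s1:
            raise ValueError("require s2 > s1")
        grid = np.linspace(s1, s2, 512)
        k = np.interp(grid, self.s, self.kappa)
        return float(np.trapezoid(k, grid) / (s2 - s1))


@dataclass
class CircleFit:
    center: np.ndarray
    radius: float
    kappa_magnitude: float
    degenerate: bool = False


@dataclass
class FrontROI:
    """Front band of a cell: cell polygon clipped to the wound-edge buffer."""

    polygon: "sgeom.Polygon"
    depth: float
    cell_id: object = None
    edge_tangent_deg: float = 0.0

    @property
    def area(self) -> float:
        return float(self.polygon.area)


def fit_circle(points: np.ndarray) -> CircleFit:
    """Algebraic (Taubin) least-squares circle through a planar point set.

    Returns centre, radius and |kappa| = 1/radius.  Collinear input yields a
    degenerate result (radius = inf, |kappa| = 0) rather than an exception:
    a straight cell edge has zero curvature.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need >=3 planar points")
    centroid = pts.mean(axis=0)
    X = pts[:, 0] - centroid[0]
    Y = pts[:, 1] - centroid[1]
    # collinearity: relative thickness of the point cloud
    sv = np.linalg.svd(np.column_stack([X, Y]), compute_uv=False)
    if sv[0] == 0 or sv[1] / sv[0] < 1e-9:
        return CircleFit(center=np.array([np.nan, np.nan]), radius=np.inf,
                         kappa_magnitude=0.0, degenerate=True)
    Z = X * X + Y * Y
    zm = Z.mean()
    Z0 = (Z - zm) / (2.0 * np.sqrt(zm))
    ZXY = np.column_stack([Z0, X, Y])
    _, _, vt = np.linalg.svd(ZXY, full_matrices=False)
    a = vt[2, :]
    a0 = a[0] / (2.0 * np.sqrt(zm))
    if abs(a0) < 1e-14:
        return CircleFit(center=np.array([np.nan, np.nan]), radius=np.inf,
                         kappa_magnitude=0.0, degenerate=True)
    coeffs = np.array([a0, a[1], a[2], -zm * a0])
    cx = -coeffs[1] / (2.0 * coeffs[0])
    cy = -coeffs[2] / (2.0 * coeffs[0])
    radius = float(np.sqrt(cx * cx + cy * cy - coeffs[3] / coeffs[0]))
    center = centroid + np.array([cx, cy])
    return CircleFit(center=center, radius=radius,
                     kappa_magnitude=1.0 / radius, degenerate=False)


def _parametric_spline(contour: Contour, smoothing: Optional[float]):
    v = contour.vertices
    if contour.closed:
        v = np.vstack([v, v[:1]])
    chord = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(v, axis=0), axis=1))])
    u = chord / chord[-1]
    tck, _ = interpolate.splprep([v[:, 0], v[:, 1]], u=u, s=smoothing,
                                 per=int(contour.closed), k=3)
    return tck


def spline_curvature(contour: Contour, smoothing: Optional[float] = None,
                     n_samples: int = 400) -> CurvatureProfile:
    """Smoothing-spline curvature profile kappa(s) at uniform arclength.

    ``smoothing`` is the spline residual budget (um^2 units, as in
    FITPACK); None uses the m - sqrt(2m) default.  The raw sign follows the
    traversal direction; use :func:`assign_sign` to apply the gap-side
    convention.
    """
    if contour.n < 6:
        raise ValueError("need >=6 vertices for a cubic smoothing spline")
    if smoothing is not None and smoothing <= 0:
        raise ValueError("smoothing must be > 0 (omit for the default)")
    tck = _parametric_spline(contour, smoothing)
    u = np.linspace(0.0, 1.0, 4 * n_samples)
    dx, dy = interpolate.splev(u, tck, der=1)
    ddx, ddy = interpolate.splev(u, tck, der=2)
    speed = np.hypot(dx, dy)
    kappa = (dx * ddy - dy * ddx) / np.maximum(speed, 1e-30) ** 3
    s_dense = np.concatenate([[0.0], np.cumsum(0.5 * (speed[1:] + speed[:-1]) * np.diff(u))])
    s_uniform = np.linspace(0.0, s_dense[-1], n_samples)
    k_uniform = np.interp(s_uniform, s_dense, kappa)
    sm = float(smoothing) if smoothing is not None else float(
        contour.n - np.sqrt(2.0 * contour.n))
    return CurvatureProfile(s=s_uniform, kappa=k_uniform, smoothing=sm)


def _side_of_polyline(line: "sgeom.LineString", pt: np.ndarray) -> float:
    """Sign of the cross product of the local tangent with (pt - foot)."""
    p = sgeom.Point(pt)
    u = line.project(p)
    foot = line.interpolate(u)
    eps = max(1e-6, 1e-4 * line.length)
    p0 = line.interpolate(max(u - eps, 0.0))
    p1 = line.interpolate(min(u + eps, line.length))
    tx, ty = p1.x - p0.x, p1.y - p0.y
    nx, ny = pt[0] - foot.x, pt[1] - foot.y
    return float(np.sign(tx * ny - ty * nx))


def assign_sign(kappa_magnitude: float, edge: Contour,
                gap_side_probe: Sequence[float], tol: float = 1e-6) -> SignedCurvature:
    """Apply the convex-positive convention using a probe point in the gap.

    The edge is convex (positive) when its osculating circle's centre lies on
    the monolayer side, i.e. on the opposite side of the edge from the
    gap-side probe.  A flat edge gets kappa = 0 regardless of the probe.
    """
    probe = np.asarray(gap_side_probe, dtype=float)
    line = sgeom.LineString(edge.vertices if not edge.closed
                            else np.vstack([edge.vertices, edge.vertices[:1]]))
    if line.distance(sgeom.Point(probe)) < tol:
        raise ValueError("probe point lies on the edge")
    fit = fit_circle(edge.vertices)
    if fit.degenerate or kappa_magnitude == 0.0:
        return SignedCurvature(kappa=0.0)
    opposite = _side_of_polyline(line, fit.center) != _side_of_polyline(line, probe)
    sign = 1.0 if opposite else -1.0
    return SignedCurvature(kappa=sign * abs(kappa_magnitude))


def passes_contact_filter(fraction: float) -> bool:
    """Inclusion rule: strictly more than 20% of the perimeter in contact."""
    return fraction > 0.20


def perimeter_contact_fraction(cell: Contour, wound_edge: Contour,
                               tol: float) -> tuple[float, bool]:
    """Fraction of the cell perimeter within ``tol`` of the wound edge.

    Cells are included in curvature analyses only when *more than* 20% of
    their perimeter contacts the wound (strict inequality); lower-exposure
    cells report geometry set by their neighbours, not by the edge.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    v = cell.vertices
    if cell.closed:
        v = np.vstack([v, v[:1]])
    seg_len = np.linalg.norm(np.diff(v, axis=0), axis=1)
    # resample each boundary segment finely, weight samples by arclength
    step = max(min(tol / 4.0, seg_len.min()), cell.perimeter() / 4000.0)
    samples, weights = [], []
    for a, b, L in zip(v[:-1], v[1:], seg_len):
        k = max(int(np.ceil(L / step)), 1)
        t = (np.arange(k) + 0.5) / k
        samples.append(a[None, :] + t[:, None] * (b - a)[None, :])
        weights.append(np.full(k, L / k))
    pts = np.concatenate(samples)
    w = np.concatenate(weights)
    edge_line = wound_edge.as_shapely()
    if isinstance(edge_line, sgeom.Polygon):
        edge_line = edge_line.exterior
    dist = shapely.distance(shapely.points(pts), edge_line)
    frac = float(w[dist <= tol].sum() / w.sum())
    return frac, passes_contact_filter(frac)


def front_roi(cell: Contour, wound_edge: Contour, d_front: float = 10.0,
              cell_id: object = None) -> FrontROI:
    """Front band: intersection of the cell with the d_front-wide strip
    inward from the wound edge."""
    edge_line = wound_edge.as_shapely()
    if isinstance(edge_line, sgeom.Polygon):
        edge_line = edge_line.exterior
    band = edge_line.buffer(d_front)
    poly = sgeom.Polygon(cell.vertices).intersection(band)
    if poly.is_empty or poly.area == 0:
        raise ValueError("cell not at edge: empty front ROI")
    if poly.geom_type == "MultiPolygon":
        poly = max(poly.geoms, key=lambda g: g.area)
    # local edge tangent at the point nearest the ROI centroid
    c = poly.centroid
    u = edge_line.project(c)
    eps = max(1e-3, 1e-3 * edge_line.length)
    p0 = edge_line.interpolate(max(u - eps, 0.0))
    p1 = edge_line.interpolate(min(u + eps, edge_line.length))
    ang = float(np.degrees(np.arctan2(p1.y - p0.y, p1.x - p0.x)))
    return FrontROI(polygon=poly, depth=float(d_front), cell_id=cell_id,
                    edge_tangent_deg=ang)


def rasterize_polygon(poly, shape: tuple[int, int], pixel_size: float) -> np.ndarray:
    """Boolean mask of a shapely polygon (or FrontROI) on an image grid.

    Pixel (r, c) is inside iff its centre ((c+0.5)p, (r+0.5)p) is inside.
    """
    if isinstance(poly, FrontROI):
        poly = poly.polygon
    if isinstance(poly, Contour):
        poly = sgeom.Polygon(poly.vertices)
    h, wdt = shape
    cc, rr = np.meshgrid(np.arange(wdt), np.arange(h))
    pts = np.column_stack([px_to_um(cc.ravel(), pixel_size),
                           px_to_um(rr.ravel(), pixel_size)])
    inside = shapely.contains(poly, shapely.points(pts))
    return inside.reshape(h, wdt)
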