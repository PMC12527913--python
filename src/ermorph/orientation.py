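"""Orientation analysis: Fourier directionality, focal adhesions, flow.

Orientation histograms follow the Fourier-components recipe: Hann-windowed
2D power spectrum, energy binned by spatial-frequency angle (structure
orientation = spectrum angle + 90 deg).  Focal-adhesion mode uses 6 bins on
[0, 90] deg; microtubule mode 10 bins on [0, 180] deg.  FA classes: parallel
for angles 0-18 deg to the edge tangent, perpendicular for 72-90 deg
(thresholds inclusive), otherwise excluded.

Kymographs stack per-frame intensity profiles along a line oriented toward
the wound edge; the flow call picks the velocity that best aligns the
mean-subtracted kymograph (a sheared-projection / Radon-style search), with
anterograde = toward the edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .geometry import px_to_um
from .image import MASK_SHEET, MASK_TUBULE, Image
from .metrics import FractionResult, tubule_fraction
from .segmentation import ClassifierModel, ClassMask, classify

PARALLEL_MAX_DEG = 18.0
PERPENDICULAR_MIN_DEG = 72.0
SPEED_FLOOR_UM_MIN = 0.05


@dataclass
class OrientationHistogram:
    bin_edges: np.ndarray   # deg, length n_bins + 1
    weights: np.ndarray     # sum to 1
    angle_range: tuple[float, float]
    n_bins: int

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be >= 0 and sum to 1")
        self.weights = w

    @property
    def argmax_bin(self) -> tuple[float, float]:
        i = int(np.argmax(self.weights))
        return float(self.bin_edges[i]), float(self.bin_edges[i + 1])


@dataclass
class FAObject:
    centroid_um: tuple[float, float]
    area_um2: float
    angle_to_edge_deg: float
    fa_class: str = ""
    er_contact: str = "none"
    pixels: Optional[np.ndarray] = None  # (n, 2) row/col footprint


@dataclass
class Kymograph:
    data: np.ndarray          # (n_space, n_time); space index grows toward edge
    space_step_um: float
    frame_interval_s: float
    line: tuple = ()
    direction: str = "none"
    speed_um_min: float = 0.0


def _fold_angle(theta_deg: np.ndarray, angle_range: tuple[float, float]) -> np.ndarray:
    lo, hi = angle_range
    span = hi - lo
    t = np.mod(theta_deg - lo, 180.0)
    if span <= 90.0 + 1e-9:
        t = np.where(t > 90.0, 180.0 - t, t)
    return np.clip(t + lo, lo, hi)


def directionality_fourier(img: Image, roi: Optional[np.ndarray] = None,
                           n_bins: int = 6,
                           angle_range: tuple[float, float] = (0.0, 90.0),
                           edge_tangent_deg: float = 0.0) -> OrientationHistogram:
    """Histogram of structure orientations by the Fourier-components method.

    Angles are reported relative to ``edge_tangent_deg`` (the local edge
    tangent) and folded into ``angle_range``.
    """
    data = img.data if roi is None else img.data[np.ix_(*_roi_slices(roi))]
    if min(data.shape) < 32:
        raise ValueError("ROI must be at least 32x32 px")
    h, w = data.shape
    win = np.outer(np.hanning(h), np.hanning(w))
    F = np.fft.fftshift(np.fft.fft2((data - data.mean()) * win))
    power = np.abs(F) ** 2
    v, u = np.meshgrid(np.fft.fftshift(np.fft.fftfreq(h)),
                       np.fft.fftshift(np.fft.fftfreq(w)), indexing="ij")
    radius = np.hypot(u * w, v * h)
    keep = (radius > 2.0) & (radius < 0.45 * min(h, w))
    # frequency angle in the y-down image frame (the same convention as the
    # edge tangent and FA angles); structures are perpendicular to it
    spec_angle = np.degrees(np.arctan2(v, u))
    struct_angle = spec_angle + 90.0 - edge_tangent_deg
    folded = _fold_angle(struct_angle[keep], angle_range)
    edges = np.linspace(angle_range[0], angle_range[1], n_bins + 1)
    idx = np.clip(np.digitize(folded, edges) - 1, 0, n_bins - 1)
    weights = np.bincount(idx, weights=power[keep], minlength=n_bins)
    total = weights.sum()
    weights = weights / total if total > 0 else np.full(n_bins, 1.0 / n_bins)
    return OrientationHistogram(bin_edges=edges, weights=weights,
                                angle_range=angle_range, n_bins=n_bins)


def _roi_slices(roi: np.ndarray):
    rows = np.flatnonzero(roi.any(axis=1))
    cols = np.flatnonzero(roi.any(axis=0))
    return np.arange(rows[0], rows[-1] + 1), np.arange(cols[0], cols[-1] + 1)


def classify_fa(angle_to_edge_deg: float) -> str:
    """Parallel (0-18 deg), perpendicular (72-90 deg) or excluded."""
    a = float(angle_to_edge_deg)
    if not 0.0 <= a <= 90.0:
        raise ValueError("angle must be in [0, 90] deg")
    if a <= PARALLEL_MAX_DEG:
        return "parallel"
    if a >= PERPENDICULAR_MIN_DEG:
        return "perpendicular"
    return "excluded"


def detect_fa(img: Image, cell_mask: Optional[np.ndarray] = None,
              edge_tangent_deg: float = 0.0,
              threshold: Optional[float] = None,
              min_area_um2: float = 0.1) -> list[FAObject]:
    """Detect FA punctae and measure their angle to the edge tangent.

    Background-subtracted Otsu threshold (overridable), connected components,
    minimum-area filter, orientation from the second-central-moment ellipse.
    """
    data = img.data - np.median(img.data)
    if cell_mask is not None:
        data = np.where(cell_mask, data, 0.0)
    pos = data[data > 0]
    if pos.size == 0:
        return []
    thr = threshold_otsu(data) if threshold is None else threshold
    binary = data > thr
    if not binary.any():
        return []
    out: list[FAObject] = []
    p = img.pixel_size
    for rp in regionprops(cc_label(binary, connectivity=2)):
        area = rp.area * p * p
        if area < min_area_um2:
            continue
        # rp.orientation: angle of major axis from the row axis, CCW, in
        # (-pi/2, pi/2]; convert to angle from the x (column) axis
        ang_x = 90.0 - np.degrees(rp.orientation)
        rel = _fold_angle(np.array([ang_x - edge_tangent_deg]), (0.0, 90.0))[0]
        r0, c0 = rp.centroid
        out.append(FAObject(
            centroid_um=(float(px_to_um(np.array([c0]), p)[0]),
                         float(px_to_um(np.array([r0]), p)[0])),
            area_um2=float(area),
            angle_to_edge_deg=float(rel),
            fa_class=classify_fa(rel),
            pixels=rp.coords))
    return out


def fa_er_association(fas: Sequence[FAObject], ermask: ClassMask,
                      contact_radius_um: float = 0.3) -> dict:
    """Majority ER class within the contact radius of each FA footprint.

    Returns per-FA contact labels (set on the objects) and, per FA class,
    the fraction contacting tubules and sheets.
    """
    if contact_radius_um < 0:
        raise ValueError("contact radius must be >= 0")
    p = ermask.pixel_size
    rad_px = max(int(np.ceil(contact_radius_um / p)), 0)
    h, w = ermask.labels.shape
    for fa in fas:
        if fa.pixels is None or len(fa.pixels) == 0:
            fa.er_contact = "none"
            continue
        foot = np.zeros((h, w), dtype=bool)
        foot[fa.pixels[:, 0], fa.pixels[:, 1]] = True
        if rad_px > 0:
            foot = ndimage.binary_dilation(foot, iterations=rad_px)
        n_tub = int((ermask.labels[foot] == MASK_TUBULE).sum())
        n_sheet = int((ermask.labels[foot] == MASK_SHEET).sum())
        if n_tub == 0 and n_sheet == 0:
            fa.er_contact = "none"
        else:
            fa.er_contact = "tubule" if n_tub >= n_sheet else "sheet"
    table: dict[str, dict[str, float]] = {}
    for cls in ("parallel", "perpendicular", "excluded"):
        members = [fa for fa in fas if fa.fa_class == cls]
        if not members:
            continue
        n = len(members)
        table[cls] = {
            "n": n,
            "frac_tubule": sum(fa.er_contact == "tubule" for fa in members) / n,
            "frac_sheet": sum(fa.er_contact == "sheet" for fa in members) / n,
            "frac_none": sum(fa.er_contact == "none" for fa in members) / n,
        }
    return table


def kymograph(stack: np.ndarray, line: tuple, width_px: int = 3,
              pixel_size: float = 1.0, frame_interval_s: float = 60.0) -> Kymograph:
    """Space-time map along ``line`` = ((r0, c0), (r1, c1)) in px, the second
    endpoint nearer the wound edge; intensity averaged across ``width_px``."""
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 5:
        raise ValueError("need a stack with >= 5 frames")
    (r0, c0), (r1, c1) = line
    nt, h, w = stack.shape
    for r, c in ((r0, c0), (r1, c1)):
        if not (0 <= r < h and 0 <= c < w):
            raise ValueError("line exits the image")
    length = np.hypot(r1 - r0, c1 - c0)
    n_s = max(int(np.ceil(length)), 2)
    t_par = np.linspace(0.0, 1.0, n_s)
    rr = r0 + t_par * (r1 - r0)
    cc = c0 + t_par * (c1 - c0)
    # perpendicular offsets for width averaging
    nx, ny = -(r1 - r0) / length, (c1 - c0) / length
    offs = np.arange(width_px) - (width_px - 1) / 2.0
    kymo = np.empty((n_s, nt))
    for t in range(nt):
        acc = np.zeros(n_s)
        for o in offs:
            coords = np.vstack([rr + o * ny, cc + o * nx])
            acc += ndimage.map_coordinates(stack[t], coords, order=1,
                                           mode="nearest")
        kymo[:, t] = acc / len(offs)
    step = length / (n_s - 1) * pixel_size
    k = Kymograph(data=kymo, space_step_um=step,
                  frame_interval_s=frame_interval_s, line=line)
    k.direction, k.speed_um_min = flow_direction(k)
    return k


def flow_direction(k: Kymograph, speed_floor: float = SPEED_FLOOR_UM_MIN,
                   with_confidence: bool = False):
    """Dominant drift by a sheared-projection search over velocities.

    Positive slope (signal moving to larger space index, i.e. toward the
    edge) is anterograde; below ``speed_floor`` the call is 'none'.
    """
    data = np.asarray(k.data, dtype=float)
    if data.shape[1] < 5:
        raise ValueError("need >= 5 time points")
    resid = data - data.mean(axis=1, keepdims=True)
    if np.allclose(resid, 0.0):
        return ("none", 0.0, np.inf) if with_confidence else ("none", 0.0)
    n_s, n_t = data.shape
    dt_min = k.frame_interval_s / 60.0
    vmax = 0.8 * n_s * k.space_step_um / ((n_t - 1) * dt_min)
    s_axis = np.arange(n_s)

    def score(v: float) -> float:
        # shear centred on mid-time so a time-reversed kymograph scores
        # exactly as the mirrored velocity (flow antisymmetry); the sum of
        # squares is normalized by per-position frame coverage so larger
        # shears are not penalized for their smaller overlap window
        shift_px = v * dt_min / k.space_step_um
        t_mid = (n_t - 1) / 2.0
        proj = np.zeros(n_s)
        cover = np.zeros(n_s)
        ones = np.ones(n_s)
        for t in range(n_t):
            xp = s_axis - shift_px * (t - t_mid)
            proj += np.interp(s_axis, xp, resid[:, t], left=0.0, right=0.0)
            cover += np.interp(s_axis, xp, ones, left=0.0, right=0.0)
        ok = cover > 0
        return float(np.sum(proj[ok] ** 2 / cover[ok]))

    grid = np.linspace(-vmax, vmax, 161)
    scores = np.array([score(v) for v in grid])
    i = int(np.argmax(scores))
    # refine around the best grid velocity
    fine = np.linspace(grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)], 41)
    fscores = np.array([score(v) for v in fine])
    v_best = float(fine[np.argmax(fscores)])
    if with_confidence:
        mirror = score(-v_best)
        conf = float(score(v_best) / mirror) if mirror > 0 else np.inf
    if abs(v_best) < speed_floor:
        out = ("none", 0.0)
    else:
        out = (("anterograde" if v_best > 0 else "retrograde"), abs(v_best))
    return out + (conf,) if with_confidence else out


def flow_consensus(stack: np.ndarray, lines: Sequence[tuple],
                   width_px: int = 3, pixel_size: float = 1.0,
                   frame_interval_s: float = 60.0) -> tuple[str, float]:
    """Flow call from the most direction-confident of several kymograph
    lines — the same choice a practitioner makes by drawing the line through
    visibly moving structures."""
    best = ("none", 0.0, -np.inf)
    for line in lines:
        k = kymograph(stack, line, width_px=width_px, pixel_size=pixel_size,
                      frame_interval_s=frame_interval_s)
        d, s, conf = flow_direction(k, with_confidence=True)
        if conf > best[2]:
            best = (d, s, conf)
    return best[0], best[1]


def tubule_fraction_timeseries(stack: np.ndarray, model: ClassifierModel,
                               rois, pixel_size: float) -> list:
    """Per-frame classify + tubule fraction; frames with empty ER in the ROI
    are flagged (None) rather than fatal."""
    rois = rois if isinstance(rois, (list, tuple)) else [rois] * len(stack)
    series = []
    for frame, roi in zip(stack, rois):
        img = Image(data=np.clip(frame, 0, None), pixel_size=pixel_size)
        mask = classify(model, img)
        try:
            series.append(tubule_fraction(mask, roi))
        except ValueError:
            series.append(None)
    return series
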