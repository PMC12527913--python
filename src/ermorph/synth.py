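"""Seeded generator of curved-edge cell scenes with ground truth.

Emulates the imaging conditions the estimators face: a wound edge of
prescribed signed curvature with the cell monolayer beneath it (gap at the
top of the frame, y-down coordinates), ER rendered as thin curvilinear
tubule strokes plus dense sheet blobs in the front band at a prescribed
tubule fraction, paxillin-like elliptical punctae with a von Mises angle
distribution relative to the edge tangent, and time-lapse stacks translated
along the edge normal at a prescribed velocity.  Images are blurred by a
Gaussian PSF and corrupted by Poisson + Gaussian read noise; ground-truth
masks are defined before noise.

Everything is driven by one integer seed: the same spec yields bit-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage.draw import disk, ellipse

from .geometry import Contour, px_to_um
from .image import MASK_BACKGROUND, MASK_SHEET, MASK_TUBULE, Image
from .segmentation import UNLABELLED


@dataclass
class SynthSpec:
    """Parameters of one synthetic scene (lengths in um unless noted)."""

    seed: int = 0
    shape: tuple[int, int] = (256, 256)
    pixel_size: float = 0.065
    kappa: float = 0.0              # signed edge curvature, +ve = convex
    f_true: float = 0.5             # target tubule fraction in the front band
    front_depth: float = 3.0        # front band depth used for the fraction
    edge_offset_frac: float = 0.30  # edge apex depth as fraction of frame height
    er_fill: float = 0.5            # ER (tubule+sheet) area fraction of the band
    tubule_width_px: int = 3
    tubule_step_px: float = 1.5
    tubule_persistence: float = 0.9
    body_fill: float = 0.10         # tubule area fraction of the cell body
    sheet_smooth_px: float = 8.0
    intensity_cyto: float = 15.0
    intensity_tubule: float = 120.0
    intensity_sheet: float = 200.0
    psf_sigma_px: float = 1.5
    poisson_scale: float = 1.0      # photons per intensity unit; 0 = off
    read_noise_sigma: float = 3.0
    fa_count: int = 30
    fa_mean_angle: float = 90.0     # deg relative to the edge tangent
    fa_concentration: float = 20.0  # von Mises concentration (0 = uniform)
    fa_axes_px: tuple[float, float] = (6.0, 2.5)
    fa_intensity: float = 150.0
    flow_velocity: float = 0.0      # um/min, +ve toward the edge
    n_frames: int = 10
    frame_interval_s: float = 60.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_true <= 1.0:
            raise ValueError("f_true must be in [0, 1]")
        if self.psf_sigma_px < 0 or self.read_noise_sigma < 0:
            raise ValueError("noise sigmas must be >= 0")


@dataclass
class GroundTruth:
    mask: np.ndarray                  # {0 bg, 1 tubule, 2 sheet}, pre-noise
    f_front: float                    # realized tubule fraction in front band
    front_band: np.ndarray            # boolean
    cell_mask: np.ndarray             # boolean
    cell_outline: Contour
    wound_edge: Contour
    fa_angles: Optional[np.ndarray] = None
    fa_centroids: Optional[np.ndarray] = None
    fa_er_contact: Optional[list] = None
    flow_velocity: Optional[float] = None


PRESETS = {
    # the operating points the live-imaging time series start from:
    # tubule-dominated convex front vs sheet-dominated concave front
    "convex-default": dict(kappa=0.05, f_true=0.64),
    "concave-default": dict(kappa=-0.05, f_true=0.35),
}


def preset_spec(name: str, seed: int = 0, **overrides) -> SynthSpec:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
    return SynthSpec(seed=seed, **{**PRESETS[name], **overrides})


# ---------------------------------------------------------------- geometry

def _arc_params(spec: SynthSpec) -> tuple[float, float, float]:
    """(xc, yc, R) of the edge arc circle; centre is on the monolayer side
    for convex edges and on the gap side for concave ones."""
    h, w = spec.shape
    width = w * spec.pixel_size
    y0 = spec.edge_offset_frac * h * spec.pixel_size
    R = 1.0 / abs(spec.kappa)
    if R < width / 2.0:
        raise ValueError("arc of this curvature exceeds the frame")
    xc = width / 2.0
    yc = y0 + R if spec.kappa > 0 else y0 - R
    return xc, yc, R


def _edge_y_of_x(spec: SynthSpec, x_um: np.ndarray) -> np.ndarray:
    """Wound edge y(x) in um; gap above (smaller y), monolayer below.

    The arc apex sits at depth edge_offset_frac * frame height; a convex
    edge (kappa > 0) protrudes toward the gap at the centre, a concave edge
    recedes into the monolayer there.
    """
    x = np.asarray(x_um, dtype=float)
    h, w = spec.shape
    y0 = spec.edge_offset_frac * h * spec.pixel_size
    if spec.kappa == 0.0:
        return np.full_like(x, y0)
    xc, yc, R = _arc_params(spec)
    root = np.sqrt(np.clip(R * R - (x - xc) ** 2, 0.0, None))
    return yc - root if spec.kappa > 0 else yc + root


def make_scene(spec: SynthSpec) -> tuple[Contour, Contour]:
    """Cell outline and wound edge for the spec (um coordinates)."""
    h, w = spec.shape
    width, height = w * spec.pixel_size, h * spec.pixel_size
    x = np.linspace(0.0, width, 200)
    y = _edge_y_of_x(spec, x)
    wound_edge = Contour(np.column_stack([x, y]), pixel_size=spec.pixel_size)
    cell = Contour(np.vstack([
        np.column_stack([x, y]),
        [[width, height], [0.0, height]],
    ]), closed=True, pixel_size=spec.pixel_size)
    return cell, wound_edge


def _scene_masks(spec: SynthSpec) -> tuple[np.ndarray, np.ndarray]:
    """(cell_mask, front_band) boolean rasters from the analytic edge."""
    h, w = spec.shape
    xs = px_to_um(np.arange(w), spec.pixel_size)
    ys = px_to_um(np.arange(h), spec.pixel_size)
    yy = ys[:, None]
    y_edge = _edge_y_of_x(spec, xs)[None, :]
    cell = yy >= y_edge
    if spec.kappa == 0.0:
        dist = np.broadcast_to(yy - y_edge, (h, w))
    else:
        xc, yc, R = _arc_params(spec)
        r = np.sqrt((xs[None, :] - xc) ** 2 + (yy - yc) ** 2)
        dist = np.abs(r - R)
    band = cell & (dist <= spec.front_depth)
    return cell, band


# ------------------------------------------------------------------ ER scene

def _draw_stroke(tub: np.ndarray, rng: np.random.Generator,
                 spec: SynthSpec, cell: np.ndarray, start_region: np.ndarray,
                 stop_region: Optional[np.ndarray] = None) -> None:
    """One smooth curvilinear tubule stroke stamped into ``tub``.

    The walk starts in ``start_region`` and terminates on leaving the cell
    or entering ``stop_region`` (used to keep body tubules out of the front
    band so the band's fraction accounting stays exact)."""
    h, w = spec.shape
    start_idx = np.flatnonzero(start_region.ravel())
    if start_idx.size == 0:
        return
    p = start_idx[rng.integers(start_idx.size)]
    r, c = divmod(p, w)
    theta = rng.uniform(0, 2 * np.pi)
    n_steps = int(rng.integers(20, 60))
    rad = max(spec.tubule_width_px / 2.0, 0.5)
    for _ in range(n_steps):
        theta += (1.0 - spec.tubule_persistence) * rng.normal(0.0, 1.5)
        r += spec.tubule_step_px * np.sin(theta)
        c += spec.tubule_step_px * np.cos(theta)
        ri, ci = int(round(r)), int(round(c))
        if not (0 <= ri < h and 0 <= ci < w) or not cell[ri, ci]:
            break
        if stop_region is not None and stop_region[ri, ci]:
            break
        rr, cc = disk((ri, ci), rad, shape=(h, w))
        tub[rr, cc] = True


def render_er(spec: SynthSpec,
              rng: Optional[np.random.Generator] = None) -> tuple[Image, GroundTruth]:
    """Render one ER scene and its pre-noise ground truth.

    The front-band tubule fraction is steered to ``f_true`` by area
    accounting: the sheet blob is thresholded to (1 - f) of the ER budget,
    then tubule strokes are added until the tubule budget is met.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    h, w = spec.shape
    cell, band = _scene_masks(spec)
    band_area = int(band.sum())
    a_er = spec.er_fill * band_area
    a_sheet_target = (1.0 - spec.f_true) * a_er
    a_tub_target = spec.f_true * a_er
    if band_area == 0 or a_er < 10:
        raise ValueError("front band too small for the requested scene")

    # sheet: thresholded smooth random field, confined to the front band
    sheet = np.zeros((h, w), dtype=bool)
    if a_sheet_target >= 1.0:
        field_ = ndimage.gaussian_filter(rng.standard_normal((h, w)),
                                         spec.sheet_smooth_px)
        vals = field_[band]
        q = 1.0 - a_sheet_target / band_area
        thr = np.quantile(vals, np.clip(q, 0.0, 1.0))
        sheet = band & (field_ >= thr)

    # body tubules: the ER network spans the whole cytoplasm, not just the
    # front band; these stay out of the band so its accounting is exact
    tub = np.zeros((h, w), dtype=bool)
    body = cell & ~band
    a_body_target = spec.body_fill * int(body.sum())
    guard = 0
    while (tub & body).sum() < a_body_target and guard < 4000:
        _draw_stroke(tub, rng, spec, cell, body, stop_region=band)
        guard += 1
    # front-band tubules: strokes until the band tubule budget is met
    guard = 0
    while (tub & band & ~sheet).sum() < a_tub_target and guard < 4000:
        _draw_stroke(tub, rng, spec, cell, band)
        guard += 1
    tub &= ~sheet

    mask = np.zeros((h, w), dtype=np.uint8)
    mask[tub] = MASK_TUBULE
    mask[sheet] = MASK_SHEET

    a_t = float((tub & band).sum())
    a_s = float((sheet & band).sum())
    f_front = a_t / (a_t + a_s) if (a_t + a_s) > 0 else np.nan

    clean = np.full((h, w), 0.0)
    clean[cell] = spec.intensity_cyto
    clean[tub] = spec.intensity_tubule
    clean[sheet] = spec.intensity_sheet
    img = _apply_optics(clean, spec, rng)

    cell_outline, wound_edge = make_scene(spec)
    gt = GroundTruth(mask=mask, f_front=f_front, front_band=band,
                     cell_mask=cell, cell_outline=cell_outline,
                     wound_edge=wound_edge)
    return Image(data=img, pixel_size=spec.pixel_size, channel="ER"), gt


def _apply_optics(clean: np.ndarray, spec: SynthSpec,
                  rng: np.random.Generator) -> np.ndarray:
    out = clean
    if spec.psf_sigma_px > 0:
        out = ndimage.gaussian_filter(out, spec.psf_sigma_px)
    if spec.poisson_scale > 0:
        out = rng.poisson(np.clip(out, 0, None) * spec.poisson_scale
                          ).astype(float) / spec.poisson_scale
    if spec.read_noise_sigma > 0:
        out = out + rng.normal(0.0, spec.read_noise_sigma, size=out.shape)
    return np.clip(out, 0.0, None)


# ------------------------------------------------------------------ FA scene

def _edge_tangent_angle(spec: SynthSpec, x_um: float) -> float:
    eps = 0.05
    y0 = _edge_y_of_x(spec, np.array([x_um - eps]))[0]
    y1 = _edge_y_of_x(spec, np.array([x_um + eps]))[0]
    return float(np.degrees(np.arctan2(y1 - y0, 2 * eps)))


def render_fa(spec: SynthSpec, on_mask: Optional[np.ndarray] = None,
              rng: Optional[np.random.Generator] = None) -> tuple[Image, dict]:
    """Elliptical FA punctae with von Mises angles relative to the edge tangent.

    ``on_mask`` optionally constrains centroids onto given pixels (e.g. ER
    tubule or sheet regions) for association tests.
    """
    rng = np.random.default_rng(spec.seed + 7919) if rng is None else rng
    h, w = spec.shape
    cell, band = _scene_masks(spec)
    allowed = band if on_mask is None else (on_mask.astype(bool) & cell)
    idx = np.flatnonzero(allowed.ravel())
    if idx.size < spec.fa_count:
        raise ValueError("FA count exceeds placeable area")
    # punctae are discrete: rejection-sample centres with a minimum
    # separation so neighbouring adhesions do not merge
    min_sep = 2.2 * max(spec.fa_axes_px)
    centres: list[int] = []
    placed: list[tuple[float, float]] = []
    attempts = 0
    while len(centres) < spec.fa_count and attempts < 200 * spec.fa_count:
        cand = int(idx[rng.integers(idx.size)])
        r, c = divmod(cand, w)
        if all((r - pr) ** 2 + (c - pc) ** 2 >= min_sep**2 for pr, pc in placed):
            centres.append(cand)
            placed.append((r, c))
        attempts += 1
    if len(centres) < spec.fa_count:
        raise ValueError("FA count exceeds placeable area")
    clean = np.zeros((h, w))
    angles, cents = [], []
    for p in centres:
        r, c = divmod(int(p), w)
        if spec.fa_concentration >= 1e6:
            rel = np.radians(spec.fa_mean_angle)
        else:
            raw = rng.vonmises(np.radians(2 * spec.fa_mean_angle),
                               spec.fa_concentration)
            rel = abs(raw) / 2.0          # fold to [0, 90] deg
        rel_deg = np.degrees(rel)
        tangent = _edge_tangent_angle(spec, px_to_um(np.array([c]),
                                                     spec.pixel_size)[0])
        sgn = rng.choice([-1.0, 1.0])
        abs_angle = tangent + sgn * rel_deg
        rr, cc = ellipse(r, c, spec.fa_axes_px[0], spec.fa_axes_px[1],
                         shape=(h, w),
                         rotation=np.radians(90.0 - abs_angle))
        clean[rr, cc] = spec.fa_intensity
        angles.append(rel_deg)
        cents.append((px_to_um(np.array([c]), spec.pixel_size)[0],
                      px_to_um(np.array([r]), spec.pixel_size)[0]))
    img = _apply_optics(clean, spec, rng)
    truth = {"angles_deg": np.array(angles), "centroids_um": np.array(cents)}
    return Image(data=img, pixel_size=spec.pixel_size, channel="FA"), truth


# --------------------------------------------------------------- time lapse

def render_timelapse(spec: SynthSpec) -> tuple[np.ndarray, float]:
    """Stack of frames with the ER scene translated along the edge normal.

    Positive flow velocity moves the scene toward the edge (decreasing y).
    Returns (stack[t, y, x], true velocity um/min).
    """
    if spec.n_frames < 5:
        raise ValueError("need >=5 frames")
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    dt_min = spec.frame_interval_s / 60.0
    total_px = abs(spec.flow_velocity) * dt_min * (spec.n_frames - 1) / spec.pixel_size
    if total_px > 0.45 * h:
        raise ValueError("velocity moves the scene out of frame")
    # render a taller scene and crop a fixed window, so translated content
    # is always real texture rather than boundary padding
    margin = int(np.ceil(total_px)) + 4
    tall = replace(spec, shape=(h + 2 * margin, w),
                   edge_offset_frac=(margin + spec.edge_offset_frac * h)
                   / (h + 2 * margin),
                   poisson_scale=0.0, read_noise_sigma=0.0)
    img, _ = render_er(tall, rng=np.random.default_rng(spec.seed))
    clean = img.data
    frames = np.empty((spec.n_frames, h, w))
    for t in range(spec.n_frames):
        dy_px = -spec.flow_velocity * dt_min * t / spec.pixel_size
        shifted = ndimage.shift(clean, (dy_px, 0.0), order=1, mode="nearest")
        frames[t] = _apply_optics(shifted[margin:margin + h], spec, rng)
    return frames, spec.flow_velocity


# ------------------------------------------------------------- training sets

def make_training_set(specs: Sequence[SynthSpec], n_per_class: int = 1000,
                      seed: int = 0) -> list[tuple[Image, np.ndarray]]:
    """Balanced sparse pixel labels sampled from ground-truth masks.

    Returns (image, labels) pairs; labels use -1 for unlabelled pixels.
    Raises if any class is absent from every spec's ground truth.
    """
    rng = np.random.default_rng(seed)
    rendered = [render_er(s) for s in specs]
    for cls, name in [(MASK_BACKGROUND, "background"), (MASK_TUBULE, "tubule"),
                      (MASK_SHEET, "sheet")]:
        if not any((gt.mask == cls).any() for _, gt in rendered):
            raise ValueError(f"class absent from all specs: {name}")
    out = []
    per_scene = max(n_per_class // max(len(specs), 1), 1)
    for img, gt in rendered:
        labels = np.full(gt.mask.shape, UNLABELLED, dtype=np.int16)
        for cls in (MASK_BACKGROUND, MASK_TUBULE, MASK_SHEET):
            idx = np.flatnonzero((gt.mask == cls).ravel())
            if idx.size == 0:
                continue
            take = idx[rng.choice(idx.size, size=min(per_scene, idx.size),
                                  replace=False)]
            labels.ravel()[take] = cls
        out.append((img, labels))
    return out
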