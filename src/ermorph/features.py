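"""Per-pixel feature bank for trainable ER pixel classification.

The bank mirrors the classic trainable-segmentation recipe: per scale a
Gaussian blur, Sobel gradient magnitude, both Hessian eigenvalues and a
difference of Gaussians; plus membrane projections, i.e. the z-aggregation
(sum, mean, max, min, median, std) of the image's response to a thin line
kernel swept over 30 orientations.  The input is z-normalized first, which
makes every downstream classification invariant to uniform intensity
rescaling.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.feature import hessian_matrix, hessian_matrix_eigvals
from skimage.transform import rotate

from .image import Image

DEFAULT_SCALES = (1, 2, 4, 8)
MEMBRANE_KERNEL_LEN = 19
MEMBRANE_N_ORIENT = 30
_MEMBRANE_AGGS = ("sum", "mean", "max", "min", "median", "std")


@dataclass
class FeatureStack:
    """Named per-pixel feature planes, all the shape of the source image."""

    planes: dict[str, np.ndarray]
    scales: tuple[int, ...]
    config_hash: str

    @property
    def names(self) -> list[str]:
        return sorted(self.planes)

    def matrix(self) -> np.ndarray:
        """(n_pixels, n_features) design matrix in sorted plane order."""
        return np.stack([self.planes[k].ravel() for k in self.names], axis=1)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.planes.values())).shape


def feature_config_hash(scales: Sequence[int],
                        kernel_len: int = MEMBRANE_KERNEL_LEN,
                        n_orient: int = MEMBRANE_N_ORIENT) -> str:
    key = f"scales={tuple(int(s) for s in scales)};line={kernel_len};nor={n_orient}"
    return hashlib.md5(key.encode()).hexdigest()[:12]


def _membrane_kernels(length: int = MEMBRANE_KERNEL_LEN,
                      n_orient: int = MEMBRANE_N_ORIENT) -> np.ndarray:
    base = np.zeros((length, length))
    base[:, length // 2] = 1.0
    kernels = np.empty((n_orient, length, length))
    for i in range(n_orient):
        kernels[i] = rotate(base, i * 180.0 / n_orient, order=1,
                            preserve_range=True)
        kernels[i] /= kernels[i].sum()
    return kernels


def line_kernel(angle_deg: float, length: int = MEMBRANE_KERNEL_LEN) -> np.ndarray:
    """Single normalized line kernel at the given orientation (for oracles)."""
    base = np.zeros((length, length))
    base[:, length // 2] = 1.0
    k = rotate(base, angle_deg, order=1, preserve_range=True)
    return k / k.sum()


def compute_features(img: Image, scales: Sequence[int] = DEFAULT_SCALES) -> FeatureStack:
    """Build the feature stack at the configured scales (px)."""
    scales = tuple(int(s) for s in scales)
    if len(scales) == 0 or any(s < 1 for s in scales):
        raise ValueError("scales must be non-empty, each >= 1 px")
    data = img.data
    if min(data.shape) < MEMBRANE_KERNEL_LEN or min(data.shape) < 4 * max(scales):
        raise ValueError("image smaller than the largest kernel")
    std = data.std()
    norm = (data - data.mean()) / std if std > 0 else np.zeros_like(data)

    planes: dict[str, np.ndarray] = {"original": norm}
    for s in scales:
        g = ndimage.gaussian_filter(norm, s)
        planes[f"gaussian_s{s}"] = g
        gx = ndimage.sobel(g, axis=1)
        gy = ndimage.sobel(g, axis=0)
        planes[f"sobel_s{s}"] = np.hypot(gx, gy)
        H = hessian_matrix(norm, sigma=s, order="rc", use_gaussian_derivatives=False)
        ev = hessian_matrix_eigvals(H)
        planes[f"hessian_e1_s{s}"] = ev[0]
        planes[f"hessian_e2_s{s}"] = ev[1]
        planes[f"dog_s{s}"] = g - ndimage.gaussian_filter(norm, 2 * s)

    kernels = _membrane_kernels()
    resp = np.empty((kernels.shape[0],) + norm.shape)
    for i, k in enumerate(kernels):
        resp[i] = ndimage.convolve(norm, k, mode="reflect")
    planes["membrane_sum"] = resp.sum(axis=0)
    planes["membrane_mean"] = resp.mean(axis=0)
    planes["membrane_max"] = resp.max(axis=0)
    planes["membrane_min"] = resp.min(axis=0)
    planes["membrane_median"] = np.median(resp, axis=0)
    planes["membrane_std"] = resp.std(axis=0)

    return FeatureStack(planes=planes, scales=scales,
                        config_hash=feature_config_hash(scales))
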