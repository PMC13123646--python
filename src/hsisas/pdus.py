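"""Power-Doppler ultrasound quantification.

Given an RGB ultrasound frame and an expert-drawn synovial polygon, measure
the synovial area (rasterized polygon pixel count) and the power-Doppler
area (thresholded red-gray pixel count inside the ROI).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon as _ShapelyPolygon

from .errors import DegenerateInputError, DimensionError, HsisasError
from .segmentation import otsu_threshold

__all__ = [
    "UltrasoundFrame",
    "SynovialROI",
    "rasterize_roi",
    "red_gray",
    "pd_area",
]


@dataclass
class UltrasoundFrame:
    rgb: np.ndarray  # (rows, cols, 3) uint8
    pixel_spacing_mm: float | None = None

    def __post_init__(self) -> None:
        self.rgb = np.asarray(self.rgb)
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise DimensionError("frame must be a 3-channel RGB image")
        if self.rgb.min() < 0 or self.rgb.max() > 255:
            raise HsisasError("channel values must lie in [0, 255]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.rgb.shape[:2]


@dataclass
class SynovialROI:
    polygon: np.ndarray  # (k, 2) of (row, col) vertices
    mask: np.ndarray

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


def _points_in_polygon(points: np.ndarray, verts: np.ndarray) -> np.ndarray:
    """Even-odd rule with boundary points counted as inside.

    ``points`` is (N, 2) of (row, col); ``verts`` is (k, 2). Vectorized over
    points, looping over edges.
    """
    py, px = points[:, 0].astype(float), points[:, 1].astype(float)
    inside = np.zeros(len(points), dtype=bool)
    on_edge = np.zeros(len(points), dtype=bool)
    k = len(verts)
    for i in range(k):
        y1, x1 = verts[i].astype(float)
        y2, x2 = verts[(i + 1) % k].astype(float)
        # on-segment test
        cross = (px - x1) * (y2 - y1) - (py - y1) * (x2 - x1)
        within = (
            (np.minimum(x1, x2) - 1e-9 <= px) & (px <= np.maximum(x1, x2) + 1e-9)
            & (np.minimum(y1, y2) - 1e-9 <= py) & (py <= np.maximum(y1, y2) + 1e-9)
        )
        on_edge |= (np.abs(cross) < 1e-9) & within
        # ray cast along +x with the half-open rule on y
        cond = (y1 <= py) != (y2 <= py)
        with np.errstate(divide="ignore", invalid="ignore"):
            x_int = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
        inside ^= cond & (px < x_int)
    return inside | on_edge


def rasterize_roi(frame: UltrasoundFrame, polygon) -> SynovialROI:
    """Rasterize a simple polygon of (row, col) vertices onto the frame grid.

    Pixels whose integer centers fall inside by the even-odd rule, including
    centers exactly on the boundary, belong to the ROI.
    """
    verts = np.asarray(polygon, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
        raise DegenerateInputError("polygon needs at least 3 (row, col) vertices")
    rows, cols = frame.shape
    if (verts[:, 0].min() < 0 or verts[:, 0].max() > rows - 1
            or verts[:, 1].min() < 0 or verts[:, 1].max() > cols - 1):
        raise HsisasError("polygon vertex outside image bounds")
    ring = _ShapelyPolygon([(c, r) for r, c in verts])
    if not ring.is_valid:
        raise HsisasError("self-intersecting polygon")

    r0, r1 = int(np.floor(verts[:, 0].min())), int(np.ceil(verts[:, 0].max()))
    c0, c1 = int(np.floor(verts[:, 1].min())), int(np.ceil(verts[:, 1].max()))
    rr, cc = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1),
                         indexing="ij")
    pts = np.column_stack([rr.ravel(), cc.ravel()])
    inside = _points_in_polygon(pts, verts).reshape(rr.shape)

    mask = np.zeros((rows, cols), dtype=bool)
    mask[r0:r1 + 1, c0:c1 + 1] = inside
    return SynovialROI(polygon=verts, mask=mask)


def red_gray(frame: UltrasoundFrame, mode: str = "red") -> np.ndarray:
    """Reduce an RGB frame to the Doppler-relevant gray image.

    ``red`` returns the red channel; ``reddom`` returns
    ``max(R - max(G, B), 0)``, which is zero on achromatic echo and isolates
    the painted Doppler overlay.
    """
    r = frame.rgb[:, :, 0].astype(np.int16)
    if mode == "red":
        return r.astype(np.uint8)
    if mode == "reddom":
        gb = np.maximum(frame.rgb[:, :, 1], frame.rgb[:, :, 2]).astype(np.int16)
        return np.maximum(r - gb, 0).astype(np.uint8)
    raise ValueError(f"unknown red-gray mode '{mode}'")


def pd_area(
    gray: np.ndarray,
    roi: SynovialROI,
    threshold: float | str = "auto",
) -> int:
    """Count ROI pixels whose gray value exceeds the threshold.

    ``threshold='auto'`` applies Otsu within the ROI; a constant ROI counts
    as zero Doppler signal.
    """
    gray = np.asarray(gray)
    if gray.shape != roi.mask.shape:
        raise DimensionError("gray image and ROI mask shapes differ")
    values = gray[roi.mask]
    if values.size == 0:
        raise DegenerateInputError("empty synovial ROI")
    if threshold == "auto":
        try:
            thr = otsu_threshold(values.astype(float))
        except DegenerateInputError:
            return 0
    else:
        thr = float(threshold)
    return int(np.count_nonzero(values > thr))
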