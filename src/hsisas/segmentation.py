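"""Wrist ROI extraction: band-ratio contrast, Otsu binarization, wrist band.

The foreground (hand) is separated from the imaging board by the ratio of
the 1303 nm band to the 1453 nm band (deep tissue-water absorption), then a
fixed-height band of rows anchored at an operator-supplied wrist row is cut
out of the hand mask and its pixel spectra gathered in raster order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .cube_io import ReflectanceCube, nearest_band
from .errors import DegenerateInputError, DimensionError, SegmentationError

__all__ = [
    "RatioImage",
    "WristROI",
    "band_ratio",
    "otsu_threshold",
    "segment_hand",
    "extract_wrist_roi",
]

RATIO_NUMERATOR_NM = 1303.0
RATIO_DENOMINATOR_NM = 1453.0
DEFAULT_EXTENSION_ROWS = 100
_RATIO_EPS = 1e-9


@dataclass
class RatioImage:
    data: np.ndarray
    numerator_nm: float
    denominator_nm: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise DimensionError("ratio image must be 2-D")


@dataclass
class WristROI:
    """Boolean wrist mask plus the (n, L) matrix of spectra under it."""

    mask: np.ndarray
    wrist_row: int
    extension_rows: int
    spectra: np.ndarray
    subject_id: str = ""
    hand: str = ""
    visit: str = ""
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return int(self.spectra.shape[0])

    @property
    def L(self) -> int:
        return int(self.spectra.shape[1])


def band_ratio(
    cube: ReflectanceCube,
    numerator_nm: float = RATIO_NUMERATOR_NM,
    denominator_nm: float = RATIO_DENOMINATOR_NM,
) -> RatioImage:
    """Element-wise ratio of two bands, denominator guarded by a small eps."""
    b_num = nearest_band(cube.axis, numerator_nm)
    b_den = nearest_band(cube.axis, denominator_nm)
    num = cube.data[:, :, b_num]
    den = np.maximum(cube.data[:, :, b_den], _RATIO_EPS)
    return RatioImage(num / den, numerator_nm, denominator_nm)


def otsu_threshold(image: np.ndarray, n_bins: int = 256) -> float:
    """Histogram-bin-edge threshold maximizing between-class variance.

    Returns the upper edge of the bin at which the split is made; pixels
    strictly above the threshold are foreground. Ties break toward the lower
    threshold. Raises on constant images.
    """
    image = np.asarray(image, dtype=np.float64).ravel()
    lo, hi = float(image.min()), float(image.max())
    if hi <= lo:
        raise DegenerateInputError("constant image has no Otsu threshold")

    counts, edges = np.histogram(image, bins=n_bins, range=(lo, hi))
    counts = counts.astype(np.float64)
    total = counts.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])

    w0 = np.cumsum(counts)
    w1 = total - w0
    sum0 = np.cumsum(counts * centers)
    mu_total = sum0[-1]
    # between-class variance for a split after bin t (thresholds edges[1:])
    valid = (w0 > 0) & (w1 > 0)
    mu0 = np.divide(sum0, w0, out=np.zeros_like(sum0), where=w0 > 0)
    mu1 = np.divide(mu_total - sum0, w1, out=np.zeros_like(sum0), where=w1 > 0)
    sigma_b = np.where(valid, w0 * w1 * (mu0 - mu1) ** 2, -np.inf)
    best = int(np.argmax(sigma_b))  # argmax takes the first (lowest) maximum
    if not np.isfinite(sigma_b[best]):
        raise DegenerateInputError("no valid split found")
    return float(edges[best + 1])


def segment_hand(
    ratio: RatioImage,
    n_bins: int = 256,
    clean: bool = True,
) -> np.ndarray:
    """Otsu-binarize the ratio image and keep the hand foreground.

    The foreground is whichever side of the threshold has the higher mean
    ratio. With ``clean`` (default) a 3x3 morphological closing is applied
    and only the largest 4-connected component kept.
    """
    thr = otsu_threshold(ratio.data, n_bins=n_bins)
    above = ratio.data > thr
    if not above.any() or above.all():
        raise SegmentationError("degenerate binarization")
    mean_above = ratio.data[above].mean()
    mean_below = ratio.data[~above].mean()
    mask = above if mean_above >= mean_below else ~above

    if clean:
        mask = ndimage.binary_closing(mask, structure=np.ones((3, 3), bool))
        labels, n_comp = ndimage.label(
            mask, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
        )
        if n_comp == 0:
            raise SegmentationError("empty foreground after cleanup")
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n_comp + 1))
        mask = labels == (int(np.argmax(sizes)) + 1)
    if not mask.any():
        raise SegmentationError("empty foreground")
    return mask


def extract_wrist_roi(
    cube: ReflectanceCube,
    hand_mask: np.ndarray,
    wrist_row: int,
    extension_rows: int = DEFAULT_EXTENSION_ROWS,
    direction: str = "down",
    **roi_meta,
) -> WristROI:
    """Cut a fixed-height band of the hand mask anchored at ``wrist_row``.

    The band is half-open: rows ``[wrist_row, wrist_row + extension_rows)``
    for ``direction='down'`` (rows increasing toward the forearm), or
    ``(wrist_row - extension_rows, wrist_row]`` for ``'up'``; both are
    clamped at the image border. Spectra are gathered in row-major order.
    """
    rows, cols, _ = cube.shape
    hand_mask = np.asarray(hand_mask, dtype=bool)
    if hand_mask.shape != (rows, cols):
        raise DimensionError("hand mask shape does not match cube")
    if not (0 <= wrist_row < rows):
        raise SegmentationError(f"wrist_row {wrist_row} outside [0, {rows})")

    if direction == "down":
        r0, r1 = wrist_row, min(wrist_row + extension_rows, rows)
    elif direction == "up":
        r0, r1 = max(wrist_row - extension_rows + 1, 0), wrist_row + 1
    else:
        raise ValueError(f"unknown direction '{direction}'")

    band = np.zeros_like(hand_mask)
    band[r0:r1, :] = True
    mask = hand_mask & band
    if not mask.any():
        raise SegmentationError("empty wrist ROI")
    spectra = cube.data[mask]  # row-major gather
    return WristROI(
        mask=mask,
        wrist_row=wrist_row,
        extension_rows=extension_rows,
        spectra=spectra,
        **roi_meta,
    )
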