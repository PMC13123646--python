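"""Figure-style outputs: mean +/- SD spectra, red-to-green abundance maps,
and the intra/inter 2-D score projection."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .cube_io import ReflectanceCube, SpectralAxis, nearest_band
from .errors import DegenerateInputError
from .scoring import AbundanceMap, ScoreRecord

__all__ = [
    "abundance_rgb",
    "plot_mean_spectra",
    "render_abundance_map",
    "plot_projection",
    "separation_statistic",
]


def plot_mean_spectra(
    pre_pool: np.ndarray,
    post_pool: np.ndarray,
    axis: SpectralAxis,
    path: str | Path,
) -> Path:
    """Mean spectrum +/- 1 SD band for the pooled pre and post pixels."""
    pre_pool = np.asarray(pre_pool, float)
    post_pool = np.asarray(post_pool, float)
    if pre_pool.size == 0 or post_pool.size == 0:
        raise DegenerateInputError("empty spectra pool")
    wl = axis.wavelengths_nm
    fig, ax = plt.subplots(figsize=(7, 4))
    for pool, label, color in ((pre_pool, "pre-treatment", "tab:red"),
                               (post_pool, "post-treatment", "tab:green")):
        mean = pool.mean(axis=0)
        sd = pool.std(axis=0)
        ax.plot(wl, mean, color=color, label=label)
        ax.fill_between(wl, mean - sd, mean + sd, color=color, alpha=0.25)
    ax.set_xlabel("wavelength (nm)")
    ax.set_ylabel("reflectance")
    ax.legend()
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def abundance_rgb(amap: AbundanceMap,
                  backdrop_cube: ReflectanceCube | None = None) -> np.ndarray:
    """Render scores red (0) -> green (1), display-clipped to [0, 1].

    Non-ROI pixels show the 1303-nm band as a grayscale backdrop when a
    reflectance cube is supplied, else black.
    """
    rows, cols = amap.scores.shape
    rgb = np.zeros((rows, cols, 3), dtype=float)
    if backdrop_cube is not None:
        band = backdrop_cube.data[:, :, nearest_band(backdrop_cube.axis, 1303.0)]
        lo, hi = band.min(), band.max()
        gray = (band - lo) / (hi - lo) if hi > lo else np.zeros_like(band)
        rgb[:] = gray[:, :, None]
    s = np.clip(amap.scores[amap.mask], 0.0, 1.0)
    rgb[amap.mask] = np.column_stack([1.0 - s, s, np.zeros_like(s)])
    return rgb


def render_abundance_map(
    amap: AbundanceMap,
    path: str | Path,
    backdrop_cube: ReflectanceCube | None = None,
) -> Path:
    import imageio.v3 as iio

    rgb = abundance_rgb(amap, backdrop_cube)
    path = Path(path)
    iio.imwrite(path, (rgb * 255).astype(np.uint8))
    return path


def separation_statistic(records: list[ScoreRecord]) -> float | None:
    """Distance between the pre and post centroids in (intra, inter) space,
    divided by the pooled within-group SD; None if only one group."""
    pts = {"pre": [], "post": []}
    for rec in records:
        if np.isfinite(rec.intra_score) and np.isfinite(rec.inter_score):
            pts[rec.visit].append((rec.intra_score, rec.inter_score))
    if not pts["pre"] or not pts["post"]:
        return None
    pre = np.asarray(pts["pre"])
    post = np.asarray(pts["post"])
    dist = float(np.linalg.norm(pre.mean(axis=0) - post.mean(axis=0)))
    pooled = np.sqrt(
        0.5 * (pre.var(axis=0).mean() + post.var(axis=0).mean())
    )
    return dist / pooled if pooled > 0 else np.inf


def plot_projection(records: list[ScoreRecord], path: str | Path) -> Path:
    """Scatter of (intra, inter) wrist scores, pre vs post markers, with
    group centroids and the separation statistic in the title."""
    fig, ax = plt.subplots(figsize=(5, 5))
    for visit, marker, color in (("pre", "o", "tab:red"),
                                 ("post", "^", "tab:green")):
        pts = np.asarray([
            (r.intra_score, r.inter_score) for r in records
            if r.visit == visit and np.isfinite(r.intra_score)
            and np.isfinite(r.inter_score)
        ])
        if len(pts) == 0:
            continue
        ax.scatter(pts[:, 0], pts[:, 1], marker=marker, color=color,
                   label=visit, alpha=0.8)
        centroid = pts.mean(axis=0)
        ax.scatter(*centroid, marker="x", color=color, s=120, linewidths=3)
    sep = separation_statistic(records)
    if sep is not None:
        ax.set_title(f"centroid separation / pooled SD = {sep:.2f}")
    ax.set_xlabel("Intra score")
    ax.set_ylabel("Inter score")
    ax.legend()
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
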