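"""Intra- and inter-subject spectral correlation matrices.

The intra matrix is the band-pair Pearson cross-correlation between
pre-treatment band a and post-treatment band b across paired wrist pixels;
the inter matrix pools the paired pixels of every subject in the cohort.
An alternative ``autocorrelation`` mode computes the classical sample
autocorrelation (1/N) * sum r r^T of the pooled spectra. Because the number
of paired pixels can be smaller than the band count the inverse used by the
scoring stage is ridge-regularized after symmetrization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, DimensionError, HsisasError
from .segmentation import WristROI

__all__ = [
    "PairedSpectra",
    "CorrelationMatrix",
    "pair_pixels",
    "stack_paired",
    "cross_band_correlation",
    "inter_correlation",
    "pooled_autocorrelation",
    "regularized_inverse",
]


@dataclass
class PairedSpectra:
    """Pre/post wrist spectra paired on a common pixel index."""

    X: np.ndarray  # (n, L) pre-treatment
    Y: np.ndarray  # (n, L) post-treatment
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.Y = np.asarray(self.Y, dtype=np.float64)
        if self.X.shape != self.Y.shape:
            raise DimensionError(
                f"paired shapes differ: {self.X.shape} vs {self.Y.shape}"
            )
        if self.X.ndim != 2 or self.X.shape[0] == 0:
            raise DimensionError("paired spectra must be a non-empty (n, L) matrix")

    @property
    def n(self) -> int:
        return int(self.X.shape[0])

    @property
    def L(self) -> int:
        return int(self.X.shape[1])

    @property
    def x_bar(self) -> np.ndarray:
        return self.X.mean(axis=0)

    @property
    def y_bar(self) -> np.ndarray:
        return self.Y.mean(axis=0)


@dataclass
class CorrelationMatrix:
    """L x L correlation structure with its regularized inverse."""

    R: np.ndarray
    kind: str  # 'intra' or 'inter'
    ridge_lambda: float
    R_inv: np.ndarray
    n_effective: int
    m: int = 1
    mode: str = "pearson"
    meta: dict = field(default_factory=dict)

    @property
    def L(self) -> int:
        return int(self.R.shape[0])


def pair_pixels(
    pre_roi: WristROI,
    post_roi: WristROI,
    strategy: str = "truncate",
    seed: int | None = None,
) -> PairedSpectra:
    """Pair pre/post ROI pixels on a common index.

    ``truncate`` (default) keeps the first ``n = min(n_pre, n_post)`` rows
    of each ROI in raster order; ``subsample`` draws ``n`` rows without
    replacement from each using ``seed``.
    """
    if pre_roi.n == 0 or post_roi.n == 0:
        raise DegenerateInputError("cannot pair an empty ROI")
    if pre_roi.L != post_roi.L:
        raise DimensionError("band counts differ between pre and post ROIs")
    n = min(pre_roi.n, post_roi.n)
    if strategy == "truncate":
        X, Y = pre_roi.spectra[:n], post_roi.spectra[:n]
    elif strategy == "subsample":
        if seed is None:
            raise ValueError("subsample pairing requires an explicit seed")
        rng = np.random.default_rng(seed)
        ix = np.sort(rng.choice(pre_roi.n, size=n, replace=False))
        iy = np.sort(rng.choice(post_roi.n, size=n, replace=False))
        X, Y = pre_roi.spectra[ix], post_roi.spectra[iy]
    else:
        raise ValueError(f"unknown pairing strategy '{strategy}'")
    return PairedSpectra(X=X, Y=Y, subject_id=pre_roi.subject_id)


def stack_paired(parts: list[PairedSpectra], subject_id: str = "") -> PairedSpectra:
    """Concatenate paired spectra (e.g. both hands of one subject)."""
    if not parts:
        raise DegenerateInputError("nothing to stack")
    return PairedSpectra(
        X=np.vstack([p.X for p in parts]),
        Y=np.vstack([p.Y for p in parts]),
        subject_id=subject_id or parts[0].subject_id,
    )


def _band_pair_pearson(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    ssx = np.einsum("ij,ij->j", Xc, Xc)
    ssy = np.einsum("ij,ij->j", Yc, Yc)
    for name, ss in (("pre", ssx), ("post", ssy)):
        zero = np.flatnonzero(ss <= 0)
        if zero.size:
            raise DegenerateInputError(
                f"zero-variance {name} band(s) at index {zero.tolist()}"
            )
    R = (Xc.T @ Yc) / np.sqrt(np.outer(ssx, ssy))
    return R


def cross_band_correlation(
    P: PairedSpectra,
    ridge_lambda: float | str = "auto",
) -> CorrelationMatrix:
    """Intra-subject matrix: R[a, b] = Pearson(pre band a, post band b)."""
    R = _band_pair_pearson(P.X, P.Y)
    lam, R_inv = regularized_inverse(R, ridge_lambda, return_lambda=True)
    return CorrelationMatrix(
        R=R, kind="intra", ridge_lambda=lam, R_inv=R_inv,
        n_effective=P.n, m=1, mode="pearson",
        meta={"subject_id": P.subject_id},
    )


def inter_correlation(
    cohort: list[PairedSpectra],
    ridge_lambda: float | str = "auto",
) -> CorrelationMatrix:
    """Inter-subject matrix: same formula over the pooled pixels of all
    subjects, with the means taken over the pooled set."""
    if not cohort:
        raise DegenerateInputError("empty cohort")
    Ls = {p.L for p in cohort}
    if len(Ls) > 1:
        raise DimensionError(f"mixed band counts across subjects: {sorted(Ls)}")
    X = np.vstack([p.X for p in cohort])
    Y = np.vstack([p.Y for p in cohort])
    R = _band_pair_pearson(X, Y)
    lam, R_inv = regularized_inverse(R, ridge_lambda, return_lambda=True)
    return CorrelationMatrix(
        R=R, kind="inter", ridge_lambda=lam, R_inv=R_inv,
        n_effective=X.shape[0], m=len(cohort), mode="pearson",
    )


def pooled_autocorrelation(
    spectra: np.ndarray,
    kind: str = "intra",
    ridge_lambda: float | str = "auto",
) -> CorrelationMatrix:
    """Classical CEM sample autocorrelation (1/N) * sum r r^T."""
    S = np.asarray(spectra, dtype=np.float64)
    if S.ndim != 2 or S.shape[0] == 0:
        raise DimensionError("spectra must be a non-empty (n, L) matrix")
    R = (S.T @ S) / S.shape[0]
    lam, R_inv = regularized_inverse(R, ridge_lambda, return_lambda=True)
    return CorrelationMatrix(
        R=R, kind=kind, ridge_lambda=lam, R_inv=R_inv,
        n_effective=S.shape[0], mode="autocorrelation",
    )


def regularized_inverse(
    R: np.ndarray,
    ridge_lambda: float | str = "auto",
    symmetrize: bool = True,
    return_lambda: bool = False,
):
    """Invert ``(sym(R) + lambda I)``.

    ``ridge_lambda='auto'`` starts at ``1e-6 * trace/L``; if the regularized
    matrix is still not positive definite the ridge is raised to just above
    the magnitude of the most negative eigenvalue (with a x10 escalation
    fallback), keeping the ridge as small as the spectrum allows so the
    whitening of dominant directions is preserved.
    """
    R = np.asarray(R, dtype=np.float64)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise DimensionError("R must be square")
    if not np.all(np.isfinite(R)):
        raise HsisasError("R contains non-finite entries")
    R_s = 0.5 * (R + R.T) if symmetrize else R

    L = R.shape[0]
    if ridge_lambda == "auto":
        lam = 1e-6 * float(np.trace(R_s)) / L
        if lam <= 0:
            lam = 1e-6
        min_eig = float(np.linalg.eigvalsh(0.5 * (R_s + R_s.T)).min())
        if min_eig + lam <= 1e-10:
            lam = max(lam, 1.05 * abs(min_eig) + 1e-9)
        while np.linalg.eigvalsh(R_s + lam * np.eye(L)).min() <= 1e-10:
            lam *= 10.0
    else:
        lam = float(ridge_lambda)
    R_inv = np.linalg.inv(R_s + lam * np.eye(L))
    if return_lambda:
        return lam, R_inv
    return R_inv
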