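"""CEM-based soft abundance scoring.

A target signature ``d`` (mean post-treatment wrist spectrum, at subject or
cohort scope) is scored against every ROI pixel spectrum ``r`` through the
constrained-energy-minimization functional

    score(r) = (r . R_inv . d) / (d^T . R_inv . d)

which responds with exactly 1 to the target itself. Per-wrist scalars are
pixel reductions of the resulting abundance maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .correlation import (
    CorrelationMatrix,
    cross_band_correlation,
    inter_correlation,
    pair_pixels,
    stack_paired,
)
from .errors import DegenerateInputError, DimensionError
from .segmentation import WristROI

__all__ = [
    "TargetSignature",
    "AbundanceMap",
    "ScoreRecord",
    "build_target",
    "cem_score",
    "score_map",
    "wrist_score",
    "score_cohort",
]

logger = logging.getLogger(__name__)

HANDS = ("L", "R")
VISITS = ("pre", "post")


@dataclass
class TargetSignature:
    d: np.ndarray  # (L,)
    scope: str  # 'subject' or 'cohort'
    source_rois: tuple = ()

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=np.float64).ravel()
        if self.d.size == 0 or not np.all(np.isfinite(self.d)):
            raise DegenerateInputError("target signature must be finite")
        if not np.any(self.d):
            raise DegenerateInputError("target signature is identically zero")

    @property
    def L(self) -> int:
        return int(self.d.size)


@dataclass
class AbundanceMap:
    """Per-pixel scores over an ROI; NaN outside the ROI."""

    scores: np.ndarray
    mask: np.ndarray
    kind: str
    target_scope: str
    R_meta: dict = field(default_factory=dict)

    @property
    def roi_values(self) -> np.ndarray:
        return self.scores[self.mask]


@dataclass
class ScoreRecord:
    subject_id: str
    hand: str
    visit: str
    intra_score: float = np.nan
    inter_score: float = np.nan
    n_pixels: int = 0
    reducer: str = "mean"
    ridge_lambda_intra: float = np.nan
    ridge_lambda_inter: float = np.nan


def build_target(post_rois: list[WristROI], scope: str) -> TargetSignature:
    """Pixel-weighted mean spectrum over the pooled post-treatment ROIs."""
    if scope not in ("subject", "cohort"):
        raise ValueError(f"unknown target scope '{scope}'")
    if not post_rois:
        raise DegenerateInputError("no ROIs to build target from")
    pooled = np.vstack([roi.spectra for roi in post_rois])
    if pooled.shape[0] == 0:
        raise DegenerateInputError("empty pixel pool for target")
    return TargetSignature(
        d=pooled.mean(axis=0),
        scope=scope,
        source_rois=tuple(
            (roi.subject_id, roi.hand, roi.visit) for roi in post_rois
        ),
    )


def cem_score(
    spectrum: np.ndarray,
    R_inv: np.ndarray,
    d: TargetSignature | np.ndarray,
    denominator: str = "inverse",
) -> float:
    """Score one spectrum.

    ``denominator='inverse'`` (default) uses d^T R_inv d, the normalization
    under which the target itself scores exactly 1; ``'plain'`` uses
    d^T (R_inv^-1) d instead.
    """
    r = np.asarray(spectrum, dtype=np.float64).ravel()
    dv = d.d if isinstance(d, TargetSignature) else np.asarray(d, float).ravel()
    R_inv = np.asarray(R_inv, dtype=np.float64)
    if r.size != dv.size or R_inv.shape != (dv.size, dv.size):
        raise DimensionError("dimension mismatch between r, R_inv and d")
    w = R_inv @ dv
    if denominator == "inverse":
        denom = float(dv @ w)
    elif denominator == "plain":
        denom = float(dv @ np.linalg.solve(R_inv, dv))
    else:
        raise ValueError(f"unknown denominator mode '{denominator}'")
    if abs(denom) < 1e-30:
        raise DegenerateInputError("singular target: d^T R d vanishes")
    return float(r @ w) / denom


def score_map(
    roi: WristROI,
    R: CorrelationMatrix,
    d: TargetSignature,
    denominator: str = "inverse",
) -> AbundanceMap:
    """Score every ROI pixel via one matrix-vector product ``w = R_inv d``
    followed by per-pixel dot products (identical to per-pixel scoring)."""
    if roi.L != d.L or R.L != d.L:
        raise DimensionError(
            f"band mismatch: roi L={roi.L}, R L={R.L}, d L={d.L}"
        )
    w = R.R_inv @ d.d
    if denominator == "inverse":
        denom = float(d.d @ w)
    elif denominator == "plain":
        denom = float(d.d @ np.linalg.solve(R.R_inv, d.d))
    else:
        raise ValueError(f"unknown denominator mode '{denominator}'")
    if abs(denom) < 1e-30:
        raise DegenerateInputError("singular target: d^T R d vanishes")
    values = (roi.spectra @ w) / denom

    scores = np.full(roi.mask.shape, np.nan)
    scores[roi.mask] = values
    return AbundanceMap(
        scores=scores,
        mask=roi.mask,
        kind=R.kind,
        target_scope=d.scope,
        R_meta={"ridge_lambda": R.ridge_lambda, "mode": R.mode,
                "n_effective": R.n_effective, "m": R.m},
    )


def wrist_score(amap: AbundanceMap, reducer: str = "mean") -> float:
    """Reduce an abundance map to one scalar per wrist."""
    values = amap.roi_values
    if values.size == 0:
        raise DegenerateInputError("empty abundance map")
    if reducer == "mean":
        return float(values.mean())
    if reducer == "median":
        return float(np.median(values))
    if reducer == "trimmed_mean":
        from scipy.stats import trim_mean

        return float(trim_mean(values, 0.10))
    raise ValueError(f"unknown reducer '{reducer}'")


def score_cohort(
    rois: dict[str, dict[str, dict[str, WristROI]]],
    reducer: str = "mean",
    pairing: str = "truncate",
    seed: int | None = None,
    ridge_lambda: float | str = "auto",
    corr_mode: str = "pearson",
) -> list[ScoreRecord]:
    """Full-cohort scoring.

    ``rois[subject][hand][visit]`` holds the wrist ROIs. Per subject the
    intra correlation matrix and subject-scope target are estimated from
    that subject's paired pre/post pixels of both hands; the inter matrix
    and cohort-scope target pool every subject. Subjects missing a visit
    are excluded from intra scoring with a warning but still contribute
    nothing to pairing-based estimates. Returns one record per
    (subject, hand, visit) present.

    ``corr_mode='pearson'`` (default) builds the band-pair Pearson
    cross-correlation of the paired pre/post pixels; ``'autocorrelation'``
    builds the classical CEM sample autocorrelation of the pooled pre+post
    spectra instead.
    """
    if corr_mode not in ("pearson", "autocorrelation"):
        raise ValueError(f"unknown corr_mode '{corr_mode}'")
    paired_by_subject: dict[str, list] = {}
    complete_subjects = []
    for sid, hands in sorted(rois.items()):
        parts = []
        for hand in HANDS:
            visits = hands.get(hand, {})
            if "pre" in visits and "post" in visits:
                parts.append(
                    pair_pixels(visits["pre"], visits["post"],
                                strategy=pairing, seed=seed)
                )
        if parts:
            paired_by_subject[sid] = parts
            complete_subjects.append(sid)
        else:
            logger.warning(
                "subject %s lacks a complete pre/post pair; excluded from "
                "intra scoring", sid,
            )

    # cohort-level structures
    pooled_pairs = [
        stack_paired(paired_by_subject[sid], subject_id=sid)
        for sid in complete_subjects
    ]
    if corr_mode == "pearson":
        inter_R = inter_correlation(pooled_pairs, ridge_lambda=ridge_lambda)
    else:
        from .correlation import pooled_autocorrelation

        pooled = np.vstack([np.vstack([p.X, p.Y]) for p in pooled_pairs])
        inter_R = pooled_autocorrelation(pooled, kind="inter",
                                         ridge_lambda=ridge_lambda)
        inter_R.m = len(pooled_pairs)
    cohort_post_rois = [
        hands[hand]["post"]
        for sid, hands in sorted(rois.items())
        for hand in HANDS
        if "post" in hands.get(hand, {})
    ]
    cohort_d = build_target(cohort_post_rois, scope="cohort")

    records: list[ScoreRecord] = []
    for sid, hands in sorted(rois.items()):
        intra_R = None
        subject_d = None
        if sid in paired_by_subject:
            subject_pairs = stack_paired(paired_by_subject[sid],
                                         subject_id=sid)
            if corr_mode == "pearson":
                intra_R = cross_band_correlation(subject_pairs,
                                                 ridge_lambda=ridge_lambda)
            else:
                from .correlation import pooled_autocorrelation

                intra_R = pooled_autocorrelation(
                    np.vstack([subject_pairs.X, subject_pairs.Y]),
                    kind="intra", ridge_lambda=ridge_lambda,
                )
            subject_post = [
                hands[h]["post"] for h in HANDS
                if "post" in hands.get(h, {})
            ]
            subject_d = build_target(subject_post, scope="subject")
        for hand in HANDS:
            for visit in VISITS:
                roi = hands.get(hand, {}).get(visit)
                if roi is None:
                    continue
                rec = ScoreRecord(
                    subject_id=sid, hand=hand, visit=visit,
                    n_pixels=roi.n, reducer=reducer,
                    ridge_lambda_inter=inter_R.ridge_lambda,
                )
                if intra_R is not None:
                    rec.intra_score = wrist_score(
                        score_map(roi, intra_R, subject_d), reducer=reducer
                    )
                    rec.ridge_lambda_intra = intra_R.ridge_lambda
                rec.inter_score = wrist_score(
                    score_map(roi, inter_R, cohort_d), reducer=reducer
                )
                records.append(rec)
    return records
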