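"""Cohort statistics: median/IQR summaries, Wilcoxon signed-rank tests,
Spearman correlations, and improvement-oriented change tables.

Wrist-level variables (synovial area, PD area, the two abundance scores) are
analyzed per wrist; DAS28 is a patient-level covariate assigned to both
wrists of a visit, and wrists missing a DAS28 visit are excluded from
DAS28-related analyses only.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateInputError, HsisasError

__all__ = [
    "WILCOXON_EXACT_MAX_N",
    "VARIABLES",
    "median_iqr",
    "wilcoxon_signed_rank",
    "spearman_rho",
    "improvement_deltas",
    "paper_tables",
]

# variable name -> (delta sign convention, pretty label)
#   'decrease': improvement is pre - post; 'increase': post - pre
VARIABLES = {
    "roi_syn_area_px": ("decrease", "ROI_Syn area (pixels)"),
    "pd_area_px": ("decrease", "PD area (pixels)"),
    "intra_hsisas": ("increase", "Intra_HSISAS"),
    "inter_hsisas": ("increase", "Inter_HSISAS"),
    "das28": ("decrease", "DAS28"),
    "esr_mm_per_h": ("decrease", "ESR (mm/h)"),
    "crp_mg_per_dl": ("decrease", "CRP (mg/dL)"),
}

WILCOXON_EXACT_MAX_N = 25


def median_iqr(values, quantile_method: str = "linear") -> tuple[float, float, float]:
    """(median, Q1, Q3) with linear interpolation of order statistics."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise DegenerateInputError("empty value list")
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75], method=quantile_method)
    return float(med), float(q1), float(q3)


@dataclass
class WilcoxonResult:
    statistic: float  # W+ (sum of positive signed ranks)
    p_value: float
    n_effective: int
    method: str

    def __iter__(self):
        return iter((self.statistic, self.p_value))


def _signed_ranks(diffs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Drop zeros, average-rank the absolute differences."""
    d = diffs[diffs != 0]
    if d.size == 0:
        raise DegenerateInputError("all paired differences are zero")
    ranks = sps.rankdata(np.abs(d))
    return d, ranks


def _exact_distribution(ranks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Null distribution of W+ by convolution over sign assignments.

    Fractional (tied) ranks are doubled to make every rank an integer, so
    the support is exact. Returns (support, pmf) on the doubled scale.
    """
    r2 = np.rint(ranks * 2).astype(np.int64)
    total = int(r2.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(pmf)
        shifted[r:] = pmf[: pmf.size - r]
        pmf = 0.5 * (pmf + shifted)
    return np.arange(total + 1), pmf


def wilcoxon_signed_rank(
    pre,
    post,
    alternative: str = "two-sided",
    zero_method: str = "wilcox",
) -> WilcoxonResult:
    """Paired signed-rank test on ``post - pre`` differences.

    Zero differences are dropped (``wilcox`` convention; ``pratt`` keeps
    them in the ranking). The exact null distribution is used up to an
    effective n of 25 — full-support sign-assignment convolution, which for
    untied data coincides with 2^n enumeration — and a tie-corrected,
    continuity-corrected normal approximation beyond.

    ``alternative='greater'`` tests for post > pre.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1 or pre.size == 0:
        raise HsisasError("pre and post must be equal-length non-empty vectors")
    diffs = post - pre

    if zero_method == "pratt":
        if np.all(diffs == 0):
            raise DegenerateInputError("all paired differences are zero")
        ranks_all = sps.rankdata(np.abs(diffs))
        keep = diffs != 0
        d, ranks = diffs[keep], ranks_all[keep]
    else:
        d, ranks = _signed_ranks(diffs)
    n = d.size
    w_plus = float(ranks[d > 0].sum())

    if n <= WILCOXON_EXACT_MAX_N:
        support, pmf = _exact_distribution(ranks)
        w2 = np.rint(w_plus * 2).astype(np.int64)
        p_ge = float(pmf[support >= w2].sum())
        p_le = float(pmf[support <= w2].sum())
        if alternative == "greater":
            p = p_ge
        elif alternative == "less":
            p = p_le
        else:
            p = min(1.0, 2.0 * min(p_ge, p_le))
        method = "exact"
    else:
        mu = n * (n + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts)) / 48.0
        sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
        if sigma == 0:
            raise DegenerateInputError("zero variance in signed ranks")
        if alternative == "greater":
            z = (w_plus - mu - 0.5) / sigma
            p = float(sps.norm.sf(z))
        elif alternative == "less":
            z = (w_plus - mu + 0.5) / sigma
            p = float(sps.norm.cdf(z))
        else:
            z = (w_plus - mu - np.sign(w_plus - mu) * 0.5) / sigma
            p = float(2.0 * sps.norm.sf(abs(z)))
            p = min(1.0, p)
        method = "normal"
    return WilcoxonResult(statistic=w_plus, p_value=p, n_effective=n,
                          method=method)


@dataclass
class SpearmanResult:
    rho: float
    p_value: float
    n: int

    def __iter__(self):
        return iter((self.rho, self.p_value))


def spearman_rho(x, y) -> SpearmanResult:
    """Spearman rank correlation with average ranks for ties; p from the
    t-distribution with n-2 degrees of freedom, two-sided."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise HsisasError("x and y must be equal-length vectors of length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DegenerateInputError("constant input has undefined rank correlation")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx @ rx) * (ry @ ry))
    rho = float((rx @ ry) / denom)
    n = x.size
    if abs(rho) >= 1.0:
        p = 0.0
        rho = float(np.clip(rho, -1.0, 1.0))
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return SpearmanResult(rho=rho, p_value=p, n=n)


# ---------------------------------------------------------------------------
# Cohort tables
# ---------------------------------------------------------------------------

def _pivot(table: pd.DataFrame, variable: str) -> pd.DataFrame:
    wide = table.pivot_table(
        index=["subject_id", "hand"], columns="visit", values=variable,
        aggfunc="first",
    )
    return wide.dropna(subset=[c for c in ("pre", "post") if c in wide.columns])


def improvement_deltas(table: pd.DataFrame) -> pd.DataFrame:
    """Per-wrist improvement-oriented changes.

    Decreasing-type variables use pre - post; the two abundance scores use
    post - pre, so a positive delta always means improvement. Wrists missing
    either visit of a variable get NaN for that variable only; DAS28 deltas
    are computed at patient level and assigned to both wrists.
    """
    wrists = table[["subject_id", "hand"]].drop_duplicates().reset_index(drop=True)
    out = wrists.copy()
    for var, (convention, _) in VARIABLES.items():
        if var not in table.columns:
            continue
        if var == "das28":
            per_subject = (
                table.groupby(["subject_id", "visit"])[var].first().unstack()
            )
            if not {"pre", "post"}.issubset(per_subject.columns):
                delta = pd.Series(np.nan, index=per_subject.index)
            else:
                delta = per_subject["pre"] - per_subject["post"]
            out["d_das28"] = out["subject_id"].map(delta)
            continue
        wide = _pivot(table, var)
        if "pre" not in wide.columns or "post" not in wide.columns:
            out["d_" + var] = np.nan
            continue
        if convention == "decrease":
            delta = wide["pre"] - wide["post"]
        else:
            delta = wide["post"] - wide["pre"]
        key = list(zip(out["subject_id"], out["hand"]))
        out["d_" + var] = [delta.get(k, np.nan) for k in key]
    return out


def paper_tables(
    table: pd.DataFrame,
    alpha: float = 0.05,
    quantile_method: str = "linear",
) -> dict:
    """Summary + correlation report.

    Returns ``{'summary': DataFrame, 'spearman': DataFrame,
    'spearman_p': DataFrame, 'deltas': DataFrame, 'notes': list}`` where
    the summary holds pre/post median (Q1, Q3) and the Wilcoxon p per
    variable and the spearman frame holds starred rho values over the
    improvement deltas.
    """
    notes = [
        "wrist-level observations; within-subject dependence of the two "
        "wrists is not modeled",
        f"quantile method: {quantile_method}; zero differences dropped; "
        "no multiple-testing correction",
    ]
    rows = []
    for var, (_, label) in VARIABLES.items():
        if var not in table.columns:
            continue
        if var == "das28":
            wide = (
                table.groupby(["subject_id", "visit"])[var].first().unstack()
            )
            wide = wide.dropna()
        else:
            wide = _pivot(table, var)
        if "pre" not in wide.columns or "post" not in wide.columns or len(wide) < 3:
            notes.append(f"variable '{var}' skipped: fewer than 3 complete pairs")
            continue
        pre_v, post_v = wide["pre"].to_numpy(), wide["post"].to_numpy()
        med_pre, q1_pre, q3_pre = median_iqr(pre_v, quantile_method)
        med_post, q1_post, q3_post = median_iqr(post_v, quantile_method)
        try:
            res = wilcoxon_signed_rank(pre_v, post_v)
            p = res.p_value
        except DegenerateInputError:
            p = np.nan
            notes.append(f"variable '{var}': all-zero differences, no test")
        rows.append({
            "variable": var, "label": label, "n": len(wide),
            "pre_median": med_pre, "pre_q1": q1_pre, "pre_q3": q3_pre,
            "post_median": med_post, "post_q1": q1_post, "post_q3": q3_post,
            "p_value": p,
        })
    summary = pd.DataFrame(rows)

    deltas = improvement_deltas(table)
    delta_cols = [c for c in deltas.columns if c.startswith("d_")]
    rho_m = pd.DataFrame(np.nan, index=delta_cols, columns=delta_cols)
    p_m = pd.DataFrame(np.nan, index=delta_cols, columns=delta_cols)
    star_m = pd.DataFrame("", index=delta_cols, columns=delta_cols)
    for a, b in itertools.combinations(delta_cols, 2):
        pair = deltas[[a, b]].dropna()
        if len(pair) < 3:
            continue
        try:
            res = spearman_rho(pair[a].to_numpy(), pair[b].to_numpy())
        except DegenerateInputError:
            continue
        for i, j in ((a, b), (b, a)):
            rho_m.loc[i, j] = res.rho
            p_m.loc[i, j] = res.p_value
            stars = "**" if res.p_value < 0.01 else ("*" if res.p_value < alpha else "")
            star_m.loc[i, j] = f"{res.rho:.3f}{stars}"
    return {
        "summary": summary,
        "spearman": rho_m,
        "spearman_p": p_m,
        "spearman_starred": star_m,
        "deltas": deltas,
        "notes": notes,
    }
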