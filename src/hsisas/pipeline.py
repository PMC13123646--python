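"""End-to-end analysis pipeline and its configuration.

``analyze_cohort`` runs the in-memory chain
calibrate -> segment -> pair -> correlation -> scoring -> PDUS -> stats
on a :class:`~hsisas.synth.CohortData`; ``run_pipeline`` additionally writes
deterministic CSV sidecars, reports and figures to a directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import stats as hstats
from .cube_io import calibrate
from .errors import HsisasError, SegmentationError
from .pdus import pd_area, rasterize_roi, red_gray
from .scoring import ScoreRecord, score_cohort
from .segmentation import band_ratio, extract_wrist_roi, segment_hand
from .synth import CohortData, PhantomScene, SpectralModel, generate_cohort

__all__ = ["PipelineConfig", "analyze_cohort", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    seed: int = 42
    m: int = 11
    treatment_delta: float = 0.10
    missing_das28_fraction: float = 0.0
    rows: int = 96
    cols: int = 64
    bands: int = 64
    extension_rows: int = 100
    direction: str = "down"
    corr_mode: str = "pearson"
    ridge_lambda: str | float = "auto"
    reducer: str = "mean"
    pairing: str = "truncate"
    quantile_method: str = "linear"
    pdus_mode: str = "reddom"
    pdus_threshold: str | float = 0.0
    include_pdus: bool = True
    make_figures: bool = True
    out_dir: str = "hsisas_out"
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class CohortResult:
    records: list[ScoreRecord]
    table: pd.DataFrame
    report: dict
    rois: dict
    config: PipelineConfig
    cohort: CohortData


def _segment_wrist(cube, hand_mask_unused, wrist_row, config):
    ratio = band_ratio(cube)
    mask = segment_hand(ratio)
    return mask


def analyze_cohort(cohort: CohortData, config: PipelineConfig) -> CohortResult:
    """Run the full analysis chain on an in-memory cohort."""
    rois: dict = {}
    for sid, sub in sorted(cohort.subjects.items()):
        rois[sid] = {}
        for (hand, visit), raw in sorted(sub.raw.items()):
            refl = calibrate(raw, sub.white[(hand, visit)],
                             sub.dark[(hand, visit)])
            try:
                hand_mask = _segment_wrist(refl, None, sub.wrist_row, config)
                roi = extract_wrist_roi(
                    refl, hand_mask, sub.wrist_row,
                    extension_rows=config.extension_rows,
                    direction=config.direction,
                    subject_id=sid, hand=hand, visit=visit,
                )
            except SegmentationError as exc:
                logger.warning("segmentation failed for %s/%s/%s: %s",
                               sid, hand, visit, exc)
                continue
            rois[sid].setdefault(hand, {})[visit] = roi

    records = score_cohort(
        rois, reducer=config.reducer, pairing=config.pairing,
        seed=config.seed, ridge_lambda=config.ridge_lambda,
        corr_mode=config.corr_mode,
    )

    rows = []
    for rec in records:
        row = {
            "subject_id": rec.subject_id, "hand": rec.hand, "visit": rec.visit,
            "intra_hsisas": rec.intra_score, "inter_hsisas": rec.inter_score,
            "n_pixels": rec.n_pixels,
        }
        key = (rec.subject_id, rec.hand, rec.visit)
        if key in cohort.pdus:
            fixture = cohort.pdus[key]
            roi = rasterize_roi(fixture["frame"], fixture["polygon"])
            gray = red_gray(fixture["frame"], mode=config.pdus_mode)
            row["roi_syn_area_px"] = roi.area_px
            row["pd_area_px"] = pd_area(gray, roi,
                                        threshold=config.pdus_threshold)
        rows.append(row)
    table = pd.DataFrame(rows)
    if cohort.clinical is not None and len(cohort.clinical):
        table = table.merge(cohort.clinical, on=["subject_id", "visit"],
                            how="left")

    report = hstats.paper_tables(table, quantile_method=config.quantile_method)
    report["notes"].append(f"config hash: {config.config_hash()}")
    report["notes"].append(
        f"corr mode: {config.corr_mode}; ridge lambda: {config.ridge_lambda}; "
        f"target scope: subject(intra)/cohort(inter); "
        f"reducer: {config.reducer}"
    )
    return CohortResult(records=records, table=table, report=report,
                        rois=rois, config=config, cohort=cohort)


def run_pipeline(config: PipelineConfig,
                 cohort: CohortData | None = None) -> Path:
    """Simulate (unless a cohort is given), analyze, and write a report
    directory; returns the directory path. Numeric sidecars are byte-stable
    for a fixed config."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if cohort is None:
        cohort = generate_cohort(
            m=config.m,
            model=SpectralModel(treatment_delta=config.treatment_delta),
            scene=PhantomScene(rows=config.rows, cols=config.cols,
                               L=config.bands),
            seed=config.seed,
            missing_das28_fraction=config.missing_das28_fraction,
            include_pdus=config.include_pdus,
        )
    result = analyze_cohort(cohort, config)

    float_fmt = "%.12g"
    result.table.to_csv(out / "cohort_table.csv", index=False,
                        float_format=float_fmt)
    result.report["summary"].to_csv(out / "summary_prepost.csv", index=False,
                                    float_format=float_fmt)
    result.report["spearman"].to_csv(out / "spearman_rho.csv",
                                     float_format=float_fmt)
    result.report["spearman_p"].to_csv(out / "spearman_p.csv",
                                       float_format=float_fmt)
    result.report["spearman_starred"].to_csv(out / "spearman_starred.csv")
    result.report["deltas"].to_csv(out / "improvement_deltas.csv", index=False,
                                   float_format=float_fmt)
    (out / "notes.txt").write_text("\n".join(result.report["notes"]) + "\n")
    (out / "config.json").write_text(
        json.dumps({"hash": config.config_hash(), **config.to_dict()},
                   indent=2, default=str)
        + "\n"
    )
    _write_markdown_report(result, out / "report.md")

    if config.make_figures:
        _write_figures(result, out)
    return out


def _write_markdown_report(result: CohortResult, path: Path) -> None:
    lines = ["# HSISAS cohort report", ""]
    lines.append("## Pre/post summary (median (Q1, Q3), Wilcoxon p)")
    lines.append("")
    summary = result.report["summary"]
    lines.append("| variable | n | pre | post | p |")
    lines.append("|---|---|---|---|---|")
    for _, r in summary.iterrows():
        lines.append(
            f"| {r['label']} | {r['n']} "
            f"| {r['pre_median']:.1f} ({r['pre_q1']:.1f}, {r['pre_q3']:.1f}) "
            f"| {r['post_median']:.1f} ({r['post_q1']:.1f}, {r['post_q3']:.1f}) "
            f"| {r['p_value']:.3g} |"
        )
    lines.append("")
    lines.append("## Spearman rho over improvement deltas (* p<0.05, ** p<0.01)")
    lines.append("")
    lines.append(result.report["spearman_starred"].to_markdown())
    lines.append("")
    lines.append("## Notes")
    lines.extend(f"- {n}" for n in result.report["notes"])
    path.write_text("\n".join(lines) + "\n")


def _write_figures(result: CohortResult, out: Path) -> None:
    from .viz import plot_mean_spectra, plot_projection, render_abundance_map
    from .scoring import build_target, score_map
    from .correlation import pair_pixels, stack_paired, inter_correlation

    axis = result.cohort.scene.axis()
    pre_pool, post_pool = [], []
    for hands in result.rois.values():
        for visits in hands.values():
            if "pre" in visits:
                pre_pool.append(visits["pre"].spectra)
            if "post" in visits:
                post_pool.append(visits["post"].spectra)
    if pre_pool and post_pool:
        plot_mean_spectra(np.vstack(pre_pool), np.vstack(post_pool), axis,
                          out / "mean_spectra.png")
    plot_projection(result.records, out / "projection.png")

    # one example abundance map (first subject with a complete pair)
    for sid, hands in sorted(result.rois.items()):
        complete = [
            (h, v) for h, v in hands.items()
            if "pre" in v and "post" in v
        ]
        if not complete:
            continue
        pairs = [
            pair_pixels(v["pre"], v["post"]) for _, v in complete
        ]
        inter_R = inter_correlation([stack_paired(pairs, subject_id=sid)])
        d = build_target([v["post"] for _, v in complete], scope="subject")
        hand, visits = complete[0]
        amap = score_map(visits["pre"], inter_R, d)
        # grayscale backdrop from the 1303-nm band of the pre cube
        sub = result.cohort.subjects[sid]
        refl = calibrate(sub.raw[(hand, "pre")], sub.white[(hand, "pre")],
                         sub.dark[(hand, "pre")])
        render_abundance_map(amap, out / f"abundance_{sid}_{hand}_pre.png",
                             backdrop_cube=refl)
        break


def simulate_to_dir(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Write a simulated cohort to disk (ENVI cubes, PNG fixtures, CSVs)."""
    import imageio.v3 as iio

    from .cube_io import write_cube

    out = Path(out_dir)
    (out / "cubes").mkdir(parents=True, exist_ok=True)
    (out / "pdus").mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(
        m=config.m,
        model=SpectralModel(treatment_delta=config.treatment_delta),
        scene=PhantomScene(rows=config.rows, cols=config.cols, L=config.bands),
        seed=config.seed,
        missing_das28_fraction=config.missing_das28_fraction,
        include_pdus=config.include_pdus,
    )
    manifest = []
    for sid, sub in sorted(cohort.subjects.items()):
        for (hand, visit), raw in sorted(sub.raw.items()):
            stem = f"{sid}_{hand}_{visit}"
            for tag, cube in (("raw", raw), ("white", sub.white[(hand, visit)]),
                              ("dark", sub.dark[(hand, visit)])):
                write_cube(cube, out / "cubes" / f"{stem}_{tag}.img")
            entry = {
                "subject_id": sid, "hand": hand, "visit": visit,
                "raw": f"cubes/{stem}_raw.img",
                "white": f"cubes/{stem}_white.img",
                "dark": f"cubes/{stem}_dark.img",
                "wrist_row": sub.wrist_row,
            }
            key = (sid, hand, visit)
            if key in cohort.pdus:
                fixture = cohort.pdus[key]
                iio.imwrite(out / "pdus" / f"{stem}.png",
                            fixture["frame"].rgb)
                np.savetxt(out / "pdus" / f"{stem}_roi.csv",
                           fixture["polygon"], delimiter=",",
                           header="row,col", comments="")
                entry["pdus_image"] = f"pdus/{stem}.png"
                entry["pdus_roi"] = f"pdus/{stem}_roi.csv"
            manifest.append(entry)
    pd.DataFrame(manifest).to_csv(out / "manifest.csv", index=False)
    cohort.clinical.to_csv(out / "clinical.csv", index=False)
    return out
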