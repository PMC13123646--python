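"""Synthetic SWIR cohort generation.

Builds fully synthetic paired pre/post wrist acquisitions (raw cube + white
and dark reference frames), clinical covariates coupled to each subject's
spectral treatment effect, and painted power-Doppler ultrasound fixtures,
so the whole analysis chain can be exercised without any real data.

The reflectance model is a low-order polynomial baseline minus Gaussian
absorption dips (tissue water near 970/1190/1450 nm plus an
inflammation-modulated feature near 1250 nm whose depth increases after
treatment). Each acquisition carries a multiplicative lognormal brightness
factor and a spatially smooth per-wrist gain field that persists across
visits, plus i.i.d. Gaussian pixel noise. Everything is a pure function of
(config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage.draw import polygon as _draw_polygon

from .cube_io import RawCube, SpectralAxis, default_axis
from .errors import HsisasError
from .pdus import UltrasoundFrame

__all__ = [
    "SpectralModel",
    "PhantomScene",
    "SubjectData",
    "CohortData",
    "hand_spectrum",
    "board_spectrum",
    "generate_subject",
    "generate_cohort",
    "generate_pdus_fixture",
]

HANDS = ("L", "R")
VISITS = ("pre", "post")

# water dips + inflammation-modulated feature: (center nm, width nm, amplitude)
DEFAULT_BANDS = (
    (970.0, 30.0, 0.10),
    (1190.0, 40.0, 0.12),
    (1450.0, 45.0, 0.35),
)
INFLAMMATION_CENTER_NM = 1250.0
INFLAMMATION_WIDTH_NM = 35.0


@dataclass(frozen=True)
class SpectralModel:
    baseline_coeffs: tuple = (0.66, -0.05, -0.06)  # polynomial in (lam-900)/800
    absorption_bands: tuple = DEFAULT_BANDS
    inflammation_amp_pre: float = 0.04
    treatment_delta: float = 0.10
    noise_sd_pixel: float = 0.01
    noise_sd_subject: float = 0.02
    subject_effect_sd: float = 0.35
    gain_field_sd: float = 0.05
    water_field_sd: float = 0.08


@dataclass(frozen=True)
class PhantomScene:
    rows: int = 96
    cols: int = 64
    L: int = 64
    wrist_row_frac: float = 0.55
    board_reflectance: float = 0.45
    board_dip_scale: float = 0.10
    white_level: float = 3000.0
    dark_level: float = 100.0

    @property
    def wrist_row(self) -> int:
        return int(self.wrist_row_frac * self.rows)

    def axis(self) -> SpectralAxis:
        return default_axis(self.L)


FULL_SIZE_SCENE = PhantomScene(rows=635, cols=640, L=512)

# hand + forearm silhouette in (row_frac, col_frac); fingers at the top,
# forearm running off the bottom edge
_HAND_TEMPLATE = np.array([
    (0.05, 0.35), (0.05, 0.65), (0.45, 0.72), (0.60, 0.68),
    (1.00, 0.66), (1.00, 0.34), (0.60, 0.32), (0.45, 0.28),
])


def _gaussian_dip(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


def _baseline(axis: SpectralAxis, model: SpectralModel) -> np.ndarray:
    u = (axis.wavelengths_nm - 900.0) / 800.0
    return np.polyval(model.baseline_coeffs[::-1], u)


def _water_dip_profile(axis: SpectralAxis, model: SpectralModel) -> np.ndarray:
    wl = axis.wavelengths_nm
    dip = np.zeros(axis.L)
    for center, width, amp in model.absorption_bands:
        dip = dip + amp * _gaussian_dip(wl, center, width)
    return dip


def _inflammation_profile(axis: SpectralAxis) -> np.ndarray:
    return _gaussian_dip(axis.wavelengths_nm, INFLAMMATION_CENTER_NM,
                         INFLAMMATION_WIDTH_NM)


def hand_spectrum(
    axis: SpectralAxis,
    model: SpectralModel,
    inflammation_amp: float,
    water_scale: float = 1.0,
) -> np.ndarray:
    """Noise-free tissue reflectance for a given inflammation-dip depth and
    tissue-water loading."""
    refl = (
        _baseline(axis, model)
        - water_scale * _water_dip_profile(axis, model)
        - inflammation_amp * _inflammation_profile(axis)
    )
    return np.clip(refl, 0.0, 1.5)


def board_spectrum(axis: SpectralAxis, model: SpectralModel,
                   scene: PhantomScene) -> np.ndarray:
    """Flat imaging-board reflectance with weak water dips."""
    wl = axis.wavelengths_nm
    refl = np.full(axis.L, scene.board_reflectance)
    for center, width, amp in model.absorption_bands:
        refl = refl - scene.board_dip_scale * amp * _gaussian_dip(wl, center, width)
    return np.clip(refl, 0.0, 1.5)


def _hand_mask(scene: PhantomScene, rng: np.random.Generator) -> np.ndarray:
    """Rasterize the silhouette with small per-subject affine jitter."""
    verts = _HAND_TEMPLATE.copy()
    shift = rng.uniform(-0.03, 0.03)
    widen = rng.uniform(0.95, 1.05)
    verts[:, 1] = 0.5 + (verts[:, 1] - 0.5) * widen + shift
    rr = verts[:, 0] * (scene.rows - 1)
    cc = verts[:, 1] * (scene.cols - 1)
    mask = np.zeros((scene.rows, scene.cols), dtype=bool)
    pr, pc = _draw_polygon(rr, cc, shape=mask.shape)
    mask[pr, pc] = True
    return mask


def _smooth_field(shape: tuple[int, int], sd: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Spatially smooth multiplicative gain field around 1 (low-rank cosine
    mixture; persistent tissue shading)."""
    rows, cols = shape
    r = np.linspace(0, np.pi, rows)[:, None]
    c = np.linspace(0, np.pi, cols)[None, :]
    phase = rng.uniform(0, 2 * np.pi, size=4)
    amp = rng.normal(0.0, 1.0, size=4)
    f = (
        amp[0] * np.cos(r + phase[0])
        + amp[1] * np.cos(c + phase[1])
        + amp[2] * np.cos(2 * r + phase[2]) * np.cos(c + phase[3])
        + amp[3] * np.cos(r) * np.cos(2 * c)
    )
    if sd == 0.0 or f.std() == 0.0:
        return np.ones(shape)
    # fixed spatial SD (random shape only), bounded away from degenerate values
    f = (f - f.mean()) * (sd / f.std())
    return np.clip(1.0 + f, 1.0 - 2.5 * sd, 1.0 + 2.5 * sd)


@dataclass
class SubjectData:
    subject_id: str
    effect: float
    wrist_row: int
    hand_masks: dict = field(default_factory=dict)       # (hand) -> bool mask
    raw: dict = field(default_factory=dict)              # (hand, visit) -> RawCube
    white: dict = field(default_factory=dict)            # (hand, visit) -> RawCube
    dark: dict = field(default_factory=dict)             # (hand, visit) -> RawCube
    true_reflectance: dict = field(default_factory=dict) # (hand, visit) -> ndarray


@dataclass
class CohortData:
    scene: PhantomScene
    model: SpectralModel
    subjects: dict  # sid -> SubjectData
    clinical: "object" = None  # pandas DataFrame
    pdus: dict = field(default_factory=dict)  # (sid, hand, visit) -> fixture dict
    seed: int = 0


def _subject_rng(seed: int, subject_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, subject_index]))


def generate_subject(
    model: SpectralModel,
    scene: PhantomScene,
    subject_id: str,
    seed: int,
    subject_index: int = 0,
    effect: float | None = None,
) -> SubjectData:
    """One subject: 2 hands x 2 visits of raw cubes plus references.

    ``raw = dark + reflectance * (white - dark)`` with the noise folded into
    the reflectance field, so ``calibrate`` recovers it exactly. Pre and
    post differ only in the inflammation-band depth (``treatment_delta``
    scaled by the subject's random effect) and fresh acquisition noise.
    Deterministic for a given (seed, subject_index).
    """
    rng = _subject_rng(seed, subject_index)
    axis = scene.axis()
    if effect is None:
        effect = float(rng.lognormal(mean=0.0, sigma=model.subject_effect_sd))
    else:
        rng.lognormal(mean=0.0, sigma=model.subject_effect_sd)  # keep stream aligned

    amp = {
        "pre": model.inflammation_amp_pre,
        "post": model.inflammation_amp_pre + model.treatment_delta * effect,
    }
    baseline = _baseline(axis, model)
    water_dip = _water_dip_profile(axis, model)
    inflam = _inflammation_profile(axis)
    board = board_spectrum(axis, model, scene)

    white_frame = np.full((scene.rows, scene.cols, axis.L), scene.white_level,
                          dtype=np.float32)
    dark_frame = np.full((scene.rows, scene.cols, axis.L), scene.dark_level,
                         dtype=np.float32)

    sub = SubjectData(subject_id=subject_id, effect=effect,
                      wrist_row=scene.wrist_row)
    for hand in HANDS:
        mask = _hand_mask(scene, rng)
        sub.hand_masks[hand] = mask
        # tissue shading and water-content maps persist across the two visits;
        # shading is an additive offset (scattering/thickness variation),
        # the water map scales the absorption-dip depths
        shade = _smooth_field((scene.rows, scene.cols), model.gain_field_sd,
                              rng) - 1.0
        water = _smooth_field((scene.rows, scene.cols), model.water_field_sd,
                              rng)
        # de-correlate the two maps so they stay distinct nuisance factors
        w0 = water - water.mean()
        s0 = shade - shade.mean()
        if s0.std() > 0 and w0.std() > 0:
            w0 = w0 - (np.sum(w0 * s0) / np.sum(s0 * s0)) * s0
            if w0.std() > 0:
                w0 *= model.water_field_sd / w0.std()
            water = np.clip(1.0 + w0, 1.0 - 2.5 * model.water_field_sd,
                            1.0 + 2.5 * model.water_field_sd)
        for visit in VISITS:
            brightness = float(
                rng.lognormal(mean=0.0, sigma=model.noise_sd_subject)
            )
            tissue = (
                baseline[None, None, :]
                + shade[:, :, None] * np.mean(baseline)
                - water[:, :, None] * water_dip[None, None, :]
                - amp[visit] * inflam[None, None, :]
            )
            field2d = np.where(mask[:, :, None], tissue, board)
            np.clip(field2d, 0.0, 1.5, out=field2d)
            field2d = field2d * brightness
            sub.true_reflectance[(hand, visit)] = field2d.astype(np.float32)
            noisy = field2d + rng.normal(
                0.0, model.noise_sd_pixel, size=field2d.shape
            )
            np.clip(noisy, 0.0, 2.0, out=noisy)
            raw = scene.dark_level + noisy * (scene.white_level - scene.dark_level)
            sub.raw[(hand, visit)] = RawCube(raw.astype(np.float32), axis)
            sub.white[(hand, visit)] = RawCube(white_frame, axis)
            sub.dark[(hand, visit)] = RawCube(dark_frame, axis)
    return sub


# ---------------------------------------------------------------------------
# Clinical covariates
# ---------------------------------------------------------------------------

_CLINICAL_BASE = {  # (pre-treatment center, between-subject sd, noise sd)
    "das28": (4.8, 0.6, 0.15),
    "esr_mm_per_h": (31.0, 12.0, 6.0),
    "crp_mg_per_dl": (1.5, 0.6, 0.3),
}
# improvement per unit of (treatment_delta * subject effect)
_CLINICAL_COUPLING = {"das28": 5.0, "esr_mm_per_h": 120.0, "crp_mg_per_dl": 10.0}


def generate_cohort(
    m: int,
    model: SpectralModel | None = None,
    scene: PhantomScene | None = None,
    seed: int = 0,
    missing_das28_fraction: float = 0.0,
    include_pdus: bool = True,
) -> CohortData:
    """m subjects x {L, R} x {pre, post} with clinical covariates.

    DAS28/ESR/CRP improvements are coupled to each subject's spectral
    treatment effect so the spectral/clinical association is recoverable;
    a ``missing_das28_fraction`` of subjects get a missing post-treatment
    DAS28 to exercise exclusion logic.
    """
    import pandas as pd

    if m < 2:
        raise HsisasError("cohort needs m >= 2 subjects")
    model = model or SpectralModel()
    scene = scene or PhantomScene()
    subjects: dict[str, SubjectData] = {}
    clinical_rows = []
    pdus_fixtures: dict = {}

    rng_cohort = np.random.default_rng(np.random.SeedSequence([seed, 10**6]))
    missing = rng_cohort.random(m) < missing_das28_fraction

    for idx in range(m):
        sid = f"s{idx + 1:02d}"
        sub = generate_subject(model, scene, sid, seed, subject_index=idx)
        subjects[sid] = sub
        improvement = model.treatment_delta * sub.effect
        rng_c = np.random.default_rng(np.random.SeedSequence([seed, 2 * 10**6, idx]))
        for visit in VISITS:
            row = {"subject_id": sid, "visit": visit}
            for var, (center, sd_between, sd_noise) in _CLINICAL_BASE.items():
                if visit == "pre":
                    row[var] = max(
                        0.1, center + rng_c.normal(0.0, sd_between)
                    )
                else:
                    pre_val = next(
                        r[var] for r in clinical_rows
                        if r["subject_id"] == sid and r["visit"] == "pre"
                    )
                    drop = (
                        _CLINICAL_COUPLING[var] * improvement
                        + rng_c.normal(0.0, sd_noise)
                    )
                    row[var] = max(0.0, pre_val - drop)
            if missing[idx] and visit == "post":
                row["das28"] = np.nan
            clinical_rows.append(row)

        if include_pdus:
            rng_p = np.random.default_rng(
                np.random.SeedSequence([seed, 3 * 10**6, idx])
            )
            for hand in HANDS:
                for visit in VISITS:
                    scale = 1.0 if visit == "pre" else max(
                        0.3, 1.0 - 2.0 * improvement
                        + rng_p.normal(0.0, 0.1)
                    )
                    fixture = _wrist_pdus_fixture(scale, rng_p)
                    pdus_fixtures[(sid, hand, visit)] = fixture

    clinical = pd.DataFrame(clinical_rows)
    return CohortData(scene=scene, model=model, subjects=subjects,
                      clinical=clinical, pdus=pdus_fixtures, seed=seed)


def _wrist_pdus_fixture(scale: float, rng: np.random.Generator) -> dict:
    """A small ultrasound-like frame whose synovial polygon and Doppler blob
    load scale with disease activity."""
    shape = (96, 96)
    cy, cx = 48.0, 48.0
    ry = 22.0 * np.sqrt(scale) * rng.uniform(0.9, 1.1)
    rx = 32.0 * np.sqrt(scale) * rng.uniform(0.9, 1.1)
    theta = np.linspace(0, 2 * np.pi, 16, endpoint=False)
    poly = np.column_stack([cy + ry * np.sin(theta), cx + rx * np.cos(theta)])
    poly = np.clip(poly, 1, np.array(shape) - 2)
    total_blob = int(max(0, rng.normal(220 * scale, 40)))
    blob_areas = []
    remaining = total_blob
    while remaining > 30:
        a = int(min(remaining, rng.integers(30, 90)))
        blob_areas.append(a)
        remaining -= a
    frame, gt = generate_pdus_fixture(
        poly, blob_areas, speckle_level=12.0,
        seed=int(rng.integers(2**31)), shape=shape,
    )
    return {"frame": frame, "polygon": poly, "ground_truth": gt}


# ---------------------------------------------------------------------------
# PDUS fixtures
# ---------------------------------------------------------------------------

def generate_pdus_fixture(
    roi_polygon,
    blob_areas: list[int],
    speckle_level: float = 10.0,
    seed: int = 0,
    shape: tuple[int, int] = (128, 128),
) -> tuple[UltrasoundFrame, dict]:
    """Gray-speckle frame with pure-red Doppler blobs of exact pixel areas.

    Blobs are grown as 4-connected regions inside the polygon; raises if the
    requested areas do not fit. Ground truth returns the blob mask and the
    total painted area.
    """
    rng = np.random.default_rng(seed)
    verts = np.asarray(roi_polygon, dtype=float)
    gray = np.clip(rng.normal(90.0, speckle_level, size=shape), 0, 255)
    rgb = np.repeat(gray[:, :, None], 3, axis=2).astype(np.uint8)

    mask = np.zeros(shape, dtype=bool)
    pr, pc = _draw_polygon(verts[:, 0], verts[:, 1], shape=shape)
    mask[pr, pc] = True

    available = mask.copy()
    blob_mask = np.zeros(shape, dtype=bool)
    for area in blob_areas:
        if area <= 0:
            continue
        if area > available.sum():
            raise HsisasError(
                f"blob of {area} px does not fit inside the ROI "
                f"({int(available.sum())} px free)"
            )
        blob = _grow_blob(available, area, rng)
        if blob is None:
            raise HsisasError(f"could not place a blob of {area} px")
        blob_mask |= blob
        available &= ~blob

    rgb[blob_mask] = (255, 0, 0)
    frame = UltrasoundFrame(rgb=rgb)
    gt = {
        "blob_mask": blob_mask,
        "pd_area_px": int(blob_mask.sum()),
        "roi_mask": mask,
    }
    return frame, gt


def _grow_blob(available: np.ndarray, area: int,
               rng: np.random.Generator) -> np.ndarray | None:
    """Grow a 4-connected region of exactly ``area`` pixels in ``available``."""
    rows, cols = available.shape
    free = np.argwhere(available)
    for _ in range(20):  # retries for unlucky seeds near the boundary
        start = tuple(free[rng.integers(len(free))])
        blob = np.zeros_like(available)
        blob[start] = True
        frontier = [start]
        count = 1
        while count < area and frontier:
            idx = rng.integers(len(frontier))
            r, c = frontier.pop(idx)
            neighbors = [(r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)]
            rng.shuffle(neighbors)
            for nr, nc in neighbors:
                if (0 <= nr < rows and 0 <= nc < cols
                        and available[nr, nc] and not blob[nr, nc]):
                    blob[nr, nc] = True
                    frontier.append((nr, nc))
                    count += 1
                    if count == area:
                        break
        if count == area:
            return blob
    return None


def make_noise_free(model: SpectralModel) -> SpectralModel:
    """Variant of the model with all stochastic terms switched off."""
    return replace(model, noise_sd_pixel=0.0, noise_sd_subject=0.0,
                   gain_field_sd=0.0, subject_effect_sd=0.0,
                   water_field_sd=0.0)
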