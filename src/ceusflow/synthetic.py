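"""Synthetic CEUS study generator.

Emulates the data structure of a flash-replenishment brain-perfusion study
in extrauterine fetal lambs: per-pixel destruction-replenishment cine
clips, a two-group cohort (hypoxic vs normoxic) with one to three exams per
animal over days 2-13 on circuit and triplicate acquisitions per exam,
arterial Doppler velocity envelopes, and daily cardiac-output tables.

The kinetic ground truth at every pixel is the mono-exponential
replenishment model

    I(t) = O + A * (1 - exp(-beta * (t - t_f)))   for t >= t_f,

with plateau amplitude ``A`` (au), replenishment rate ``beta`` (1/s) and
post-destruction residual ``O`` (au); before the flash the signal sits at
the steady-state plateau ``O + A`` and during destruction at ``O``.
Acquisition noise is modelled as i.i.d. multiplicative log-normal factors
with unit mean (a simple positive, scale-proportional stand-in for speckle).

Group- and region-level default parameters encode the study conditions:
per-region median microvascular flow velocity (MFV = A*beta) and transit
time (TT = 1/beta) for each group, with animal- and exam-level log-normal
random effects of median one so configured group medians are the ground
truth medians.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cine import CineClip, RoiSpec, circular_mask, elliptical_mask
from .errors import InvalidConfigError
from .hemodynamics import DopplerTrace

__all__ = [
    "CineConfig",
    "TissueMap",
    "CohortConfig",
    "CohortAcquisition",
    "CohortSim",
    "simulate_cine",
    "simulate_cohort",
    "simulate_doppler",
    "simulate_cardiac_table",
    "DEFAULT_REGION_MEDIANS",
    "DEFAULT_CARDIAC_MEDIANS",
    "DEFAULT_PI_MEDIANS",
]

GROUPS = ("hypoxic", "normoxic")
REGIONS = ("whole_brain", "central_thalamic", "peripheral_parenchyma")

#: Per-group, per-region median (MFV [au/s], transit time [s]).  The
#: generator converts these to the kinetic parameters A = MFV * TT and
#: beta = 1 / TT.  MBF = A^2 * beta follows and is *not* independently
#: configurable (group medians of a nonlinear function of A and beta need
#: not match any printed summary of MBF).
DEFAULT_REGION_MEDIANS: dict[tuple[str, str], tuple[float, float]] = {
    ("hypoxic", "whole_brain"): (0.78, 0.99),
    ("hypoxic", "central_thalamic"): (1.32, 3.65),
    ("hypoxic", "peripheral_parenchyma"): (0.59, 3.84),
    ("normoxic", "whole_brain"): (1.10, 0.63),
    ("normoxic", "central_thalamic"): (1.47, 3.17),
    ("normoxic", "peripheral_parenchyma"): (0.84, 1.87),
}

#: Per-group median (LVCO, RVCO, circuit_flow, oxygen_delivery), mL/kg/min.
DEFAULT_CARDIAC_MEDIANS: dict[str, tuple[float, float, float, float]] = {
    "hypoxic": (320.0, 460.0, 221.0, 15.6),
    "normoxic": (290.0, 460.0, 278.0, 21.6),
}

#: Per-group median middle cerebral artery pulsatility index.
DEFAULT_PI_MEDIANS: dict[str, float] = {"hypoxic": 0.65, "normoxic": 0.78}


@dataclass
class CineConfig:
    """Acquisition geometry and timing for one synthetic cine clip."""

    height_px: int = 64
    width_px: int = 64
    pixel_spacing_mm: float = 0.5
    frame_rate_hz: float = 15.0
    destruction_duration_s: float = 3.0
    imaging_duration_s: float = 15.0
    baseline_duration_s: float = 1.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height_px < 1 or self.width_px < 1:
            raise InvalidConfigError("cine grid must be non-empty")
        if not (self.pixel_spacing_mm > 0):
            raise InvalidConfigError("pixel_spacing_mm must be positive")
        if not (self.frame_rate_hz > 0):
            raise InvalidConfigError("frame_rate_hz must be positive")
        if self.destruction_duration_s < 0 or self.baseline_duration_s < 0:
            raise InvalidConfigError("durations must be nonnegative")
        if not (self.imaging_duration_s > 0):
            raise InvalidConfigError("imaging_duration_s must be positive")
        if self.imaging_duration_s * self.frame_rate_hz < 10:
            raise InvalidConfigError("imaging window must span at least 10 frames")
        if self.noise_sigma < 0:
            raise InvalidConfigError("noise_sigma must be nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height_px, self.width_px)

    @property
    def flash_end_s(self) -> float:
        return self.baseline_duration_s + self.destruction_duration_s

    @property
    def n_frames(self) -> int:
        total = self.flash_end_s + self.imaging_duration_s
        return int(round(total * self.frame_rate_hz))


@dataclass
class TissueMap:
    """Per-pixel kinetic ground truth: plateau amplitude A (au),
    replenishment rate beta (1/s), and residual offset O (au)."""

    amplitude: np.ndarray
    rate: np.ndarray
    offset: np.ndarray

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        self.offset = np.asarray(self.offset, dtype=float)
        if not (self.amplitude.shape == self.rate.shape == self.offset.shape):
            raise InvalidConfigError("tissue maps must share one pixel grid")
        if self.amplitude.ndim != 2:
            raise InvalidConfigError("tissue maps must be 2-D")
        for name, arr in (("amplitude", self.amplitude), ("rate", self.rate), ("offset", self.offset)):
            if np.any(arr < 0):
                raise InvalidConfigError(f"{name} map has negative entries")

    @classmethod
    def uniform(cls, shape: tuple[int, int], amplitude: float, rate: float, offset: float = 0.0) -> "TissueMap":
        return cls(
            amplitude=np.full(shape, amplitude, dtype=float),
            rate=np.full(shape, rate, dtype=float),
            offset=np.full(shape, offset, dtype=float),
        )

    @property
    def shape(self) -> tuple[int, int]:
        return self.amplitude.shape


def simulate_cine(
    config: CineConfig,
    tissue: TissueMap,
    dtype: np.dtype | type = np.float64,
    clip_id: str = "",
) -> CineClip:
    """Render one flash-replenishment cine clip from a tissue map.

    Noiseless pixel means follow the kinetic model exactly; with
    ``noise_sigma > 0`` every pixel-frame is multiplied by an independent
    log-normal factor of unit mean and log-scale standard deviation
    ``noise_sigma``.  Identical seeds and configs give identical clips.
    """
    if tissue.shape != config.shape:
        raise InvalidConfigError(
            f"tissue grid {tissue.shape} does not match cine grid {config.shape}"
        )
    times = np.arange(config.n_frames) / config.frame_rate_hz
    t_f = config.flash_end_s
    A = tissue.amplitude[None, :, :]
    beta = tissue.rate[None, :, :]
    O = tissue.offset[None, :, :]

    frames = np.empty((config.n_frames,) + config.shape, dtype=float)
    pre = times < config.baseline_duration_s
    during = (~pre) & (times < t_f)
    post = times >= t_f
    frames[pre] = O + A
    frames[during] = O
    dt = (times[post] - t_f)[:, None, None]
    frames[post] = O + A * -np.expm1(-beta * dt)

    if config.noise_sigma > 0:
        rng = np.random.default_rng(config.seed)
        sigma = config.noise_sigma
        factors = np.exp(
            rng.standard_normal(frames.shape) * sigma - 0.5 * sigma**2
        )
        frames = frames * factors

    flash_end_index = int(math.ceil(t_f * config.frame_rate_hz - 1e-9))
    return CineClip(
        frames=np.ascontiguousarray(frames, dtype=dtype),
        frame_interval_s=1.0 / config.frame_rate_hz,
        pixel_spacing_mm=config.pixel_spacing_mm,
        flash_end_index=flash_end_index,
        clip_id=clip_id,
    )


# --- cohort ------------------------------------------------------------------


@dataclass
class CohortConfig:
    """Study design of the synthetic two-group cohort.

    ``region_medians`` maps (group, region) to median (MFV, transit time);
    ``dispersion`` is the marginal log-scale spread of each kinetic
    parameter (A and beta), with 80% of the variance between animals and
    20% between exams within an animal.  With ``dispersion=0`` every
    animal carries exactly the group medians.
    """

    n_hypoxic: int = 9
    n_normoxic: int = 6
    exams_per_animal: tuple[int, int] = (1, 3)
    day_range: tuple[int, int] = (2, 13)
    region_medians: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_REGION_MEDIANS)
    )
    cardiac_medians: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CARDIAC_MEDIANS)
    )
    pi_medians: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PI_MEDIANS))
    dispersion: float = 0.3
    replicate_count: int = 3
    seed: int = 0
    cine: CineConfig = field(default_factory=lambda: CineConfig(noise_sigma=0.05))
    roi_diameter_mm: float = 5.0
    peripheral_offset_mm: float = 10.0

    def __post_init__(self) -> None:
        if self.n_hypoxic < 1 or self.n_normoxic < 1:
            raise InvalidConfigError("each group needs at least one animal")
        lo, hi = self.exams_per_animal
        if not (1 <= lo <= hi <= 3):
            raise InvalidConfigError("exams_per_animal must lie within 1-3")
        dlo, dhi = self.day_range
        if not (1 <= dlo <= dhi <= 21):
            raise InvalidConfigError("day_range must lie within [1, 21]")
        if dhi - dlo + 1 < hi:
            raise InvalidConfigError("day_range too narrow for the exam count")
        for key, (mfv, tt) in self.region_medians.items():
            if not (mfv > 0 and tt > 0):
                raise InvalidConfigError(f"medians for {key} must be strictly positive")
        if self.dispersion < 0:
            raise InvalidConfigError("dispersion must be nonnegative")
        if self.replicate_count < 1:
            raise InvalidConfigError("replicate_count must be at least 1")


@dataclass
class CohortAcquisition:
    """One rendered cine replicate with its ROI specifications and labels."""

    clip: CineClip
    rois: list[RoiSpec]
    animal_id: str
    group: str
    day: int
    exam_id: str
    replicate: int


@dataclass
class CohortSim:
    """Output of :func:`simulate_cohort`: acquisitions plus ground truth."""

    acquisitions: list[CohortAcquisition]
    truth: pd.DataFrame


def _roi_centers_mm(config: CohortConfig) -> dict[str, tuple[float, float]]:
    cine = config.cine
    center = (
        cine.height_px * cine.pixel_spacing_mm / 2.0,
        cine.width_px * cine.pixel_spacing_mm / 2.0,
    )
    peripheral = (center[0] - config.peripheral_offset_mm, center[1])
    return {"central_thalamic": center, "peripheral_parenchyma": peripheral}


def _exam_tissue(config: CohortConfig, params: dict[str, tuple[float, float]]) -> TissueMap:
    """Tissue map: whole-brain background with central and peripheral discs."""
    cine = config.cine
    shape = cine.shape
    A_wb, b_wb = params["whole_brain"]
    amplitude = np.full(shape, A_wb, dtype=float)
    rate = np.full(shape, b_wb, dtype=float)
    centers = _roi_centers_mm(config)
    for region in ("central_thalamic", "peripheral_parenchyma"):
        mask = circular_mask(shape, centers[region], config.roi_diameter_mm, cine.pixel_spacing_mm)
        A_r, b_r = params[region]
        amplitude[mask] = A_r
        rate[mask] = b_r
    return TissueMap(amplitude=amplitude, rate=rate, offset=np.zeros(shape))


def _whole_brain_spec(config: CohortConfig) -> RoiSpec:
    """Whole-brain ROI: a large ellipse minus the two focal ROIs.

    Excluding the focal discs keeps the whole-brain measurement
    homogeneous (the background carries the configured whole-brain
    kinetics), so every configured region is measured over tissue with a
    single ground-truth parameter set.
    """
    cine = config.cine
    mask = elliptical_mask(
        cine.shape,
        (cine.height_px / 2.0, cine.width_px / 2.0),
        (0.45 * cine.height_px, 0.45 * cine.width_px),
    )
    for center in _roi_centers_mm(config).values():
        mask &= ~circular_mask(cine.shape, center, config.roi_diameter_mm, cine.pixel_spacing_mm)
    return RoiSpec(label="whole_brain", mask=mask)


def simulate_cohort(config: CohortConfig, render_clips: bool = True) -> CohortSim:
    """Draw a full synthetic cohort and (optionally) render its cine clips.

    Each animal receives a log-normal random effect (median 1) shared
    across its exams, each exam an additional effect at half the log-scale
    spread; regional kinetic parameters are the configured group medians
    times those effects.  Exam days are distinct integers within
    ``day_range`` (hence at least one day apart).  The returned truth table
    has one row per exam and region with columns A, beta, MFV,
    transit_time, MBF.  Deterministic under ``seed``.

    Set ``render_clips=False`` to obtain the truth table alone (used by
    resampling checks that do not need imagery).
    """
    rng = np.random.default_rng(config.seed)
    sigma = config.dispersion
    lo, hi = config.exams_per_animal
    dlo, dhi = config.day_range
    centers = _roi_centers_mm(config)
    wb_spec = _whole_brain_spec(config) if render_clips else None

    acquisitions: list[CohortAcquisition] = []
    rows: list[dict] = []
    animals = [("hypoxic", f"H{i + 1:02d}") for i in range(config.n_hypoxic)] + [
        ("normoxic", f"N{i + 1:02d}") for i in range(config.n_normoxic)
    ]
    # dispersion = marginal log-scale SD of each kinetic parameter; split
    # 80% of the variance between animals, 20% between exams within animal
    sd_animal = sigma * np.sqrt(0.8)
    sd_exam = sigma * np.sqrt(0.2)
    for group, animal_id in animals:
        animal_eff = {
            "A": float(np.exp(rng.standard_normal() * sd_animal)),
            "beta": float(np.exp(rng.standard_normal() * sd_animal)),
        }
        n_exams = int(rng.integers(lo, hi + 1))
        days = np.sort(rng.choice(np.arange(dlo, dhi + 1), size=n_exams, replace=False))
        for exam_no, day in enumerate(days, start=1):
            exam_eff_A = float(np.exp(rng.standard_normal() * sd_exam))
            exam_eff_b = float(np.exp(rng.standard_normal() * sd_exam))
            exam_id = f"{animal_id}-e{exam_no}"
            params: dict[str, tuple[float, float]] = {}
            for region in REGIONS:
                mfv_med, tt_med = config.region_medians[(group, region)]
                A = mfv_med * tt_med * animal_eff["A"] * exam_eff_A
                beta = (1.0 / tt_med) * animal_eff["beta"] * exam_eff_b
                params[region] = (A, beta)
                rows.append(
                    {
                        "animal_id": animal_id,
                        "group": group,
                        "exam_id": exam_id,
                        "day": int(day),
                        "region": region,
                        "A": A,
                        "beta": beta,
                        "MFV": A * beta,
                        "transit_time": 1.0 / beta,
                        "MBF": A**2 * beta,
                    }
                )
            if not render_clips:
                continue
            tissue = _exam_tissue(config, params)
            for replicate in range(1, config.replicate_count + 1):
                clip_seed = int(rng.integers(0, 2**31 - 1))
                cine = replace(config.cine, seed=clip_seed)
                clip = simulate_cine(
                    cine,
                    tissue,
                    dtype=np.float32,
                    clip_id=f"{exam_id}-r{replicate}",
                )
                rois = [
                    RoiSpec(label="whole_brain", mask=wb_spec.mask, clip_id=clip.clip_id),
                    RoiSpec(
                        label="central_thalamic",
                        center_mm=centers["central_thalamic"],
                        diameter_mm=config.roi_diameter_mm,
                        clip_id=clip.clip_id,
                    ),
                    RoiSpec(
                        label="peripheral_parenchyma",
                        center_mm=centers["peripheral_parenchyma"],
                        diameter_mm=config.roi_diameter_mm,
                        clip_id=clip.clip_id,
                    ),
                ]
                acquisitions.append(
                    CohortAcquisition(
                        clip=clip,
                        rois=rois,
                        animal_id=animal_id,
                        group=group,
                        day=int(day),
                        exam_id=exam_id,
                        replicate=replicate,
                    )
                )
    truth = pd.DataFrame(rows)
    return CohortSim(acquisitions=acquisitions, truth=truth)


# --- Doppler -----------------------------------------------------------------


def simulate_doppler(
    psv: float,
    edv: float,
    heart_rate_hz: float = 2.0,
    n_cycles: int = 5,
    sample_rate_hz: float = 100.0,
    seed: int = 0,
) -> DopplerTrace:
    """Synthetic arterial velocity envelope: a raised-cosine waveform.

    v(t) = EDV + (PSV - EDV) * (1 + cos(2 pi f t)) / 2, sampled over an
    integer number of cardiac cycles, so the per-cycle maximum is ``psv``,
    the minimum ``edv``, and the time average (PSV + EDV) / 2.  ``seed`` is
    accepted for interface uniformity; the default waveform is
    deterministic.
    """
    if not (psv > edv >= 0):
        raise InvalidConfigError("need psv > edv >= 0")
    if heart_rate_hz <= 0 or sample_rate_hz <= 0:
        raise InvalidConfigError("rates must be positive")
    if n_cycles < 1:
        raise InvalidConfigError("need at least one cardiac cycle")
    duration = n_cycles / heart_rate_hz
    n = int(round(duration * sample_rate_hz))
    times = np.arange(n) / sample_rate_hz
    envelope = edv + (psv - edv) * 0.5 * (1.0 + np.cos(2.0 * np.pi * heart_rate_hz * times))
    return DopplerTrace(times_s=times, envelope_velocity=envelope, n_cycles=n_cycles)


# --- cardiac tables ----------------------------------------------------------


def simulate_cardiac_table(config: CohortConfig) -> pd.DataFrame:
    """Daily cardiac flows per animal: one row per animal-day.

    LVCO, RVCO, circuit flow and oxygen delivery are the configured group
    medians times animal-level (log-scale spread ``dispersion``) and
    day-level (half spread) log-normal effects of median one.
    Deterministic under ``seed`` (offset from the cohort seed so cardiac
    draws do not alias the perfusion draws).
    """
    rng = np.random.default_rng(config.seed + 1_000_003)
    sigma = config.dispersion
    rows = []
    animals = [("hypoxic", f"H{i + 1:02d}") for i in range(config.n_hypoxic)] + [
        ("normoxic", f"N{i + 1:02d}") for i in range(config.n_normoxic)
    ]
    days = range(1, config.day_range[1] + 1)
    for group, animal_id in animals:
        lvco_m, rvco_m, circ_m, o2_m = config.cardiac_medians[group]
        eff = np.exp(rng.standard_normal(4) * sigma)
        for day in days:
            jitter = np.exp(rng.standard_normal(4) * sigma / 2.0)
            rows.append(
                {
                    "animal_id": animal_id,
                    "group": group,
                    "day": int(day),
                    "LVCO": lvco_m * eff[0] * jitter[0],
                    "RVCO": rvco_m * eff[1] * jitter[1],
                    "circuit_flow": circ_m * eff[2] * jitter[2],
                    "oxygen_delivery": o2_m * eff[3] * jitter[3],
                }
            )
    return pd.DataFrame(rows)
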