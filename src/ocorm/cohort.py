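"""Synthetic two-group CO-rebreathing cohorts.

Generates subjects in a control group (CONT) and a group with severely
reduced ejection fraction (EFsev), each with demographic and hematologic
attributes, a CO dose chosen to hit a target COHb rise, and a capillary COHb
time course.  The groups differ in their mixing kinetics: on the
15-min-normalized scale the EFsev curve sits above the control curve early
(default excess 2.8 points at 3 min, decaying to 0 at 15 min), emulating
delayed vascular mixing of the CO tracer.

Construction guarantees an exact round trip in noiseless mode: each subject's
6/8-min COHb rise equals the value implied by their true hemoglobin mass and
dose, so the deterministic analysis recovers the true Hbmass to floating-point
precision.  The 15-min-normalized curve of a subject equals the group profile
exactly, so kinetics contrasts recover the programmed offsets.

Defaults emulate the printed study conditions: Hbmass 12.0 +/- 2.5 (CONT) vs
10.6 +/- 1.6 g/kg (EFsev), BMI 22.7 +/- 2.6 vs 27.6 +/- 3.2, Hb 15.2 +/- 1.4
vs 16.2 +/- 1.7 g/dL, Hct 41.9 +/- 3.7 vs 44.2 +/- 4.0%, 2-min CO uptake
0.92 +/- 0.03, baseline COHb uniform on 0.8-1.4%, and absolute COHb means of
6.0% at 3 min and 5.6% at 6 min.  The reference normalized curve itself and
the height distributions are not published quantities; they are package
defaults calibrated so the absolute COHb means above are reproduced.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    HUEFNER_ML_CO_PER_G_HB,
    HematologyPanel,
    InvalidInputError,
    RebreathingSession,
    SAMPLE_TIMES_MIN,
    compute_k,
)


@dataclass(frozen=True)
class GroupParams:
    """Per-group sampling distributions (mean, SD unless noted)."""

    hbmass_per_kg: tuple[float, float]  # g/kg
    bmi: tuple[float, float]  # kg/m^2
    hb_conc: tuple[float, float]  # g/dL
    hct: tuple[float, float]  # %
    female_fraction: float
    #: EFsev excess over the reference normalized curve, points at each
    #: sampling time; zero for the reference group
    delta_offsets: tuple[float, ...] = (0.0,) * 6


CONT_DEFAULTS = GroupParams(
    hbmass_per_kg=(12.0, 2.5),
    bmi=(22.7, 2.6),
    hb_conc=(15.2, 1.4),
    hct=(41.9, 3.7),
    female_fraction=10 / 25,
)

EFSEV_DEFAULTS = GroupParams(
    hbmass_per_kg=(10.6, 1.6),
    bmi=(27.6, 3.2),
    hb_conc=(16.2, 1.7),
    hct=(44.2, 4.0),
    female_fraction=6 / 21,
    delta_offsets=(2.8, 1.0, 0.4, 0.5, 0.3, 0.0),
)

#: reference 15-min-normalized washout curve at (3, 6, 8, 10, 12, 15) min.
#: Not a published quantity: calibrated so that, with the default baseline and
#: target dCOHb distributions and the EFsev offsets, pooled absolute COHb
#: means are 6.0% at 3 min and 5.6% at 6 min.
REFERENCE_CURVE = (110.0, 103.5, 102.3, 101.5, 100.7, 100.0)


@dataclass(frozen=True)
class CohortConfig:
    """All tunable knobs of the synthetic-cohort generator."""

    n_cont: int = 25
    n_efsev: int = 21
    cont: GroupParams = CONT_DEFAULTS
    efsev: GroupParams = EFSEV_DEFAULTS
    reference_curve: tuple[float, ...] = REFERENCE_CURVE
    #: pre-rebreathing COHb, uniform bounds (%)
    baseline_cohb_range: tuple[float, float] = (0.8, 1.4)
    #: per-subject target mean COHb rise at 6/8 min (mean, SD, %-points);
    #: calibrated jointly with the reference curve (see module docstring)
    target_delta_cohb: tuple[float, float] = (4.46, 0.85)
    #: 2-min CO uptake fraction (mean, SD)
    uptake_fraction: tuple[float, float] = (0.92, 0.03)
    #: heights for BMI -> body mass, cm (mean, SD), by sex
    height_cm_male: tuple[float, float] = (175.0, 7.0)
    height_cm_female: tuple[float, float] = (165.0, 6.0)
    #: ambient conditions
    pressure_mmhg: tuple[float, float] = (755.0, 5.0)
    temperature_c: tuple[float, float] = (21.0, 2.0)
    #: additive measurement noise per capillary COHb sample, %-points
    noise_sd: float = 0.05
    #: hemoximeter recording resolution, %-points (0 disables rounding)
    resolution: float = 0.01
    #: fraction of exams with a missing post-rebreathing timepoint
    missing_rate: float = 0.114
    #: fraction of exams failed by CO leakage
    leakage_rate: float = 0.143

    def __post_init__(self) -> None:
        if self.n_cont < 0 or self.n_efsev < 0:
            raise InvalidInputError("cohort sizes must be >= 0")
        for name in ("missing_rate", "leakage_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise InvalidInputError(f"{name} must be in [0, 1], got {v}")
        if self.noise_sd < 0 or self.resolution < 0:
            raise InvalidInputError("noise_sd and resolution must be >= 0")
        if len(self.reference_curve) != len(SAMPLE_TIMES_MIN):
            raise InvalidInputError("reference_curve must cover all sampling times")
        if self.reference_curve[-1] != 100.0:
            raise InvalidInputError("reference_curve must end at 100 (15-min anchor)")
        if any(
            b > a for a, b in zip(self.reference_curve, self.reference_curve[1:])
        ):
            raise InvalidInputError("reference_curve must be non-increasing")

    def noiseless(self) -> "CohortConfig":
        """Copy with measurement noise, rounding, and missingness disabled."""
        return replace(
            self, noise_sd=0.0, resolution=0.0, missing_rate=0.0, leakage_rate=0.0
        )


@dataclass(frozen=True)
class SubjectProfile:
    """Ground-truth attributes of one synthetic subject."""

    subject_id: str
    group: str
    sex: str
    height_cm: float
    body_mass_kg: float
    hbmass_true_g: float
    hb_conc: float
    hct: float
    mchc: float
    baseline_cohb: float
    target_delta_cohb: float
    uptake_fraction: float
    pressure: float
    temperature: float

    @property
    def panel(self) -> HematologyPanel:
        return HematologyPanel(hb_conc=self.hb_conc, hct=self.hct, mchc=self.mchc)


@dataclass
class Cohort:
    """Generated subjects plus their simulated rebreathing sessions."""

    config: CohortConfig
    seed: int | None
    profiles: list[SubjectProfile]
    sessions: list[RebreathingSession]
    n_leakage: int = 0

    def to_session_frame(self) -> pd.DataFrame:
        """Wide session table, one row per exam (the session-CSV layout)."""
        rows = []
        for p, s in zip(self.profiles, self.sessions):
            row = {
                "subject_id": s.subject_id,
                "group": s.group,
                "pressure_mmhg": s.pressure,
                "temperature_c": s.temperature,
                "co_administered_ml": s.co_administered,
                "co_lost_ml": s.co_lost,
                "k_factor": s.k_factor,
                "cohb_pre": s.cohb_baseline,
            }
            series = dict(s.cohb_series)
            for t in SAMPLE_TIMES_MIN:
                row[f"cohb_{t}"] = series.get(t, np.nan)
            row.update(
                hb_g_dl=p.hb_conc,
                hct_pct=p.hct,
                mchc_g_dl=p.mchc,
                body_mass_kg=p.body_mass_kg,
                flags=";".join(s.flags),
            )
            rows.append(row)
        return pd.DataFrame(rows)

    def to_long_frame(self, include_leakage: bool = False) -> pd.DataFrame:
        """Long kinetics table (subject_id, group, time_min, cohb_pct)."""
        rows = []
        for s in self.sessions:
            if not include_leakage and "leakage" in s.flags:
                continue
            for t, v in s.cohb_series:
                rows.append(
                    {
                        "subject_id": s.subject_id,
                        "group": s.group,
                        "time_min": t,
                        "cohb_pct": v,
                    }
                )
        return pd.DataFrame(rows)


def _truncated_normal(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    low: float,
    high: float = np.inf,
    size: int | None = None,
) -> np.ndarray | float:
    """Normal draws truncated to (low, high) by resampling."""
    n = 1 if size is None else size
    out = rng.normal(mean, sd, n)
    bad = (out <= low) | (out >= high)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out <= low) | (out >= high)
    return float(out[0]) if size is None else out


def sample_subjects(
    config: CohortConfig, seed: int | np.random.Generator | None = None
) -> list[SubjectProfile]:
    """Draw subject profiles for both groups; reproducible under seed."""
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    profiles: list[SubjectProfile] = []
    specs = [("CONT", config.cont, config.n_cont), ("EFsev", config.efsev, config.n_efsev)]
    idx = 0
    for group, params, n in specs:
        for _ in range(n):
            idx += 1
            sex = "f" if rng.random() < params.female_fraction else "m"
            h_mean, h_sd = (
                config.height_cm_female if sex == "f" else config.height_cm_male
            )
            height = _truncated_normal(rng, h_mean, h_sd, 120.0, 220.0)
            bmi = _truncated_normal(rng, *params.bmi, 14.0, 60.0)
            mass = bmi * (height / 100.0) ** 2
            per_kg = _truncated_normal(rng, *params.hbmass_per_kg, 3.0)
            # Hb and Hct are physiologically coupled; draw them jointly so the
            # implied MCHC stays in a realistic band, then jitter MCHC slightly
            while True:
                z1, z2 = rng.standard_normal(2)
                rho = 0.8
                hb = params.hb_conc[0] + params.hb_conc[1] * z1
                hct = params.hct[0] + params.hct[1] * (
                    rho * z1 + np.sqrt(1 - rho**2) * z2
                )
                if not (0 < hb < 25 and 0 < hct < 100):
                    continue
                mchc = hb / (hct / 100.0) + rng.normal(0.0, 0.3)
                implied = hb / (hct / 100.0)
                if 25.5 < mchc < 39.5 and abs(mchc - implied) <= 0.14 * implied:
                    break
            profiles.append(
                SubjectProfile(
                    subject_id=f"sim_{idx:05d}",
                    group=group,
                    sex=sex,
                    height_cm=height,
                    body_mass_kg=mass,
                    hbmass_true_g=per_kg * mass,
                    hb_conc=hb,
                    hct=hct,
                    mchc=mchc,
                    baseline_cohb=rng.uniform(*config.baseline_cohb_range),
                    target_delta_cohb=_truncated_normal(
                        rng, *config.target_delta_cohb, 1.5
                    ),
                    uptake_fraction=_truncated_normal(
                        rng, *config.uptake_fraction, 0.5, 0.995
                    ),
                    pressure=_truncated_normal(rng, *config.pressure_mmhg, 500.0),
                    temperature=_truncated_normal(rng, *config.temperature_c, 10.0, 35.0),
                )
            )
    return profiles


def dose_for_target(
    hbmass_true_g: float,
    target_delta_cohb: float,
    k_factor: float,
    uptake_fraction: float,
) -> tuple[float, float, float]:
    """CO dose producing a target 6/8-min COHb rise for a known Hbmass.

    Inverts the Hbmass mass balance: MCO = Hbmass*1.39*dCOHb/(100*K); the
    administered volume is MCO over the 2-min uptake fraction and the residual
    is the difference.  Returns (co_administered, mco, co_residual), all ml.
    """
    if target_delta_cohb <= 0:
        raise InvalidInputError("target_delta_cohb must be > 0")
    if uptake_fraction <= 0:
        raise InvalidInputError("uptake_fraction must be > 0")
    mco = hbmass_true_g * HUEFNER_ML_CO_PER_G_HB * target_delta_cohb / (100.0 * k_factor)
    administered = mco / uptake_fraction
    return administered, mco, administered - mco


def simulate_cohb_series(
    profile: SubjectProfile,
    config: CohortConfig,
    seed: int | np.random.Generator | None = None,
) -> RebreathingSession:
    """Simulate one subject's full rebreathing session.

    The group's normalized curve (reference + group offsets) is scaled so the
    mean COHb at 6 and 8 min exceeds baseline by exactly the subject's
    Hbmass-implied target rise; Gaussian measurement noise and recording
    rounding are then applied per sample.
    """
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    params = config.efsev if profile.group == "EFsev" else config.cont
    curve = np.asarray(config.reference_curve) + np.asarray(params.delta_offsets)
    times = SAMPLE_TIMES_MIN
    i6, i8 = times.index(6), times.index(8)

    k = compute_k(profile.pressure, profile.temperature)
    administered, mco, residual = dose_for_target(
        profile.hbmass_true_g, profile.target_delta_cohb, k, profile.uptake_fraction
    )
    # scale the curve so mean(COHb@6, COHb@8) - baseline hits the target rise
    scale = (
        200.0
        * (profile.target_delta_cohb + profile.baseline_cohb)
        / (curve[i6] + curve[i8])
    )
    cohb = scale * curve / 100.0
    baseline = profile.baseline_cohb
    if config.noise_sd > 0:
        cohb = cohb + rng.normal(0.0, config.noise_sd, len(cohb))
        baseline = baseline + rng.normal(0.0, config.noise_sd)
    if config.resolution > 0:
        cohb = np.round(cohb / config.resolution) * config.resolution
        baseline = round(baseline / config.resolution) * config.resolution
    if (cohb > 100).any() or baseline > 100:
        raise InvalidInputError(
            f"{profile.subject_id}: simulated COHb exceeds 100% (unphysical config)"
        )
    return RebreathingSession(
        subject_id=profile.subject_id,
        group=profile.group,
        pressure=profile.pressure,
        temperature=profile.temperature,
        co_administered=administered,
        co_lost=residual,
        cohb_baseline=float(baseline),
        cohb_series=tuple((float(t), float(v)) for t, v in zip(times, cohb)),
    )


def apply_missingness(
    cohort: Cohort, seed: int | np.random.Generator | None = None
) -> Cohort:
    """Mark leakage failures and blank random timepoints at the config rates.

    With probability ``missing_rate`` one post-rebreathing timepoint (uniform
    among the six) is removed from an exam, making it incomplete; with
    probability ``leakage_rate`` the exam is flagged as a leakage failure.
    """
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    cfg = cohort.config
    sessions: list[RebreathingSession] = []
    n_leak = 0
    for s in cohort.sessions:
        series = list(s.cohb_series)
        flags = list(s.flags)
        if cfg.missing_rate > 0 and rng.random() < cfg.missing_rate:
            series.pop(rng.integers(len(series)))
            flags.append("missing_timepoint")
        if cfg.leakage_rate > 0 and rng.random() < cfg.leakage_rate:
            flags.append("leakage")
            n_leak += 1
        new = replace(s, cohb_series=tuple(series), flags=[])
        new.flags.extend(f for f in flags if f not in new.flags)
        sessions.append(new)
    return Cohort(
        config=cfg,
        seed=cohort.seed,
        profiles=cohort.profiles,
        sessions=sessions,
        n_leakage=n_leak,
    )


def generate_cohort(
    config: CohortConfig | None = None,
    seed: int | None = None,
    with_missingness: bool = False,
) -> Cohort:
    """Generate a complete synthetic cohort (profiles + sessions).

    ``with_missingness`` additionally applies the configured missingness and
    leakage processes; by default all exams are complete.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(seed)
    profiles = sample_subjects(config, rng)
    sessions = [simulate_cohb_series(p, config, rng) for p in profiles]
    cohort = Cohort(config=config, seed=seed, profiles=profiles, sessions=sessions)
    if with_missingness:
        cohort = apply_missingness(cohort, rng)
    return cohort
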