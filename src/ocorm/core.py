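"""Deterministic optimized CO-rebreathing (oCORM) calculations.

The oCORM exam labels circulating hemoglobin with a small bolus of carbon
monoxide rebreathed for 2 min and measures the resulting rise of
carboxyhemoglobin (COHb) in capillary blood.  Total hemoglobin mass follows
from a CO mass balance::

    Hbmass = K * MCO * 100 / (dCOHb * 1.39)

where ``K`` corrects the gas volume for barometric pressure and temperature,
``MCO`` is the CO volume actually circulating (administered minus losses to
the system, lung, and exhalation, ml), ``dCOHb`` is the COHb rise above
baseline in percentage points (conventionally the mean of the 6- and 8-min
samples), and 1.39 ml CO per g Hb is Huefner's number.  Red cell, blood, and
plasma volumes derive from Hbmass, MCHC, and hematocrit, the latter corrected
to whole-body hematocrit by the factor 0.91.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

HUEFNER_ML_CO_PER_G_HB = 1.39
STANDARD_PRESSURE_MMHG = 760.0
GAS_EXPANSION_PER_C = 0.003661  # 1/273.15, thermal expansion coefficient

#: capillary sampling grid (minutes after commencement of rebreathing)
SAMPLE_TIMES_MIN = (3, 6, 8, 10, 12, 15)
#: conventional Hbmass sampling times
DEFAULT_HBMASS_TIMES = (6, 8)

KConvention = Literal["as_printed", "stpd"]


class InvalidInputError(ValueError):
    """An input violates a physical or range constraint."""


class MissingDataError(KeyError):
    """A required timepoint or field is absent."""


class DegenerateMeasurementError(ValueError):
    """The session shows no CO uptake (dCOHb <= 0)."""


@dataclass(frozen=True)
class HematologyPanel:
    """Hematologic quantities needed for volume derivation.

    Parameters
    ----------
    hb_conc : float
        Hemoglobin concentration, g/dL.
    hct : float
        Venous/capillary hematocrit, percent.
    mchc : float
        Mean corpuscular hemoglobin concentration, g/dL of red cells.
        Derived as ``hb_conc / (hct/100)`` when not supplied.
    """

    hb_conc: float
    hct: float
    mchc: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.hct < 100:
            raise InvalidInputError(f"hct must be in (0, 100)%, got {self.hct}")
        if not 0 < self.hb_conc < 25:
            raise InvalidInputError(
                f"hb_conc must be in (0, 25) g/dL, got {self.hb_conc}"
            )
        if self.mchc is None:
            object.__setattr__(self, "mchc", self.hb_conc / (self.hct / 100.0))
        if not 25 <= self.mchc <= 40:
            raise InvalidInputError(
                f"mchc must be in [25, 40] g/dL, got {self.mchc:.2f}"
            )
        implied = self.hb_conc / (self.hct / 100.0)
        if abs(self.mchc - implied) > 0.15 * implied:
            raise InvalidInputError(
                f"mchc {self.mchc:.1f} inconsistent with hb/hct (implies "
                f"{implied:.1f} g/dL, tolerance 15%)"
            )


@dataclass
class RebreathingSession:
    """One oCORM exam: environment, CO dose accounting, COHb time series.

    ``cohb_series`` holds ordered ``(time_min, cohb_percent)`` pairs at times
    drawn from :data:`SAMPLE_TIMES_MIN`; ``cohb_baseline`` is the
    pre-rebreathing COHb.  ``k_factor``, when supplied (as printed session
    records do), bypasses the pressure/temperature formula.
    """

    subject_id: str
    co_administered: float
    co_lost: float
    cohb_baseline: float
    cohb_series: Sequence[tuple[float, float]]
    group: str | None = None
    pressure: float | None = None
    temperature: float | None = None
    k_factor: float | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.group is not None and self.group not in ("CONT", "EFsev"):
            raise InvalidInputError(f"group must be CONT or EFsev, got {self.group!r}")
        if self.pressure is not None and self.pressure <= 0:
            raise InvalidInputError(f"pressure must be > 0, got {self.pressure}")
        if self.temperature is not None and not -10 <= self.temperature <= 45:
            raise InvalidInputError(
                f"temperature must be in [-10, 45] C, got {self.temperature}"
            )
        if self.co_administered <= 0:
            raise InvalidInputError(
                f"co_administered must be > 0, got {self.co_administered}"
            )
        if not 0 <= self.co_lost < self.co_administered:
            raise InvalidInputError(
                f"co_lost must be in [0, co_administered), got {self.co_lost}"
            )
        times = [t for t, _ in self.cohb_series]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise InvalidInputError("cohb_series times must be strictly increasing")
        values = [v for _, v in self.cohb_series] + [self.cohb_baseline]
        if any(not 0 <= v <= 100 for v in values):
            raise InvalidInputError("COHb values must lie in [0, 100]%")
        # below-baseline readings are suspicious but not fatal: flag only
        if any(v < self.cohb_baseline for _, v in self.cohb_series):
            self.flags.append("cohb_below_baseline")

    def cohb_at(self, time_min: float) -> float:
        for t, v in self.cohb_series:
            if t == time_min:
                return v
        raise MissingDataError(
            f"session {self.subject_id}: no COHb sample at {time_min} min"
        )

    @property
    def times(self) -> tuple[float, ...]:
        return tuple(t for t, _ in self.cohb_series)


@dataclass(frozen=True)
class HbmassResult:
    """Derived oCORM measurement outputs for one session."""

    subject_id: str
    k_factor: float
    mco: float
    delta_cohb: float
    hbmass_g: float
    rcv_ml: float | None
    bv_ml: float | None
    pv_ml: float | None
    uptake_fraction: float | None
    warnings: tuple[str, ...] = ()


def compute_k(
    pressure: float,
    temperature: float,
    convention: KConvention = "as_printed",
) -> float:
    """Barometric/temperature gas-volume correction factor K.

    ``as_printed`` evaluates ``(pressure/760) * (1 + 0.003661*T)``; ``stpd``
    divides by the temperature term instead, the standard conversion of an
    ambient gas volume to standard temperature and pressure, dry.  Both are
    offered because printed K values near 0.93 at room conditions are only
    consistent with the sub-unity (stpd) form.
    """
    if pressure <= 0:
        raise InvalidInputError(f"pressure must be > 0, got {pressure}")
    thermal = 1.0 + GAS_EXPANSION_PER_C * temperature
    if convention == "as_printed":
        return pressure / STANDARD_PRESSURE_MMHG * thermal
    if convention == "stpd":
        return pressure / STANDARD_PRESSURE_MMHG / thermal
    raise InvalidInputError(f"unknown K convention {convention!r}")


def compute_mco(co_administered: float, co_lost: float | Sequence[float]) -> float:
    """CO volume circulating in blood: administered minus losses (ml).

    ``co_lost`` may be a single figure or itemized components (system
    residual, exhaled, myoglobin-bound), which are summed.
    """
    lost = float(sum(co_lost)) if not isinstance(co_lost, (int, float)) else float(co_lost)
    if co_administered <= 0:
        raise InvalidInputError(f"co_administered must be > 0, got {co_administered}")
    if not 0 <= lost < co_administered:
        raise InvalidInputError(
            f"co_lost ({lost}) must be in [0, co_administered={co_administered})"
        )
    return co_administered - lost


def compute_delta_cohb(
    session: RebreathingSession,
    sample_times: Sequence[float] = DEFAULT_HBMASS_TIMES,
) -> float:
    """COHb rise above baseline: mean over ``sample_times`` minus baseline.

    The mean of the sampled COHb values is taken first, then the baseline
    subtracted (equivalent to averaging per-time differences).
    """
    values = [session.cohb_at(t) for t in sample_times]
    return sum(values) / len(values) - session.cohb_baseline


def compute_hbmass(k_factor: float, mco: float, delta_cohb: float) -> float:
    """Total hemoglobin mass (g) from the CO mass balance."""
    if k_factor <= 0:
        raise InvalidInputError(f"k_factor must be > 0, got {k_factor}")
    if mco <= 0:
        raise InvalidInputError(f"mco must be > 0, got {mco}")
    if delta_cohb <= 0:
        raise DegenerateMeasurementError(
            f"no CO uptake detected (dCOHb = {delta_cohb})"
        )
    return k_factor * mco * 100.0 / (delta_cohb * HUEFNER_ML_CO_PER_G_HB)


def compute_volumes(
    hbmass_g: float,
    panel: HematologyPanel,
    body_hct_factor: float = 0.91,
) -> tuple[float, float, float]:
    """Red cell, blood, and plasma volume (ml) from Hbmass and hematology.

    RCV = Hbmass/MCHC*100; BV = RCV*100/(Hct*f) with the whole-body
    hematocrit factor f (default 0.91); PV = BV - RCV, so PV + RCV = BV
    holds exactly by construction.
    """
    if hbmass_g <= 0:
        raise InvalidInputError(f"hbmass_g must be > 0, got {hbmass_g}")
    if panel.mchc <= 0 or panel.hct <= 0:
        raise InvalidInputError("mchc and hct must be > 0")
    rcv = hbmass_g / panel.mchc * 100.0
    whole_body_hct = panel.hct * body_hct_factor
    bv = rcv * 100.0 / whole_body_hct
    pv = bv - rcv
    # re-derive BV from its parts so the conservation identity is bit-exact
    return rcv, rcv + pv, pv


def compute_uptake_fraction(co_administered: float, co_residual_after_2min: float) -> float:
    """Fraction of the administered CO taken up within the 2-min rebreathing.

    A proxy proportional to pulmonary CO diffusion capacity: CO that left the
    circuit over the administered amount.
    """
    if co_administered <= 0:
        raise InvalidInputError(f"co_administered must be > 0, got {co_administered}")
    if not 0 <= co_residual_after_2min <= co_administered:
        raise InvalidInputError(
            f"residual ({co_residual_after_2min}) must be in [0, administered]"
        )
    return (co_administered - co_residual_after_2min) / co_administered


@dataclass(frozen=True)
class AnalysisOptions:
    """Tunable parameters of :func:`analyze_session`."""

    sample_times: tuple[float, ...] = DEFAULT_HBMASS_TIMES
    k_convention: KConvention = "as_printed"
    body_hct_factor: float = 0.91
    safety_cohb_threshold: float = 10.0


def analyze_session(
    session: RebreathingSession,
    panel: HematologyPanel | None = None,
    options: AnalysisOptions | None = None,
) -> HbmassResult:
    """Full oCORM evaluation of one session.

    Computes K (or uses the session's supplied value verbatim), MCO, dCOHb at
    the configured sampling times, Hbmass, and — when a hematology panel is
    given — the intravascular volumes.  A warning flag is set when any COHb
    reading exceeds the safety threshold (default 10%).
    """
    opts = options or AnalysisOptions()
    warnings = list(session.flags)
    try:
        if session.k_factor is not None:
            k = session.k_factor
        elif session.pressure is not None and session.temperature is not None:
            k = compute_k(session.pressure, session.temperature, opts.k_convention)
        else:
            raise MissingDataError(
                "neither k_factor nor pressure+temperature supplied"
            )
        mco = compute_mco(session.co_administered, session.co_lost)
        delta = compute_delta_cohb(session, opts.sample_times)
        hbmass = compute_hbmass(k, mco, delta)
    except (InvalidInputError, MissingDataError, DegenerateMeasurementError) as err:
        raise type(err)(f"session {session.subject_id}: {err}") from err

    all_cohb = [session.cohb_baseline] + [v for _, v in session.cohb_series]
    if any(v > opts.safety_cohb_threshold for v in all_cohb):
        warnings.append(f"cohb_above_{opts.safety_cohb_threshold:g}pct")

    rcv = bv = pv = None
    if panel is not None:
        rcv, bv, pv = compute_volumes(hbmass, panel, opts.body_hct_factor)

    uptake = None
    if session.co_lost > 0:
        # interpret co_lost as the circuit residual + losses up to sampling;
        # the 2-min uptake proxy uses the residual when itemized, else total
        uptake = compute_uptake_fraction(session.co_administered, session.co_lost)

    if not math.isfinite(hbmass):
        raise DegenerateMeasurementError(
            f"session {session.subject_id}: non-finite Hbmass"
        )
    return HbmassResult(
        subject_id=session.subject_id,
        k_factor=k,
        mco=mco,
        delta_cohb=delta,
        hbmass_g=hbmass,
        rcv_ml=rcv,
        bv_ml=bv,
        pv_ml=pv,
        uptake_fraction=uptake,
        warnings=tuple(warnings),
    )
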