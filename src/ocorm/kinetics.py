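"""COHb washout kinetics: normalization and group contrasts.

After the rebreathing period, capillary COHb declines as CO redistributes and
is slowly eliminated.  By 15 min the slow, roughly linear washout phase is
assumed reached, so each subject's series is normalized to its 15-min value
(x 100).  On that scale, group differences between heart-failure patients with
severely reduced ejection fraction (EFsev) and controls (CONT) isolate mixing
kinetics from the COHb level itself.

The model is a linear mixed model with a random intercept per subject, time as
a categorical fixed effect (equivalently a saturated orthogonal-polynomial
basis), a group main effect, and time-by-group interactions.  The 15-min cell
is identically 100 by construction (zero variance) and is excluded from the
response; it only serves as the normalization anchor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import MissingDataError, SAMPLE_TIMES_MIN

logger = logging.getLogger(__name__)

#: timepoints modelled (the 15-min anchor is excluded, see module docstring)
MODEL_TIMES = tuple(t for t in SAMPLE_TIMES_MIN if t != 15)


class ModelFitError(RuntimeError):
    """The kinetics design is singular or the fit failed."""


@dataclass(frozen=True)
class NormalizedSeries:
    """A subject's post-rebreathing COHb series normalized to the 15-min value."""

    subject_id: str
    group: str
    values: tuple[tuple[float, float], ...]  # (time_min, normalized %)


@dataclass(frozen=True)
class KineticsContrast:
    """Model-based group difference (EFsev - CONT) at one timepoint."""

    time_min: float
    estimate: float  # normalized percentage points
    standard_error: float
    p_value: float
    n_per_group: dict[str, int]
    significant: bool  # at alpha = 0.05


@dataclass(frozen=True)
class InteractionTest:
    """Wald test of the time-by-group interaction at one polynomial degree."""

    polynomial_degree: int
    statistic: float
    p_value: float


@dataclass(frozen=True)
class KineticsFit:
    """Fitted kinetics model: interaction tests and per-timepoint effects."""

    interactions: tuple[InteractionTest, ...]
    contrasts: tuple[KineticsContrast, ...]
    n_subjects: dict[str, int]
    n_excluded: int
    group_effect: float  # average EFsev - CONT offset over modelled times
    converged: bool


def normalize_series(
    series: list[tuple[float, float]],
    subject_id: str = "",
    group: str = "",
) -> NormalizedSeries:
    """Normalize a complete post-rebreathing series to its 15-min value.

    Requires all six post-rebreathing timepoints (3, 6, 8, 10, 12, 15 min);
    the pre-rebreathing baseline is not part of the normalization.
    """
    times = tuple(t for t, _ in series)
    if 15 not in times:
        raise MissingDataError(f"subject {subject_id}: 15-min value missing")
    if set(times) != set(SAMPLE_TIMES_MIN):
        missing = sorted(set(SAMPLE_TIMES_MIN) - set(times))
        raise MissingDataError(
            f"subject {subject_id}: incomplete series, missing timepoints {missing}"
        )
    anchor = dict(series)[15]
    if anchor <= 0:
        raise MissingDataError(f"subject {subject_id}: non-positive 15-min value")
    values = tuple((t, 100.0 * v / anchor) for t, v in series)
    return NormalizedSeries(subject_id=subject_id, group=group, values=values)


def normalize_cohort(long_table: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Normalize every subject in a long table (subject_id, group, time_min, cohb_pct).

    Subjects with any missing post-rebreathing timepoint are excluded listwise,
    mirroring a complete-case kinetics analysis; the exclusion count is
    returned and logged.
    """
    rows: list[dict] = []
    n_excluded = 0
    for (sid, grp), sub in long_table.groupby(["subject_id", "group"], sort=False):
        sub = sub.dropna(subset=["cohb_pct"])
        pairs = sorted(zip(sub["time_min"], sub["cohb_pct"]))
        pairs = [(t, v) for t, v in pairs if t in SAMPLE_TIMES_MIN]
        try:
            norm = normalize_series(pairs, subject_id=str(sid), group=str(grp))
        except MissingDataError as err:
            logger.info("excluding %s: %s", sid, err)
            n_excluded += 1
            continue
        for t, v in norm.values:
            rows.append(
                {"subject_id": sid, "group": grp, "time_min": t, "normalized": v}
            )
    return pd.DataFrame(rows), n_excluded


def _orthogonal_time_basis(times: np.ndarray) -> np.ndarray:
    """Orthonormal polynomial basis (degrees 1..k-1) over k distinct times."""
    levels = np.sort(np.unique(times))
    vand = np.vander(levels, N=len(levels), increasing=True).astype(float)
    q, _ = np.linalg.qr(vand)
    # columns 1.. are the centered orthogonal polynomials, degree = column index
    return q[:, 1:]


def fit_time_group_model(long_table: pd.DataFrame, max_degree: int = 3) -> KineticsFit:
    """Fit the mixed kinetics model and extract interactions and contrasts.

    Parameters
    ----------
    long_table : DataFrame
        Columns ``subject_id, group, time_min, cohb_pct`` (raw COHb; it is
        normalized here) or ``normalized`` if already normalized.
    max_degree : int
        Highest polynomial degree of the time-by-group interaction to report
        (default 3).

    Returns
    -------
    KineticsFit with one :class:`InteractionTest` per degree 1..max_degree and
    one :class:`KineticsContrast` per modelled timepoint.
    """
    import statsmodels.api as sm

    if "normalized" in long_table.columns:
        data, n_excluded = long_table.copy(), 0
    else:
        data, n_excluded = normalize_cohort(long_table)
    if data.empty:
        raise ModelFitError("no complete subjects to fit")
    data = data[data["time_min"].isin(MODEL_TIMES)].copy()

    groups = sorted(data["group"].unique())
    if len(groups) != 2:
        raise ModelFitError(f"need exactly two groups, got {groups}")
    ref, alt = ("CONT", "EFsev") if set(groups) == {"CONT", "EFsev"} else groups
    n_subj = {
        g: data.loc[data["group"] == g, "subject_id"].nunique() for g in (ref, alt)
    }
    if min(n_subj.values()) < 2:
        raise ModelFitError(f"need >=2 subjects per group, got {n_subj}")

    times = np.asarray(sorted(data["time_min"].unique()), dtype=float)
    if len(times) < 2:
        raise ModelFitError("need >=2 timepoints")
    basis = _orthogonal_time_basis(times)  # (k, k-1), degree d in column d-1
    time_idx = data["time_min"].map({t: i for i, t in enumerate(times)}).to_numpy()
    g = (data["group"] == alt).to_numpy(dtype=float)

    p = basis[time_idx]  # per-row polynomial values
    exog = np.column_stack([np.ones(len(data)), p, g, p * g[:, None]])
    names = (
        ["intercept"]
        + [f"time_p{d}" for d in range(1, len(times))]
        + ["group"]
        + [f"group:time_p{d}" for d in range(1, len(times))]
    )

    model = sm.MixedLM(
        data["normalized"].to_numpy(), exog, groups=data["subject_id"].to_numpy()
    )
    try:
        fit = model.fit(reml=True)
    except Exception as err:  # pragma: no cover - singular designs
        raise ModelFitError(f"mixed model failed: {err}") from err

    beta = np.asarray(fit.fe_params)
    cov = np.asarray(fit.cov_params())[: len(beta), : len(beta)]
    df_t = sum(n_subj.values()) - 2  # between-subject contrast df

    interactions = []
    for d in range(1, min(max_degree, len(times) - 1) + 1):
        j = names.index(f"group:time_p{d}")
        z = beta[j] / np.sqrt(cov[j, j])
        pval = 2 * stats.t.sf(abs(z), df_t)
        interactions.append(
            InteractionTest(polynomial_degree=d, statistic=float(z), p_value=float(pval))
        )

    contrasts = []
    jg = names.index("group")
    for i, t in enumerate(times):
        ell = np.zeros(len(beta))
        ell[jg] = 1.0
        for d in range(1, len(times)):
            ell[names.index(f"group:time_p{d}")] = basis[i, d - 1]
        est = float(ell @ beta)
        se = float(np.sqrt(ell @ cov @ ell))
        tstat = est / se
        pval = float(2 * stats.t.sf(abs(tstat), df_t))
        contrasts.append(
            KineticsContrast(
                time_min=float(t),
                estimate=est,
                standard_error=se,
                p_value=pval,
                n_per_group=dict(n_subj),
                significant=pval < 0.05,
            )
        )

    return KineticsFit(
        interactions=tuple(interactions),
        contrasts=tuple(contrasts),
        n_subjects=dict(n_subj),
        n_excluded=n_excluded,
        group_effect=float(beta[jg]),
        converged=bool(fit.converged),
    )


def group_contrasts(
    long_table: pd.DataFrame, times: list[float] | None = None
) -> list[KineticsContrast]:
    """Per-timepoint EFsev - CONT differences from the mixed kinetics model."""
    fit = fit_time_group_model(long_table)
    by_time = {c.time_min: c for c in fit.contrasts}
    if times is None:
        return list(fit.contrasts)
    out = []
    for t in times:
        if float(t) not in by_time:
            raise MissingDataError(f"no modelled contrast at {t} min")
        out.append(by_time[float(t)])
    return out
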