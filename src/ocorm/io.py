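"""CSV readers/writers for session records and kinetics tables.

The session CSV is one row per exam (UTF-8, comma separator, point decimal):
``subject_id, group, pressure_mmhg, temperature_c, co_administered_ml,
co_lost_ml, k_factor, cohb_pre, cohb_3 ... cohb_15, hb_g_dl, hct_pct,
mchc_g_dl, body_mass_kg``; blank cells are missing.  ``k_factor``, when
present, overrides the pressure/temperature formula.  The kinetics table is
long format: ``subject_id, group, time_min, cohb_pct``.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    HbmassResult,
    HematologyPanel,
    InvalidInputError,
    RebreathingSession,
    SAMPLE_TIMES_MIN,
)

SESSION_COLUMNS = (
    ["subject_id", "group", "pressure_mmhg", "temperature_c", "co_administered_ml",
     "co_lost_ml", "k_factor", "cohb_pre"]
    + [f"cohb_{t}" for t in SAMPLE_TIMES_MIN]
    + ["hb_g_dl", "hct_pct", "mchc_g_dl", "body_mass_kg"]
)


def _opt(row: pd.Series, key: str) -> float | None:
    v = row.get(key)
    if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
        return None
    return float(v)


def session_from_row(row: pd.Series) -> tuple[RebreathingSession, HematologyPanel | None]:
    """Build a session (and hematology panel, if supplied) from one CSV row."""
    co_lost = _opt(row, "co_lost_ml")
    if co_lost is None:
        parts = [
            _opt(row, c)
            for c in ("co_residual_ml", "co_exhaled_ml", "co_myoglobin_ml")
        ]
        if all(p is None for p in parts):
            raise InvalidInputError(
                f"row {row.get('subject_id')}: no co_lost_ml or itemized losses"
            )
        co_lost = sum(p for p in parts if p is not None)
    series = []
    for t in SAMPLE_TIMES_MIN:
        v = _opt(row, f"cohb_{t}")
        if v is not None:
            series.append((float(t), v))
    group = row.get("group")
    if group is not None and (pd.isna(group) or group == ""):
        group = None
    session = RebreathingSession(
        subject_id=str(row["subject_id"]),
        group=group,
        pressure=_opt(row, "pressure_mmhg"),
        temperature=_opt(row, "temperature_c"),
        co_administered=float(row["co_administered_ml"]),
        co_lost=co_lost,
        k_factor=_opt(row, "k_factor"),
        cohb_baseline=float(row["cohb_pre"]),
        cohb_series=tuple(series),
    )
    hb, hct = _opt(row, "hb_g_dl"), _opt(row, "hct_pct")
    panel = (
        HematologyPanel(hb_conc=hb, hct=hct, mchc=_opt(row, "mchc_g_dl"))
        if hb is not None and hct is not None
        else None
    )
    return session, panel


def read_sessions(path: str | Path) -> pd.DataFrame:
    """Read a session CSV; raises on empty or header-less files."""
    df = pd.read_csv(path)
    if df.empty:
        raise InvalidInputError(f"{path}: no session rows")
    missing = {"subject_id", "co_administered_ml", "cohb_pre"} - set(df.columns)
    if missing:
        raise InvalidInputError(f"{path}: missing required columns {sorted(missing)}")
    return df


def results_to_frame(results: list[HbmassResult]) -> pd.DataFrame:
    rows = [
        {
            "subject_id": r.subject_id,
            "k_factor": r.k_factor,
            "mco_ml": r.mco,
            "delta_cohb_pct": r.delta_cohb,
            "hbmass_g": r.hbmass_g,
            "rcv_ml": r.rcv_ml,
            "bv_ml": r.bv_ml,
            "pv_ml": r.pv_ml,
            "uptake_fraction": r.uptake_fraction,
            "warnings": ";".join(r.warnings),
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def example_sessions_path() -> Path:
    """Path of the packaged three-subject example session CSV."""
    return Path(importlib.resources.files("ocorm") / "data" / "example_sessions.csv")
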