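"""File formats: CGM CSV, event CSV, parameter YAML.

All files are comma-separated UTF-8 with a mandatory header row and '.'
decimal separator.  Time is integer minutes from series start; rates and
doses are in user units (g, U, mg/dL) and converted to internal units at the
model boundary.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .model import BasalSegment, Bolus, EventSchedule, MealEvent
from .params import PatientParameters
from .series import GLUCOSE_RANGE, CGMSeries

log = logging.getLogger(__name__)

PathLike = Union[str, Path]

CGM_COLUMNS = ("time_min", "glucose_mgdl")
EVENT_COLUMNS = ("time_min", "type", "value", "abs_class")
EVENT_TYPES = ("meal", "bolus", "basal")

#: local clock window (minutes past midnight) in which unlabelled meals are
#: treated as medium absorption (lunch/dinner); outside it they are fast
#: (breakfast and snacks).
MEDIUM_MEAL_WINDOW = (11 * 60, 22 * 60)


class ParseError(ValueError):
    """Malformed input file; the message names the offending row."""


def default_meal_class(time_min: float) -> str:
    """Absorption class for a meal with no recorded class, by time of day."""
    tod = time_min % 1440
    if MEDIUM_MEAL_WINDOW[0] <= tod < MEDIUM_MEAL_WINDOW[1]:
        return "medium"
    return "fast"


def read_cgm_csv(path: PathLike, m: int = 5) -> CGMSeries:
    """Read a CGM series; rejects out-of-range glucose and non-monotone time."""
    df = pd.read_csv(path)
    missing = [c for c in CGM_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    t = df["time_min"].to_numpy(dtype=float)
    g = df["glucose_mgdl"].to_numpy(dtype=float)
    if not np.all(np.isfinite(t)) or not np.all(np.isfinite(g)):
        rows = np.flatnonzero(~(np.isfinite(t) & np.isfinite(g)))[:5] + 2
        raise ParseError(f"{path}: non-numeric values at rows {rows.tolist()}")
    bad_t = np.flatnonzero(np.diff(t) <= 0)
    if bad_t.size:
        raise ParseError(
            f"{path}: non-increasing time at row {int(bad_t[0]) + 3} "
            f"(t={t[bad_t[0] + 1]})"
        )
    bad_g = np.flatnonzero((g < GLUCOSE_RANGE[0]) | (g > GLUCOSE_RANGE[1]))
    if bad_g.size:
        raise ParseError(
            f"{path}: glucose outside {GLUCOSE_RANGE} at rows "
            f"{(bad_g[:5] + 2).tolist()}"
        )
    imputed = (
        df["imputed"].to_numpy(dtype=bool)
        if "imputed" in df.columns
        else np.zeros(t.size, dtype=bool)
    )
    return CGMSeries(t, g, imputed, m)


def write_cgm_csv(cgm: CGMSeries, path: PathLike) -> None:
    pd.DataFrame(
        {"time_min": cgm.t, "glucose_mgdl": cgm.g, "imputed": cgm.imputed.astype(int)}
    ).to_csv(path, index=False)


def read_events_csv(path: PathLike) -> EventSchedule:
    """Read meal/bolus/basal events.

    Meal rows with a blank absorption class default by local time of day:
    breakfast and snacks fast, lunch and dinner medium.
    """
    df = pd.read_csv(path)
    missing = [c for c in EVENT_COLUMNS[:3] if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    meals, boluses, basal = [], [], []
    horizon = 0.0
    for i, row in df.iterrows():
        rowno = int(i) + 2
        try:
            t = float(row["time_min"])
            value = float(row["value"])
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: non-numeric time/value at row {rowno}") from exc
        if value < 0 or t < 0:
            raise ParseError(f"{path}: negative time or value at row {rowno}")
        etype = str(row["type"]).strip().lower()
        if etype == "meal":
            cls = row.get("abs_class")
            cls = None if cls is None or (isinstance(cls, float) and np.isnan(cls)) else str(cls).strip().lower()
            if not cls:
                cls = default_meal_class(t)
            if cls not in ("fast", "medium", "slow"):
                raise ParseError(f"{path}: unknown abs_class {cls!r} at row {rowno}")
            meals.append(MealEvent(t, value, cls))
        elif etype == "bolus":
            boluses.append(Bolus(t, value))
        elif etype == "basal":
            basal.append(BasalSegment(t, value))
        else:
            raise ParseError(f"{path}: unknown event type {etype!r} at row {rowno}")
        horizon = max(horizon, t)
    return EventSchedule(
        meals=meals, boluses=boluses, basal=basal, horizon_min=int(np.ceil(horizon)) + 1
    )


def write_events_csv(schedule: EventSchedule, path: PathLike) -> None:
    rows = []
    for ev in schedule.meals:
        rows.append((ev.time_min, "meal", ev.grams, ev.abs_class))
    for b in schedule.boluses:
        rows.append((b.time_min, "bolus", b.units, ""))
    for seg in schedule.basal:
        rows.append((seg.start_min, "basal", seg.rate_u_per_h, ""))
    rows.sort(key=lambda r: r[0])
    pd.DataFrame(rows, columns=list(EVENT_COLUMNS)).to_csv(path, index=False)


def read_params_yaml(path: PathLike) -> PatientParameters:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ParseError(f"{path}: expected a flat key-value mapping")
    return PatientParameters.from_dict(data)


def write_params_yaml(params: PatientParameters, path: PathLike,
                      header: Optional[str] = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)
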