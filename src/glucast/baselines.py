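"""Third-order ARX glucose forecaster (comparison baseline).

The baseline regresses the next CGM sample on three lags of glucose and
three lags of two exogenous channels (insulin and carbohydrate), fit by
ordinary least squares on one-step-ahead error, and forecasts multiple steps
by recursive iteration, feeding predictions back as lags.

By default the exogenous channels are the raw event impulse trains binned
to the CGM grid (insulin units and carbohydrate grams per interval), the
simplest construction used by published ARX glucose forecasters.  A
"filtered" mode that passes the event log through the absorption submodels
with population parameters is available behind a flag; on data generated by
the same composite model those filtered channels hand the baseline the true
response shapes and make it an implicit physiological model, which defeats
its purpose as a data-driven comparator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

log = logging.getLogger(__name__)

from . import _kernels
from .model import EventSchedule
from .params import PatientParameters
from .series import CGMSeries

ORDER = 3


@dataclass
class ArxModel:
    """Fitted coefficients: 3 AR lags, 3 insulin lags, 3 carb lags, intercept."""

    ar: np.ndarray
    ex_ins: np.ndarray
    ex_cho: np.ndarray
    intercept: float
    m: int = 5

    @property
    def n_params(self) -> int:
        return self.ar.size + self.ex_ins.size + self.ex_cho.size + 1


def build_exogenous(
    schedule: EventSchedule,
    params: PatientParameters,
    t_grid: np.ndarray,
    mode: str = "raw",
    extra_minutes: int = 0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Exogenous input channels sampled on the CGM grid.

    ``filtered``: plasma insulin (uU/mL) and glucose rate of appearance
    (mg/min) from the absorption submodels with population parameters.
    ``raw``: impulse trains binned to the grid (U and g per interval).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    t_end = int(round(t_grid[-1])) + extra_minutes + 1
    if mode == "raw":
        m = t_grid[1] - t_grid[0] if t_grid.size > 1 else 5.0
        ins = np.zeros(t_grid.size)
        cho = np.zeros(t_grid.size)
        for b in schedule.boluses:
            idx = np.searchsorted(t_grid, b.time_min, side="right") - 1
            if 0 <= idx < ins.size:
                ins[idx] += b.units
        for ev in schedule.meals:
            idx = np.searchsorted(t_grid, ev.time_min, side="right") - 1
            if 0 <= idx < cho.size:
                cho[idx] += ev.grams
        return ins, cho
    if mode != "filtered":
        raise ValueError(f"unknown exogenous mode {mode!r}")
    ucho, uins, tmaxi, tmg = schedule.to_input_arrays(params, t_end)
    x0 = np.zeros(7)
    x0[0] = params.gb
    traj = _kernels.simulate_kernel(
        x0, params.to_vector(), ucho, uins, tmaxi, tmg, t_end - 1, 1.0
    )
    idx = np.round(t_grid).astype(int)
    return traj[idx, 4].copy(), traj[idx, 6].copy()


def fit_arx(
    cgm: CGMSeries,
    schedule: EventSchedule,
    params: Optional[PatientParameters] = None,
    mode: str = "raw",
) -> ArxModel:
    """OLS fit of the one-step-ahead ARX(3) model on a regular-grid series."""
    if not cgm.is_regular:
        raise ValueError("ARX requires a regular-grid (imputed) CGM series")
    params = params or PatientParameters()
    # grid times relative to series start so exogenous arrays align
    t_rel = cgm.t - cgm.t[0]
    shifted = EventSchedule(
        meals=[type(ev)(ev.time_min - cgm.t[0], ev.grams, ev.abs_class) for ev in schedule.meals
               if ev.time_min >= cgm.t[0]],
        boluses=[type(b)(b.time_min - cgm.t[0], b.units) for b in schedule.boluses
                 if b.time_min >= cgm.t[0]],
        basal=[type(s)(s.start_min - cgm.t[0], s.rate_u_per_h) for s in schedule.basal],
        horizon_min=int(t_rel[-1]) + 1,
    )
    ins, cho = build_exogenous(shifted, params, t_rel, mode=mode)
    y = cgm.g
    n = y.size
    n_params = 3 * ORDER + 1
    if n - ORDER < 10 * n_params:
        raise ValueError(
            f"need at least {10 * n_params + ORDER} samples to fit {n_params} parameters, got {n}"
        )
    rows = []
    targets = []
    for k in range(ORDER, n):
        rows.append(np.concatenate([
            y[k - ORDER:k][::-1], ins[k - ORDER:k][::-1], cho[k - ORDER:k][::-1], [1.0]
        ]))
        targets.append(y[k])
    a = np.asarray(rows)
    b = np.asarray(targets)
    coef, _, rank, _ = np.linalg.lstsq(a, b, rcond=None)
    if rank < n_params:
        # constant glucose or empty input channels: fall back to the
        # minimum-norm OLS solution (e.g. intercept-only for a flat series)
        log.warning("rank-deficient ARX regression (rank %d < %d); "
                    "using the minimum-norm least-squares fit", rank, n_params)
    return ArxModel(
        ar=coef[:ORDER], ex_ins=coef[ORDER:2 * ORDER], ex_cho=coef[2 * ORDER:3 * ORDER],
        intercept=float(coef[-1]), m=cgm.m,
    )


def predict_arx(
    model: ArxModel,
    history: Sequence[float],
    future_ins: Sequence[float],
    future_cho: Sequence[float],
    ph: int,
) -> float:
    """Recursive PH-ahead forecast from the last three observed samples.

    ``future_ins``/``future_cho`` hold the exogenous channel values at the
    anchor and the following steps (lags are taken from them as the recursion
    advances).
    """
    if ph % model.m:
        raise ValueError(f"ph={ph} is not a multiple of the sampling interval {model.m}")
    steps = ph // model.m
    hist = list(history)[-ORDER:]
    if len(hist) < ORDER:
        raise ValueError("need at least three history samples")
    ins = list(future_ins)
    cho = list(future_cho)
    if len(ins) < ORDER + steps or len(cho) < ORDER + steps:
        raise ValueError("insufficient exogenous history/future for the horizon")
    y = list(hist)
    for s in range(steps):
        ylags = y[-1], y[-2], y[-3]
        ilags = ins[ORDER + s - 1], ins[ORDER + s - 2], ins[ORDER + s - 3]
        clags = cho[ORDER + s - 1], cho[ORDER + s - 2], cho[ORDER + s - 3]
        nxt = (
            float(np.dot(model.ar, ylags))
            + float(np.dot(model.ex_ins, ilags))
            + float(np.dot(model.ex_cho, clags))
            + model.intercept
        )
        y.append(nxt)
    return y[-1]


def arx_forecast_series(
    model: ArxModel,
    cgm: CGMSeries,
    schedule: EventSchedule,
    params: Optional[PatientParameters] = None,
    ph: int = 30,
    mode: str = "raw",
) -> np.ndarray:
    """PH-ahead forecasts at every anchor (NaN before three lags exist)."""
    params = params or PatientParameters()
    t_rel = cgm.t - cgm.t[0]
    shifted = EventSchedule(
        meals=[type(ev)(ev.time_min - cgm.t[0], ev.grams, ev.abs_class) for ev in schedule.meals
               if ev.time_min >= cgm.t[0]],
        boluses=[type(b)(b.time_min - cgm.t[0], b.units) for b in schedule.boluses
                 if b.time_min >= cgm.t[0]],
        basal=[type(s)(s.start_min - cgm.t[0], s.rate_u_per_h) for s in schedule.basal],
        horizon_min=int(t_rel[-1]) + ph + 1,
    )
    grid = np.arange(t_rel[0], t_rel[-1] + ph + 1, cgm.m, dtype=float)
    ins, cho = build_exogenous(shifted, params, grid, mode=mode, extra_minutes=0)
    steps = ph // cgm.m
    n = len(cgm)
    out = np.full(n, np.nan)
    y = cgm.g
    for k in range(ORDER - 1, n):
        out[k] = predict_arx(
            model, y[k - (ORDER - 1): k + 1],  # last three observed values
            ins[k - ORDER + 1: k + steps + 1],
            cho[k - ORDER + 1: k + steps + 1],
            ph,
        )
    return out
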