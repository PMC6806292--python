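"""Per-CGM-sample forecast cycle and batch driver.

Each time a CGM sample arrives the cycle (i) advances the composite model by
the elapsed minutes with the scheduled inputs, (ii) deconvolves the CGM
signal to re-estimate the gut states, (iii) fuses model and deconvolution
estimates by fixed weighted averages

``Ra_check = Q1 Ra_tilde + (1-Q1) Ra``,
``Ra1_check = Q1 Ra1_tilde + (1-Q1) Ra1``,
``G_check = Q2 G_cgm + (1-Q2) G``,

leaving the insulin states (X, S1, S2, I) untouched, and (iv) propagates the
fused state open-loop over the prediction horizon to produce the forecast
``G(k+PH)``.  Future meals and boluses inside the horizon are assumed
announced and included in the propagation; announcement of meals can be
switched off for sensitivity studies.

``run_forecaster`` executes the cycle over a whole series using a compiled
kernel; ``fast=False`` selects a pure-Python reference path composed of the
individual operations, which must (and is tested to) agree with the kernel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from . import _kernels
from .deconvolution import Deconvolver, RaEstimate
from .model import EventSchedule, ModelState
from .params import PatientParameters
from .series import CGMSeries

#: samples needed before the first forecast (3-point regression derivative)
WARMUP_SAMPLES = 3


@dataclass
class FusionConfig:
    """Fusion weights and prediction horizon.

    ``q1`` weighs the deconvolution gut-state estimates against the model's,
    ``q2`` weighs the CGM measurement against the model glucose.  The paper's
    operating points are 0.5/0.5 during identification and 0.7/0.7 at test.
    ``ph`` is the prediction horizon in minutes (a positive multiple of the
    CGM interval); ``use_meal_classes`` enables the meal-absorption shifts;
    ``announce_meals`` feeds scheduled future meals to the propagation.
    """

    q1: float = 0.7
    q2: float = 0.7
    ph: int = 30
    use_meal_classes: bool = True
    announce_meals: bool = True

    def validate(self, m: int = 5) -> None:
        if not (0.0 <= self.q1 <= 1.0 and 0.0 <= self.q2 <= 1.0):
            raise ValueError(f"fusion weights must lie in [0, 1]: q1={self.q1}, q2={self.q2}")
        if self.ph < 0 or self.ph % m:
            raise ValueError(f"ph={self.ph} must be a non-negative multiple of M={m}")


@dataclass
class ForecastRecord:
    """One forecast anchored at sample time ``t_min``."""

    t_min: float
    g_fused: float
    g_forecast: float
    g_observed: Optional[float] = None
    observed_imputed: bool = False


def initialize(cgm0: float) -> ModelState:
    """Initial model state at the first CGM sample: ``[G_cgm, 0, ..., 0]``."""
    if not np.isfinite(cgm0) or cgm0 <= 0:
        raise ValueError(f"invalid initial CGM value {cgm0!r}")
    return ModelState(g=float(cgm0))


def fuse(
    model_state: ModelState,
    deconv: RaEstimate,
    cgm: float,
    cfg: FusionConfig,
) -> ModelState:
    """Weighted fusion of gut states and glucose; insulin states pass through."""
    cfg.validate(m=1)
    return ModelState(
        g=cfg.q2 * cgm + (1.0 - cfg.q2) * model_state.g,
        x=model_state.x,
        s1=model_state.s1,
        s2=model_state.s2,
        i=model_state.i,
        ra1=cfg.q1 * deconv.ra1_tilde + (1.0 - cfg.q1) * model_state.ra1,
        ra=cfg.q1 * deconv.ra_tilde + (1.0 - cfg.q1) * model_state.ra,
    )


def _py_step(x: np.ndarray, p: np.ndarray, ucho: float, uins: float,
             tmaxi: float, tmg: float, dt: float) -> np.ndarray:
    """Pure-Python mirror of the compiled Euler step (reference path)."""
    from .params import UU_PER_ML_PER_MU_PER_ML as _UU

    g, xa, s1, s2, i, ra1, ra = x
    d = np.array([
        -(p[0] + xa) * g + p[0] * p[2] + ra / (p[3] * p[5]),
        -p[7] * xa + p[7] * p[1] * i,
        uins - s1 / tmaxi,
        (s1 - s2) / tmaxi,
        -p[6] * i + _UU * s2 / (p[4] * p[5] * tmaxi),
        -(ra1 - p[8] * ucho) / tmg,
        -(ra - ra1) / tmg,
    ])
    return np.maximum(x + dt * d, 0.0)


def _build_arrays(
    cgm: CGMSeries,
    schedule: EventSchedule,
    params: PatientParameters,
    cfg: FusionConfig,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, int]:
    """Dense per-minute input arrays covering the series plus the horizon.

    Event times are absolute; the arrays are shifted so index 0 is the first
    CGM sample.
    """
    t0 = int(round(cgm.t[0]))
    n_min = int(round(cgm.t[-1])) - t0 + int(cfg.ph) + 1
    shifted = EventSchedule(
        meals=[type(ev)(ev.time_min - t0, ev.grams, ev.abs_class, ev.ag_scale, ev.tmaxg_scale)
               for ev in schedule.meals],
        boluses=[type(b)(b.time_min - t0, b.units, b.tmaxi_scale) for b in schedule.boluses],
        basal=[type(s)(s.start_min - t0, s.rate_u_per_h) for s in schedule.basal],
        horizon_min=n_min,
    )
    # events before the series start cannot be replayed into the state
    shifted.meals = [ev for ev in shifted.meals if ev.time_min >= 0]
    shifted.boluses = [b for b in shifted.boluses if b.time_min >= 0]
    ucho, uins, tmaxi, tmg = shifted.to_input_arrays(
        params, n_min, use_classes=cfg.use_meal_classes, use_perturbations=False
    )
    return ucho, uins, tmaxi, tmg, t0


def run_forecaster(
    cgm: CGMSeries,
    schedule: EventSchedule,
    params: PatientParameters,
    cfg: FusionConfig,
    fast: bool = True,
) -> List[ForecastRecord]:
    """Run the forecast cycle over a regular-grid CGM series.

    Returns one record per sample from warm start (third sample) onward;
    anchors whose target time exceeds the series end carry no observation.
    """
    if len(cgm) == 0:
        raise ValueError("empty CGM series")
    if not cgm.is_regular:
        raise ValueError(
            "CGM series has gaps or irregular sampling; run gap imputation first"
        )
    cfg.validate(m=cgm.m)
    out = forecast_arrays(cgm, schedule, params, cfg, fast=fast)
    g_fore, fused_g = out[0], out[1]
    steps = cfg.ph // cgm.m
    records: List[ForecastRecord] = []
    n = len(cgm)
    for j in range(WARMUP_SAMPLES - 1, n):
        tgt = j + steps
        obs = float(cgm.g[tgt]) if tgt < n else None
        records.append(
            ForecastRecord(
                t_min=float(cgm.t[j]),
                g_fused=float(fused_g[j]),
                g_forecast=float(g_fore[j]),
                g_observed=obs,
                observed_imputed=bool(cgm.imputed[tgt]) if tgt < n else False,
            )
        )
    return records


def forecast_arrays(
    cgm: CGMSeries,
    schedule: EventSchedule,
    params: PatientParameters,
    cfg: FusionConfig,
    fast: bool = True,
) -> Tuple[np.ndarray, ...]:
    """Array-valued cycle output ``(g_forecast, g_fused, ra_hat, ra_tilde,
    ra1_tilde, final_state)``; NaN where no forecast is produced."""
    ucho, uins, tmaxi, tmg, _ = _build_arrays(cgm, schedule, params, cfg)
    t = np.asarray(cgm.t, dtype=np.float64)
    g = np.asarray(cgm.g, dtype=np.float64)
    if fast:
        return _kernels.forecaster_kernel(
            g, t, params.to_vector(), params.tmax_g, ucho, uins, tmaxi, tmg,
            int(cfg.ph), float(cfg.q1), float(cfg.q2), 3, cfg.announce_meals,
        )
    return _reference_cycle(g, t, params, ucho, uins, tmaxi, tmg, cfg)


def _reference_cycle(g, t, params, ucho, uins, tmaxi, tmg, cfg):
    """Pure-Python composition of the cycle from the module operations."""
    n = g.size
    p = params.to_vector()
    g_fore = np.full(n, np.nan)
    fused_g = np.full(n, np.nan)
    ra_hat = np.zeros(n)
    ra_tilde = np.zeros(n)
    ra1_tilde = np.zeros(n)
    dec = Deconvolver(params)
    dec.observe(t[0], g[0])
    x = initialize(g[0]).as_array()
    t_off = t[0]
    for j in range(1, n):
        m_j = int(round(t[j] - t[j - 1]))
        t_prev = int(round(t[j - 1] - t_off))
        for s in range(m_j):
            tt = t_prev + s
            x = _py_step(x, p, ucho[tt], uins[tt], tmaxi[tt], tmg[tt], 1.0)
        est = dec.update(t[j], g[j], x[1])
        ra_hat[j], ra_tilde[j], ra1_tilde[j] = est.ra_hat, est.ra_tilde, est.ra1_tilde
        fused = fuse(ModelState.from_array(x), est, g[j], cfg)
        x = fused.as_array()
        fused_g[j] = x[0]
        if j >= WARMUP_SAMPLES - 1:
            xp = x.copy()
            t_j = int(round(t[j] - t_off))
            for s in range(cfg.ph):
                tt = t_j + s
                uc = ucho[tt] if cfg.announce_meals else 0.0
                xp = _py_step(xp, p, uc, uins[tt], tmaxi[tt], tmg[tt], 1.0)
            g_fore[j] = xp[0]
    return g_fore, fused_g, ra_hat, ra_tilde, ra1_tilde, x


def step_cycle(
    prev_state: ModelState,
    dec: Deconvolver,
    t_prev: float,
    t_now: float,
    cgm_now: float,
    schedule: EventSchedule,
    params: PatientParameters,
    cfg: FusionConfig,
) -> Tuple[ModelState, ForecastRecord]:
    """Single incremental cycle (online use): advance, deconvolve, fuse,
    propagate.  ``dec`` carries the CGM history; gaps must be imputed before
    calling."""
    m_j = int(round(t_now - t_prev))
    if m_j < 1:
        raise ValueError("CGM samples must advance in time")
    horizon = int(round(t_now)) + int(cfg.ph) + 1
    ucho, uins, tmaxi, tmg = schedule.to_input_arrays(
        params, horizon, use_classes=cfg.use_meal_classes
    )
    p = params.to_vector()
    x = prev_state.as_array()
    for s in range(m_j):
        tt = int(round(t_prev)) + s
        x = _py_step(x, p, ucho[tt], uins[tt], tmaxi[tt], tmg[tt], 1.0)
    est = dec.update(t_now, cgm_now, x[1])
    fused = fuse(ModelState.from_array(x), est, cgm_now, cfg)
    xp = fused.as_array().copy()
    for s in range(cfg.ph):
        tt = int(round(t_now)) + s
        uc = ucho[tt] if cfg.announce_meals else 0.0
        xp = _py_step(xp, p, uc, uins[tt], tmaxi[tt], tmg[tt], 1.0)
    record = ForecastRecord(
        t_min=float(t_now), g_fused=fused.g, g_forecast=float(xp[0])
    )
    return fused, record
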