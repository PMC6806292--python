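"""Composite minimal model of glucose-insulin dynamics.

The model couples three well-known compartmental blocks:

* Bergman's minimal model of glucose disappearance
  ``dG = -(SG + X) G + SG Gb + Ra/(V W)``, ``dX = -p2 X + p2 SI I``;
* Hovorka's two-compartment subcutaneous insulin absorption chain
  ``dS1 = uINS - S1/tmaxI``, ``dS2 = (S1 - S2)/tmaxI``,
  ``dI = -ke I + S2/(Vi W tmaxI)`` (converted to uU/mL);
* Hovorka's two-compartment gut absorption chain
  ``dRa1 = -(Ra1 - Ag uCHO)/tmaxG``, ``dRa = -(Ra - Ra1)/tmaxG``.

Meal absorption class (fast / medium / slow) shifts the gut time constant:
fast meals use ``tmaxG - tl``, slow meals ``tmaxG + td`` for the duration of
the meal's absorption.

Simulation uses a forward-Euler discretisation with a 1-min step; any state
driven negative by the discretisation is clamped to zero (the plasma-insulin
equation is stiff at this step size).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from . import _kernels
from .params import MG_PER_GRAM, MU_PER_UNIT, UU_PER_ML_PER_MU_PER_ML, PatientParameters

log = logging.getLogger(__name__)

MEAL_CLASSES = ("fast", "medium", "slow")
#: a meal's class shift applies from its start for at most this long (min)
MEAL_CLASS_WINDOW_MIN = 480


@dataclass
class ModelState:
    """State vector ``x = [G, X, S1, S2, I, Ra1, Ra]``.

    G plasma glucose (mg/dL), X insulin action (1/min), S1/S2 subcutaneous
    insulin compartments (mU), I plasma insulin (uU/mL), Ra1/Ra gut
    compartments (mg/min).
    """

    g: float
    x: float = 0.0
    s1: float = 0.0
    s2: float = 0.0
    i: float = 0.0
    ra1: float = 0.0
    ra: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.g, self.x, self.s1, self.s2, self.i, self.ra1, self.ra])

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "ModelState":
        return cls(*map(float, arr))

    def validate(self) -> None:
        arr = self.as_array()
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"non-finite model state: {arr}")
        if self.g <= 0:
            raise ValueError(f"glucose must be positive, got {self.g}")
        if np.any(arr[1:] < 0):
            raise ValueError(f"negative compartment in state: {arr}")


@dataclass
class ExogenousInput:
    """Inputs at one instant: carbohydrate (mg/min), insulin (mU/min), class."""

    u_cho: float = 0.0
    u_ins: float = 0.0
    abs_class: str = "none"

    def validate(self) -> None:
        if self.u_cho < 0 or self.u_ins < 0:
            raise ValueError("input rates must be non-negative")
        if self.abs_class not in MEAL_CLASSES + ("none",):
            raise ValueError(f"unknown absorption class {self.abs_class!r}")


@dataclass
class MealEvent:
    time_min: float
    grams: float
    abs_class: str = "medium"
    # per-meal kinetic perturbations, used by the virtual-patient truth only
    ag_scale: float = 1.0
    tmaxg_scale: float = 1.0


@dataclass
class Bolus:
    time_min: float
    units: float
    tmaxi_scale: float = 1.0


@dataclass
class BasalSegment:
    """Piecewise-constant basal insulin from ``start_min`` onward (U/h)."""

    start_min: float
    rate_u_per_h: float


@dataclass
class EventSchedule:
    """Time-indexed exogenous inputs over ``[0, horizon_min]``.

    Meals and boluses are delivered as single 1-min impulses (1 g -> 1000
    mg/min for one minute; 1 U -> 1000 mU/min for one minute); basal insulin
    is a piecewise-constant rate.
    """

    meals: List[MealEvent] = field(default_factory=list)
    boluses: List[Bolus] = field(default_factory=list)
    basal: List[BasalSegment] = field(default_factory=list)
    horizon_min: int = 0

    def validate(self) -> None:
        for ev in self.meals:
            if ev.grams < 0 or not 0 <= ev.time_min <= self.horizon_min:
                raise ValueError(f"invalid meal event {ev}")
            if ev.abs_class not in MEAL_CLASSES:
                raise ValueError(f"unknown meal class {ev.abs_class!r}")
        for b in self.boluses:
            if b.units < 0 or not 0 <= b.time_min <= self.horizon_min:
                raise ValueError(f"invalid bolus {b}")
        for seg in self.basal:
            if seg.rate_u_per_h < 0:
                raise ValueError(f"negative basal rate {seg}")

    def to_input_arrays(
        self,
        params: PatientParameters,
        n_minutes: Optional[int] = None,
        use_classes: bool = True,
        use_perturbations: bool = False,
    ) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Discretise to dense per-minute arrays ``(ucho, uins, tmaxi, tmg)``.

        ``use_classes=False`` treats every meal as medium absorption (the
        forecaster variant without meal-absorption information);
        ``use_perturbations=True`` additionally applies the per-event kinetic
        scale factors (virtual-patient ground truth).
        """
        n = int(n_minutes if n_minutes is not None else self.horizon_min)
        ucho = np.zeros(n)
        uins = np.zeros(n)
        tmaxi = np.full(n, params.tmax_i)
        tmg = np.full(n, params.tmax_g)

        # basal: piecewise constant, U/h -> mU/min
        for seg in sorted(self.basal, key=lambda s: s.start_min):
            start = max(0, int(round(seg.start_min)))
            if start < n:
                uins[start:] = seg.rate_u_per_h * MU_PER_UNIT / 60.0

        for b in self.boluses:
            t = int(round(b.time_min))
            if 0 <= t < n:
                uins[t] += b.units * MU_PER_UNIT
        if use_perturbations:
            for b in sorted(self.boluses, key=lambda e: e.time_min):
                t = max(0, int(round(b.time_min)))
                if t < n:
                    tmaxi[t:] = params.tmax_i * b.tmaxi_scale

        meals = sorted(self.meals, key=lambda e: e.time_min)
        for idx, ev in enumerate(meals):
            t = int(round(ev.time_min))
            if not 0 <= t < n:
                continue
            ag_scale = ev.ag_scale if use_perturbations else 1.0
            # bioavailability perturbation folded into the delivered dose
            ucho[t] += ev.grams * MG_PER_GRAM * ag_scale
            cls = ev.abs_class if use_classes else "medium"
            eff = effective_tmaxg(params, cls)
            if use_perturbations:
                eff *= ev.tmaxg_scale
            end = min(n, t + MEAL_CLASS_WINDOW_MIN)
            if idx + 1 < len(meals):
                nxt = int(round(meals[idx + 1].time_min))
                if nxt < end:
                    if meals[idx + 1].abs_class != ev.abs_class:
                        log.debug(
                            "overlapping meals with different classes at %s/%s min; "
                            "later meal's class wins from its start",
                            ev.time_min, meals[idx + 1].time_min,
                        )
                    end = nxt
            tmg[t:end] = eff
        return ucho, uins, tmaxi, tmg


def effective_tmaxg(params: PatientParameters, meal_class: str) -> float:
    """Meal-class-adjusted gut time constant (min).

    Fast meals absorb earlier (``tmaxG - tl``), slow meals later
    (``tmaxG + td``); medium meals use ``tmaxG`` unchanged.
    """
    if meal_class == "fast":
        eff = params.tmax_g - params.tl
    elif meal_class == "medium":
        eff = params.tmax_g
    elif meal_class == "slow":
        eff = params.tmax_g + params.td
    else:
        raise ValueError(f"unknown meal class {meal_class!r}")
    if eff <= 0:
        raise ValueError(f"effective tmax_g must be positive, got {eff}")
    return eff


def derivatives(
    state: ModelState, params: PatientParameters, inp: ExogenousInput
) -> ModelState:
    """Time derivative of the state under the composite model equations."""
    arr = state.as_array()
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"non-finite state: {arr}")
    inp.validate()
    tmg = effective_tmaxg(params, inp.abs_class) if inp.abs_class != "none" else params.tmax_g
    dg = -(params.sg + state.x) * state.g + params.sg * params.gb + state.ra / (params.v * params.w)
    dx = -params.p2 * state.x + params.p2 * params.si * state.i
    ds1 = inp.u_ins - state.s1 / params.tmax_i
    ds2 = (state.s1 - state.s2) / params.tmax_i
    di = -params.ke * state.i + UU_PER_ML_PER_MU_PER_ML * state.s2 / (
        params.vi * params.w * params.tmax_i
    )
    dra1 = -(state.ra1 - params.ag * inp.u_cho) / tmg
    dra = -(state.ra - state.ra1) / tmg
    return ModelState(dg, dx, ds1, ds2, di, dra1, dra)


def euler_step(
    state: ModelState,
    params: PatientParameters,
    inp: ExogenousInput,
    dt: float = 1.0,
) -> ModelState:
    """One forward-Euler step; negative results are clamped to zero."""
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    d = derivatives(state, params, inp)
    new = state.as_array() + dt * d.as_array()
    if np.any(new < 0):
        log.debug("clamping negative state components to 0: %s", new)
        new = np.maximum(new, 0.0)
    return ModelState.from_array(new)


def simulate(
    state0: ModelState,
    params: PatientParameters,
    schedule: EventSchedule,
    use_classes: bool = True,
    use_perturbations: bool = False,
) -> np.ndarray:
    """Integrate the model at 1-min resolution over the schedule horizon.

    Returns an ``(horizon+1, 7)`` trajectory with ``trajectory[0] = state0``.
    """
    n = int(schedule.horizon_min)
    if n < 1:
        raise ValueError("schedule horizon must be at least 1 min")
    schedule.validate()
    state0.validate()
    ucho, uins, tmaxi, tmg = schedule.to_input_arrays(
        params, n, use_classes=use_classes, use_perturbations=use_perturbations
    )
    return _kernels.simulate_kernel(
        state0.as_array(), params.to_vector(), ucho, uins, tmaxi, tmg, n, 1.0
    )
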