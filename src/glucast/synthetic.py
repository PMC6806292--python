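"""Virtual-patient cohort and scenario generator.

Ground truth is the composite model itself, driven with per-subject
parameters and per-event kinetic perturbations, so that the forecaster sees
realistic model mismatch without depending on a licensed simulator:

* inter-subject spread: insulin sensitivity drawn around 0.00275 +- 0.0014
  (truncated to the admissible box), absorption time constants within +-30%
  of the population value, bioavailability within +-10%;
* meal pattern: 70 g at 07:00, 100 g at 13:00, 80 g at 19:00, with +-20 min
  timing jitter (truncated Gaussian) and 10% size CV; the *logged*
  carbohydrate values are additionally corrupted by a Uniform(-30%, +20%)
  counting error while the true values drive the simulation;
* per-meal absorption-rate perturbation (+-30% on the rate, i.e. the gut time
  constant is divided by the factor) and +-10% bioavailability perturbation;
  per-bolus +-30% perturbation of the insulin absorption time constant;
* CGM: 5-min subsampling of the 1-min truth plus additive Gaussian sensor
  error with marginal SD 10 mg/dL and AR(1) autocorrelation 0.7 between
  consecutive samples (CGM error is strongly autocorrelated; white error
  would exaggerate the derivative noise the deconvolution sees), and random
  sensor gaps.

Boluses are computed from the *logged* carbohydrates with a carb-ratio rule
derived analytically from the subject's model constants (grams covered per
unit at a reference glucose), so carb-counting errors propagate into dosing
errors exactly as they would through a bolus calculator.  In this model the
basal state ``G = Gb`` is self-sustaining (endogenous production ``SG*Gb``
balances disposal at zero insulin), so the steady-state basal rate is zero.

The module also provides the meal-absorption classifier (share of the Ra
profile's area absorbed within two and four hours) and Akima-style gap
imputation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.interpolate import Akima1DInterpolator

from . import _kernels
from .model import Bolus, EventSchedule, MealEvent, ModelState, effective_tmaxg, simulate
from .params import (MG_PER_GRAM, MU_PER_UNIT, SI_BOUNDS, TMAXG_BOUNDS,
                     TMAXI_BOUNDS, UU_PER_ML_PER_MU_PER_ML, PatientParameters)
from .series import GLUCOSE_RANGE, CGMSeries

#: AUC-share thresholds of the meal-absorption classifier
FAST_AUC_2H = 0.60
SLOW_AUC_4H = 0.80


@dataclass
class RaProfile:
    """Rate-of-appearance profile of one meal (1-min grid)."""

    t: np.ndarray
    ra: np.ndarray
    grams: float


@dataclass
class MealSlot:
    """One daily meal: nominal clock time (min past midnight), grams, class."""

    time_min: float
    grams: float
    abs_class: str


DEFAULT_MEAL_PATTERN = (
    MealSlot(7 * 60, 70.0, "fast"),     # breakfast: fast absorption
    MealSlot(13 * 60, 100.0, "medium"),  # lunch: medium absorption
    MealSlot(19 * 60, 80.0, "medium"),   # dinner: medium absorption
)


@dataclass
class CohortConfig:
    """Study conditions of the virtual cohort."""

    n_subjects: int = 10
    base: PatientParameters = field(default_factory=PatientParameters)
    si_mean: float = 0.00275
    si_sd: float = 0.0014
    gb_mean: float = 120.0
    gb_sd: float = 10.0
    w_mean: float = 70.0
    w_sd: float = 10.0
    tmaxi_frac: float = 0.30
    tmaxg_frac: float = 0.30
    ag_frac: float = 0.10
    meal_pattern: Tuple[MealSlot, ...] = DEFAULT_MEAL_PATTERN
    meal_size_cv: float = 0.10
    meal_time_sd: float = 20.0
    meal_time_max: float = 60.0
    carb_err_low: float = -0.30
    carb_err_high: float = 0.20
    meal_kabs_frac: float = 0.30
    meal_ag_frac: float = 0.10
    bolus_tmaxi_frac: float = 0.30
    bolus_target_glucose: float = 140.0
    cgm_sigma: float = 10.0
    cgm_ar1: float = 0.7
    gap_rate_per_day: float = 0.5
    gap_dur_min: float = 15.0
    gap_dur_max: float = 60.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("si_sd", "gb_sd", "w_sd", "tmaxi_frac", "tmaxg_frac", "ag_frac",
                     "meal_size_cv", "meal_time_sd", "meal_kabs_frac", "meal_ag_frac",
                     "bolus_tmaxi_frac", "cgm_sigma", "gap_rate_per_day"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.carb_err_low > self.carb_err_high:
            raise ValueError("carb error support is empty")
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float) -> float:
    if lo >= hi:
        raise ValueError(f"empty admissible region [{lo}, {hi}]")
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    raise ValueError(f"could not sample within [{lo}, {hi}] around {mean} +- {sd}")


def sample_cohort(cfg: CohortConfig) -> List[PatientParameters]:
    """Draw per-subject true parameter sets (deterministic under the seed)."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    cohort = []
    base = cfg.base
    for _ in range(cfg.n_subjects):
        si = _truncnorm(rng, cfg.si_mean, cfg.si_sd, *SI_BOUNDS)
        tmaxi = base.tmax_i * rng.uniform(1 - cfg.tmaxi_frac, 1 + cfg.tmaxi_frac) \
            if cfg.tmaxi_frac else base.tmax_i
        tmaxg = base.tmax_g * rng.uniform(1 - cfg.tmaxg_frac, 1 + cfg.tmaxg_frac) \
            if cfg.tmaxg_frac else base.tmax_g
        ag = base.ag * rng.uniform(1 - cfg.ag_frac, 1 + cfg.ag_frac) if cfg.ag_frac else base.ag
        gb = _truncnorm(rng, cfg.gb_mean, cfg.gb_sd, 90.0, 160.0)
        w = _truncnorm(rng, cfg.w_mean, cfg.w_sd, 45.0, 110.0)
        cohort.append(base.replace(
            si=si,
            tmax_i=float(np.clip(tmaxi, *TMAXI_BOUNDS)),
            tmax_g=float(np.clip(tmaxg, *TMAXG_BOUNDS)),
            ag=float(np.clip(ag, 0.05, 1.0)),
            gb=gb, w=w,
        ))
    return cohort


def carb_ratio_g_per_unit(params: PatientParameters, g_ref: float = 140.0) -> float:
    """Carbohydrate grams covered by one insulin unit, from the model itself.

    Equates the integrated glucose forcing of one gram
    (``Ag * 1000 / (V W)`` mg/dL) with the integrated insulin-driven disposal
    of one unit at a reference glucose (``g_ref * SI * \\int I dt`` with
    ``\\int I dt = 1000 * 1000 / (ke Vi W)``).  Clinically typical magnitudes
    are not meaningful under the population constants of this composite
    model; the rule guarantees dosing that is consistent with the dynamics
    being simulated.
    """
    disposal_per_unit = g_ref * params.si * MU_PER_UNIT * UU_PER_ML_PER_MU_PER_ML / (
        params.ke * params.vi * params.w
    )
    forcing_per_gram = params.ag * MG_PER_GRAM / (params.v * params.w)
    return disposal_per_unit / forcing_per_gram


def generate_scenario(
    cfg: CohortConfig,
    days: int,
    params: PatientParameters,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[EventSchedule, EventSchedule]:
    """Sample one open-loop scenario: ``(true_schedule, logged_schedule)``.

    The true schedule carries the actually ingested carbohydrates and the
    per-event kinetic perturbations; the logged schedule carries the counted
    carbohydrates and the boluses computed from them, i.e. what the
    forecaster is allowed to see.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    horizon = days * 1440
    true_meals: List[MealEvent] = []
    logged_meals: List[MealEvent] = []
    boluses: List[Bolus] = []
    ratio = carb_ratio_g_per_unit(params, cfg.bolus_target_glucose)
    for day in range(days):
        for slot in cfg.meal_pattern:
            jitter = _truncnorm(rng, 0.0, cfg.meal_time_sd,
                                -cfg.meal_time_max, cfg.meal_time_max) \
                if cfg.meal_time_sd else 0.0
            t = day * 1440 + slot.time_min + jitter
            t = float(np.clip(t, 0, horizon - 1))
            true_g = slot.grams * max(0.05, 1.0 + cfg.meal_size_cv * rng.standard_normal())
            logged_g = true_g * (1.0 + rng.uniform(cfg.carb_err_low, cfg.carb_err_high))
            kabs_fac = rng.uniform(1 - cfg.meal_kabs_frac, 1 + cfg.meal_kabs_frac)
            ag_fac = rng.uniform(1 - cfg.meal_ag_frac, 1 + cfg.meal_ag_frac)
            true_meals.append(MealEvent(
                t, true_g, slot.abs_class,
                ag_scale=ag_fac, tmaxg_scale=1.0 / kabs_fac,
            ))
            logged_meals.append(MealEvent(t, logged_g, slot.abs_class))
            tmaxi_fac = rng.uniform(1 - cfg.bolus_tmaxi_frac, 1 + cfg.bolus_tmaxi_frac)
            units = round(logged_g / ratio, 2)
            boluses.append(Bolus(t, units, tmaxi_scale=1.0 / tmaxi_fac))
    true_sched = EventSchedule(meals=true_meals, boluses=boluses, horizon_min=horizon)
    logged_sched = EventSchedule(
        meals=logged_meals,
        boluses=[Bolus(b.time_min, b.units) for b in boluses],
        horizon_min=horizon,
    )
    return true_sched, logged_sched


def generate_cgm(
    trajectory_g: np.ndarray,
    cfg: CohortConfig,
    rng: Optional[np.random.Generator] = None,
    m: int = 5,
) -> CGMSeries:
    """Sample a CGM series from a 1-min truth trajectory: subsample, add
    (optionally AR(1)) noise, and delete random gap windows."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    g_true = np.asarray(trajectory_g, dtype=float)
    t = np.arange(0, g_true.size, m, dtype=float)
    g = g_true[t.astype(int)].copy()
    if cfg.cgm_sigma > 0:
        z = rng.standard_normal(t.size)
        if cfg.cgm_ar1 > 0:
            e = np.empty(t.size)
            e[0] = z[0]
            c = np.sqrt(1.0 - cfg.cgm_ar1 ** 2)
            for k in range(1, t.size):
                e[k] = cfg.cgm_ar1 * e[k - 1] + c * z[k]
            z = e
        g = g + cfg.cgm_sigma * z
    g = np.clip(g, *GLUCOSE_RANGE)
    keep = np.ones(t.size, dtype=bool)
    days = g_true.size / 1440.0
    n_gaps = rng.poisson(cfg.gap_rate_per_day * days) if cfg.gap_rate_per_day > 0 else 0
    for _ in range(n_gaps):
        dur = rng.uniform(cfg.gap_dur_min, cfg.gap_dur_max)
        n_miss = max(1, int(round(dur / m)))
        start = rng.integers(1, max(2, t.size - n_miss - 1))
        keep[start:start + n_miss] = False
    keep[0] = keep[-1] = True  # keep boundaries so imputation can anchor
    return CGMSeries(t[keep], g[keep], np.zeros(int(keep.sum()), dtype=bool), m)


def impute_gaps(cgm: CGMSeries) -> CGMSeries:
    """Fill missing grid samples by modified-Akima cubic Hermite interpolation.

    Original samples are untouched; filled samples carry the imputed flag.
    """
    t0, t1 = cgm.t[0], cgm.t[-1]
    grid = np.arange(t0, t1 + 1, cgm.m, dtype=float)
    present = np.isin(grid, cgm.t)
    if present.all():
        return CGMSeries(grid, cgm.g.copy(), cgm.imputed.copy(), cgm.m)
    if len(cgm) < 2:
        raise ValueError("cannot impute a series with fewer than 2 samples")
    interp = Akima1DInterpolator(cgm.t, cgm.g, method="makima")
    g = np.empty(grid.size)
    imputed = np.zeros(grid.size, dtype=bool)
    g[present] = cgm.g
    imputed[present] = cgm.imputed
    g[~present] = np.clip(interp(grid[~present]), *GLUCOSE_RANGE)
    imputed[~present] = True
    return CGMSeries(grid, g, imputed, cgm.m)


def make_ra_profile(
    meal_class: str,
    grams: float,
    params: Optional[PatientParameters] = None,
    tmaxg_scale: float = 1.0,
) -> RaProfile:
    """Impulse response of the gut chain for one meal.

    ``Ra(t) = D Ag t exp(-t/tau) / tau^2`` with ``tau`` the class-adjusted
    gut time constant; the AUC equals ``Ag * grams * 1000`` mg.
    """
    if grams <= 0:
        raise ValueError("grams must be positive")
    params = params or PatientParameters()
    tau = effective_tmaxg(params, meal_class) * tmaxg_scale
    t_end = int(np.ceil(12 * tau))
    t = np.arange(0, t_end + 1, dtype=float)
    dose = grams * MG_PER_GRAM * params.ag
    ra = dose * t * np.exp(-t / tau) / tau ** 2
    return RaProfile(t=t, ra=ra, grams=grams)


def classify_meal(profile: RaProfile) -> str:
    """Classify a meal by the share of Ra area within two and four hours."""
    total = float(np.trapezoid(profile.ra, profile.t))
    if total <= 0:
        raise ValueError("profile has zero area under the curve")

    def frac(minutes: float) -> float:
        sel = profile.t <= minutes
        if sel.sum() < 2:
            return 0.0
        return float(np.trapezoid(profile.ra[sel], profile.t[sel])) / total

    if frac(120.0) > FAST_AUC_2H:
        return "fast"
    if frac(240.0) < SLOW_AUC_4H:
        return "slow"
    return "medium"


@dataclass
class SubjectDataset:
    """Everything generated for one virtual subject."""

    params: PatientParameters
    true_schedule: EventSchedule
    logged_schedule: EventSchedule
    truth: np.ndarray         # (minutes+1, 7) state trajectory
    cgm: CGMSeries            # with gaps
    cgm_imputed: CGMSeries    # regular grid


def generate_subject_dataset(
    params: PatientParameters,
    cfg: CohortConfig,
    days: int,
    rng: np.random.Generator,
) -> SubjectDataset:
    """Simulate one subject end to end: scenario, truth, CGM, imputation."""
    true_sched, logged_sched = generate_scenario(cfg, days, params, rng)
    x0 = ModelState(g=params.gb)
    truth = simulate(x0, params, true_sched, use_classes=True, use_perturbations=True)
    cgm = generate_cgm(truth[:, 0], cfg, rng)
    return SubjectDataset(
        params=params,
        true_schedule=true_sched,
        logged_schedule=logged_sched,
        truth=truth,
        cgm=cgm,
        cgm_imputed=impute_gaps(cgm),
    )
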