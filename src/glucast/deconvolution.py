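"""Real-time estimation of the gut states from the CGM signal.

The glucose rate of appearance is recovered by inverting the minimal-model
glucose balance at the sensor:

``Ra_hat(k) = [G'_cgm(k) + (SG + X(k)) G_cgm(k) - SG Gb] V W``

with the CGM derivative taken as the OLS slope of three consecutive samples,
bounded to +-1 mg/dL/min against sensor noise.  A recursive moving-average
filter then smooths ``Ra_hat``; the first gut compartment follows from the
filtered signal and its slope:

``Ra1_tilde(k) = Ra_tilde'(k) tmaxG + Ra_tilde(k)``.

The raw estimate may legitimately be negative (the balance equation has no
floor); non-negativity is enforced only on the filtered outputs so the filter
stays linear.  The filter recursion runs on the unfloored values; the
reported/fused signals are floored at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np

from .params import PatientParameters

#: CGM derivative bound, mg/dL per min
DERIVATIVE_BOUND = 1.0
#: default moving-average window, in samples
DEFAULT_FILTER_WINDOW = 3


@dataclass
class RaEstimate:
    """Deconvolution output at one CGM sample (all in mg/min)."""

    ra_hat: float
    ra_tilde: float
    ra1_tilde: float
    n: int = DEFAULT_FILTER_WINDOW


def _ols_slope(times: np.ndarray, values: np.ndarray) -> float:
    tm = times.mean()
    den = float(((times - tm) ** 2).sum())
    return float(((times - tm) * (values - values.mean())).sum() / den)


def bounded_derivative(times: Sequence[float], values: Sequence[float]) -> float:
    """Bounded OLS slope of up to three consecutive CGM samples (mg/dL/min).

    With fewer than three samples (start-up) the slope falls back to a
    two-point difference, then zero.  Real timestamps are used so imputed
    5-min grids and irregular spacing are handled alike.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape or t.ndim != 1 or t.size > 3:
        raise ValueError("expected up to three paired (time, value) samples")
    if t.size >= 2 and np.unique(t).size != t.size:
        raise ValueError("duplicate timestamps in derivative window")
    if t.size <= 1:
        return 0.0
    if t.size == 2:
        slope = float((y[1] - y[0]) / (t[1] - t[0]))
    else:
        slope = _ols_slope(t, y)
    return float(np.clip(slope, -DERIVATIVE_BOUND, DERIVATIVE_BOUND))


def estimate_ra(
    cgm_value: float,
    cgm_slope: float,
    x_action: float,
    params: PatientParameters,
) -> float:
    """Raw rate-of-appearance estimate (mg/min); may be negative."""
    if not np.all(np.isfinite([cgm_value, cgm_slope, x_action])):
        raise ValueError("non-finite deconvolution input")
    return (
        cgm_slope + (params.sg + x_action) * cgm_value - params.sg * params.gb
    ) * params.v * params.w


def moving_average(prev_filtered: Sequence[float], raw: float, n: int = DEFAULT_FILTER_WINDOW) -> float:
    """Recursive moving average: mean of the last ``n-1`` *filtered* values
    and the current raw estimate.  Missing start-up history counts as zero."""
    if n < 1:
        raise ValueError(f"filter window must be >= 1, got {n}")
    hist = list(prev_filtered)[-(n - 1):] if n > 1 else []
    return (sum(hist) + raw) / n


def estimate_ra1(
    times: Sequence[float],
    filtered_values: Sequence[float],
    tmax_g: float,
) -> float:
    """First-compartment estimate from the filtered series (floored at 0)."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(filtered_values, dtype=float)
    if t.size == 0:
        raise ValueError("empty filtered series")
    if t.size == 1:
        slope = 0.0
    elif t.size == 2:
        slope = float((y[1] - y[0]) / (t[1] - t[0]))
    else:
        slope = _ols_slope(t[-3:], y[-3:])
    return max(0.0, slope * tmax_g + float(y[-1]))


@dataclass
class Deconvolver:
    """Stateful three-step estimator fed one CGM sample at a time."""

    params: PatientParameters
    n: int = DEFAULT_FILTER_WINDOW
    _times: List[float] = field(default_factory=list)
    _values: List[float] = field(default_factory=list)
    _filt_times: List[float] = field(default_factory=list)
    _filt_raw: List[float] = field(default_factory=list)
    _filt: List[float] = field(default_factory=list)

    def observe(self, time_min: float, cgm_value: float) -> None:
        """Record a CGM sample without producing an estimate (start-up)."""
        self._times.append(time_min)
        self._values.append(cgm_value)

    def update(self, time_min: float, cgm_value: float, x_action: float) -> RaEstimate:
        self._times.append(time_min)
        self._values.append(cgm_value)
        slope = bounded_derivative(self._times[-3:], self._values[-3:])
        raw = estimate_ra(cgm_value, slope, x_action, self.params)
        filt_unfloored = moving_average(self._filt_raw, raw, self.n)
        self._filt_raw.append(filt_unfloored)
        filt = max(0.0, filt_unfloored)
        self._filt_times.append(time_min)
        self._filt.append(filt)
        ra1 = estimate_ra1(self._filt_times[-3:], self._filt[-3:], self.params.tmax_g)
        return RaEstimate(ra_hat=raw, ra_tilde=filt, ra1_tilde=ra1, n=self.n)

    def series(self) -> np.ndarray:
        """Filtered estimate history (floored), for diagnostics."""
        return np.asarray(self._filt)
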