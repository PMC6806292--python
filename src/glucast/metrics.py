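"""Forecast evaluation: RMSE, error-grid analysis, hypoglycaemia prediction.

The error grid classifies each (forecast, observation) pair into clinical
regions A-E with a fixed precedence A -> E -> D -> C -> B (the rule list
overlaps; B is the residual "benign error" region, and a forecast inside
the 70-180 target band with an out-of-band observation is a detection
failure, region D, even when it also lies 100 mg/dL below the
observation):

* A: |error| <= 20% of the observation, or both values <= 70 mg/dL;
* E: forecast indicates hypo while the observation indicates hyper, or the
  reverse;
* D: forecast in the 70-180 target band while the observation is outside it;
* C: forecast at least 100 mg/dL below the observation, or forecast <= 70
  while the observation lies in [130, 180];
* B: everything else.

Hypoglycaemia prediction is scored on events -- maximal runs of at least
three consecutive samples below 70 mg/dL -- compared sample-wise between the
forecast and observation series, summarised by the Matthews correlation
coefficient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

HYPO_THRESHOLD = 70.0
HYPER_THRESHOLD = 180.0
#: minimum run length (samples) constituting a hypoglycaemic event
HYPO_MIN_RUN = 3

EGA_REGIONS = ("A", "B", "C", "D", "E")


@dataclass
class HypoEvent:
    """Maximal run of >= 3 consecutive samples below 70 mg/dL."""

    start: int
    end: int  # inclusive

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class MetricsReport:
    """Per-horizon evaluation summary."""

    ph: int
    n: int
    rmse: float
    ega: Dict[str, float]
    tp: int
    fp: int
    tn: int
    fn: int
    mcc: float

    def to_dict(self) -> dict:
        d = {"ph": self.ph, "n": self.n, "rmse": self.rmse, "mcc": self.mcc,
             "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn}
        d.update({f"ega_{r.lower()}": self.ega[r] for r in EGA_REGIONS})
        return d


def rmse(forecasts: Sequence[float], observations: Sequence[float]) -> float:
    """Root mean squared forecast error (mg/dL)."""
    f = np.asarray(forecasts, dtype=float)
    o = np.asarray(observations, dtype=float)
    if f.size == 0 or f.shape != o.shape:
        raise ValueError("need at least one matched (forecast, observation) pair")
    return float(np.sqrt(np.mean((f - o) ** 2)))


def ega_region(forecast: float, observation: float) -> str:
    """Error-grid region of one (forecast, observation) pair."""
    if forecast <= 0 or observation <= 0:
        raise ValueError("glucose values must be positive")
    err = abs(forecast - observation)
    if err <= 0.2 * observation or (forecast <= HYPO_THRESHOLD and observation <= HYPO_THRESHOLD):
        return "A"
    if (forecast <= HYPO_THRESHOLD and observation >= HYPER_THRESHOLD) or (
        forecast >= HYPER_THRESHOLD and observation <= HYPO_THRESHOLD
    ):
        return "E"
    if HYPO_THRESHOLD <= forecast <= HYPER_THRESHOLD and (
        observation < HYPO_THRESHOLD or observation > HYPER_THRESHOLD
    ):
        return "D"
    if forecast <= observation - 100.0 or (
        forecast <= HYPO_THRESHOLD and 130.0 <= observation <= HYPER_THRESHOLD
    ):
        return "C"
    return "B"


def ega_summary(
    forecasts: Sequence[float], observations: Sequence[float]
) -> Dict[str, float]:
    """Percentage of pairs in each error-grid region (sums to 100)."""
    f = np.asarray(forecasts, dtype=float)
    o = np.asarray(observations, dtype=float)
    if f.size == 0:
        raise ValueError("need at least one matched pair")
    counts = {r: 0 for r in EGA_REGIONS}
    for fi, oi in zip(f, o):
        counts[ega_region(fi, oi)] += 1
    return {r: 100.0 * counts[r] / f.size for r in EGA_REGIONS}


def detect_hypo_events(series: Sequence[float]) -> List[HypoEvent]:
    """Maximal runs of at least three consecutive values below 70 mg/dL."""
    g = np.asarray(series, dtype=float)
    events: List[HypoEvent] = []
    start = None
    for i, v in enumerate(g):
        if v < HYPO_THRESHOLD:
            if start is None:
                start = i
        else:
            if start is not None and i - start >= HYPO_MIN_RUN:
                events.append(HypoEvent(start, i - 1))
            start = None
    if start is not None and g.size - start >= HYPO_MIN_RUN:
        events.append(HypoEvent(start, g.size - 1))
    return events


def _event_mask(series: Sequence[float]) -> np.ndarray:
    mask = np.zeros(len(series), dtype=bool)
    for ev in detect_hypo_events(series):
        mask[ev.start:ev.end + 1] = True
    return mask


def hypo_confusion(
    forecasts: Sequence[float],
    observations: Sequence[float],
    event_level: bool = False,
) -> Tuple[int, int, int, int]:
    """Confusion counts ``(TP, FP, TN, FN)`` for hypoglycaemia prediction.

    Default is sample-level counting of in-event indicators; with
    ``event_level=True`` whole events are matched (any overlap counts as a
    true positive) and TN counts event-free samples.
    """
    f = np.asarray(forecasts, dtype=float)
    o = np.asarray(observations, dtype=float)
    if f.shape != o.shape or f.ndim != 1:
        raise ValueError("forecast and observation series must be aligned 1-D arrays")
    pred = _event_mask(f)
    act = _event_mask(o)
    if not event_level:
        tp = int(np.sum(pred & act))
        fp = int(np.sum(pred & ~act))
        tn = int(np.sum(~pred & ~act))
        fn = int(np.sum(~pred & act))
        return tp, fp, tn, fn
    pred_events = detect_hypo_events(f)
    act_events = detect_hypo_events(o)
    tp = sum(1 for e in act_events if pred[e.start:e.end + 1].any())
    fn = len(act_events) - tp
    fp = sum(1 for e in pred_events if not act[e.start:e.end + 1].any())
    tn = int(np.sum(~pred & ~act))
    return tp, fp, tn, fn


def mcc(tp: int, tn: int, fp: int, fn: int) -> float:
    """Matthews correlation coefficient; 0 when a denominator factor is 0."""
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def evaluate_forecasts(
    forecasts: Sequence[float],
    observations: Sequence[float],
    ph: int,
    imputed: Optional[Sequence[bool]] = None,
    event_level: bool = False,
) -> MetricsReport:
    """Full report for one horizon.

    RMSE and the error grid are computed on measured observations only
    (imputed samples excluded); hypoglycaemia events are detected on the full
    aligned series so that runs are not broken by exclusions.
    """
    f = np.asarray(forecasts, dtype=float)
    o = np.asarray(observations, dtype=float)
    keep = np.ones(f.size, dtype=bool) if imputed is None else ~np.asarray(imputed, dtype=bool)
    if not np.any(keep):
        raise ValueError("no measured observations to evaluate")
    err = rmse(f[keep], o[keep])
    ega = ega_summary(f[keep], o[keep])
    tp, fp, tn, fn = hypo_confusion(f, o, event_level=event_level)
    return MetricsReport(
        ph=ph, n=int(np.sum(keep)), rmse=err, ega=ega,
        tp=tp, fp=fp, tn=tn, fn=fn, mcc=mcc(tp, tn, fp, fn),
    )


def evaluate_records(records, ph: int, event_level: bool = False) -> MetricsReport:
    """Report from :class:`~glucast.forecaster.ForecastRecord` objects with a
    matched observation."""
    matched = [r for r in records if r.g_observed is not None]
    if not matched:
        raise ValueError("no records with matched observations")
    return evaluate_forecasts(
        [r.g_forecast for r in matched],
        [r.g_observed for r in matched],
        ph=ph,
        imputed=[r.observed_imputed for r in matched],
        event_level=event_level,
    )
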