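"""Cohort benchmark: simulate, identify, forecast, evaluate.

Reproduces the study layout: a two-week open-loop scenario per subject, the
first week used to identify the physiological model (and to fit the ARX
baseline), the second week for testing.  The physiological forecaster is run
with fusion weights 0.7/0.7 at test time (0.5/0.5 during identification);
``pm`` ignores meal-absorption classes, ``pmma`` uses them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .baselines import arx_forecast_series, fit_arx
from .forecaster import FusionConfig, run_forecaster
from .identification import (IdentificationSpec, estimate_basal_glucose,
                             identify)
from .metrics import MetricsReport, evaluate_forecasts, evaluate_records
from .params import PatientParameters
from .series import CGMSeries
from .synthetic import CohortConfig, generate_subject_dataset, sample_cohort

log = logging.getLogger(__name__)

TEST_FUSION_WEIGHT = 0.7
DEFAULT_HORIZONS = (30, 60, 90, 120)
METHODS = ("pm", "pmma", "arx")


@dataclass
class BenchmarkConfig:
    """Settings of one cohort benchmark run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    days: int = 14
    train_days: int = 7
    horizons: Tuple[int, ...] = DEFAULT_HORIZONS
    methods: Tuple[str, ...] = ("pm", "arx")
    event_level: bool = False

    def validate(self) -> None:
        if not 0 < self.train_days < self.days:
            raise ValueError("train/test split requires 0 < train_days < days")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods {sorted(unknown)}")


def _split_weeks(cgm: CGMSeries, split_min: float) -> Tuple[CGMSeries, CGMSeries]:
    return cgm.window(cgm.t[0], split_min), cgm.window(split_min, cgm.t[-1] + 1)


def run_benchmark(cfg: BenchmarkConfig) -> pd.DataFrame:
    """Per-subject, per-method, per-horizon metrics table."""
    cfg.validate()
    cohort = sample_cohort(cfg.cohort)
    rng = np.random.default_rng(cfg.cohort.seed + 1)
    rows: List[dict] = []
    for subj, true_params in enumerate(cohort):
        data = generate_subject_dataset(true_params, cfg.cohort, cfg.days, rng)
        split = cfg.train_days * 1440
        train, test = _split_weeks(data.cgm_imputed, split)
        schedule = data.logged_schedule

        # a-priori subject information: weight known, basal glucose from
        # overnight training CGM
        fixed = PatientParameters(
            w=true_params.w, gb=estimate_basal_glucose(train)
        )

        for ph in cfg.horizons:
            for method in cfg.methods:
                if method in ("pm", "pmma"):
                    use_classes = method == "pmma"
                    ident = identify(IdentificationSpec(
                        cgm=train, schedule=schedule, fixed=fixed, ph=ph,
                        use_meal_classes=use_classes,
                    ))
                    test_cfg = FusionConfig(
                        q1=TEST_FUSION_WEIGHT, q2=TEST_FUSION_WEIGHT, ph=ph,
                        use_meal_classes=use_classes,
                    )
                    records = run_forecaster(test, schedule, ident.params, test_cfg)
                    report = evaluate_records(records, ph, event_level=cfg.event_level)
                    extra = {"si": ident.si, "tmax_i": ident.tmax_i,
                             "tmax_g": ident.tmax_g, "train_mard": ident.mard}
                elif method == "arx":
                    model = fit_arx(train, schedule)
                    fore = arx_forecast_series(model, test, schedule, ph=ph)
                    steps = ph // test.m
                    idx = np.arange(len(test))
                    anchors = idx[(idx >= 2) & (idx + steps < len(test))]
                    anchors = anchors[np.isfinite(fore[anchors])]
                    report = evaluate_forecasts(
                        fore[anchors], test.g[anchors + steps], ph,
                        imputed=test.imputed[anchors + steps],
                        event_level=cfg.event_level,
                    )
                    extra = {}
                row = {"subject": subj, "method": method, **report.to_dict(), **extra}
                rows.append(row)
                log.info("subject %d %s PH=%d: RMSE=%.2f MCC=%.3f",
                         subj, method, ph, report.rmse, report.mcc)
    return pd.DataFrame(rows)


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Cohort mean +- STD per method and horizon (Table-style summary)."""
    cols = ["rmse", "mcc", "ega_a", "ega_b", "ega_c", "ega_d", "ega_e"]
    grouped = table.groupby(["method", "ph"])[cols]
    mean = grouped.mean().add_suffix("_mean")
    std = grouped.std(ddof=1).add_suffix("_std")
    return mean.join(std).reset_index()
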