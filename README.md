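# glucast

Long-term blood-glucose forecasting for type 1 diabetes from continuous
glucose monitoring (CGM), insulin and meal records, using a physiological
model whose gastrointestinal states are estimated in real time by
deconvolution of the CGM signal.

Forecasting glucose 30 min ahead is largely a solved problem; horizons of
90-120 min — the ones insulin-dosing decision support and closed-loop
control actually need — are not, because data-driven predictors revert to
the mean long before meal and insulin dynamics have played out.  This
package targets those long horizons and is aimed at researchers working on
glucose prediction, predictive alarms and insulin decision support.

## Method

The core is a composite compartmental model with state
`x = [G, X, S1, S2, I, Ra1, Ra]`: Bergman's minimal model of glucose
disappearance,

```
dG/dt = -(SG + X) G + SG·Gb + Ra/(V·W),      dX/dt = -p2·X + p2·SI·I,
```

coupled to Hovorka's two-compartment subcutaneous-insulin chain
(`S1, S2 -> I`, time constant `tmaxI`, decay `ke`) and gut-absorption chain
(`Ra1 -> Ra`, time constant `tmaxG`, bioavailability `Ag`).  Every time a
CGM sample arrives, the model is advanced to the present, the gut states
are re-estimated from the sensor by inverting the glucose balance

```
Ra_hat(k) = [G'cgm(k) + (SG + X(k))·Gcgm(k) - SG·Gb]·V·W
```

(three-point regression derivative bounded to ±1 mg/dL/min, recursive
moving-average filter, floor at zero), and model and deconvolution are
fused by fixed weights `Q1` (gut states) and `Q2` (glucose) before the
fused state is propagated open-loop to the prediction horizon.  Meals can
optionally carry a fast/medium/slow absorption class that shifts `tmaxG`
by ∓20 min for the duration of that meal.

Around the core the package provides subject-specific identification of
`(SI, tmaxI, tmaxG)` by constrained MARD minimisation, a third-order ARX
baseline, the evaluation suite (RMSE, error-grid regions A-E,
hypoglycaemia-event confusion and MCC), and a seeded virtual-patient
generator (open-loop two-week scenarios with meal variability,
carb-counting error, kinetic perturbations, autocorrelated CGM noise and
sensor gaps) so the entire pipeline runs and is tested without clinical
data.  See `docs/methods.md` for assumptions, defaults and known
limitations.

## Worked example

Generate a virtual subject, identify the model on week 1, forecast week 2
at a 120-min horizon:

```python
import numpy as np
import glucast
from glucast import CohortConfig, FusionConfig, PatientParameters
from glucast.identification import (IdentificationSpec,
                                    estimate_basal_glucose, identify)
from glucast.metrics import evaluate_records
from glucast.synthetic import generate_subject_dataset, sample_cohort

cfg = CohortConfig(n_subjects=1, seed=7)
subject = sample_cohort(cfg)[0]
data = generate_subject_dataset(subject, cfg, days=14,
                                rng=np.random.default_rng(8))

train = data.cgm_imputed.window(0, 7 * 1440)
test = data.cgm_imputed.window(7 * 1440, data.cgm_imputed.t[-1] + 1)

fixed = PatientParameters(w=subject.w, gb=estimate_basal_glucose(train))
result = identify(IdentificationSpec(cgm=train, schedule=data.logged_schedule,
                                     fixed=fixed, ph=120))
print(f"identified SI={result.si:.5f}, tmaxI={result.tmax_i:.1f} min, "
      f"tmaxG={result.tmax_g:.1f} min (training MARD {result.mard:.1f}%)")

records = glucast.run_forecaster(test, data.logged_schedule, result.params,
                                 FusionConfig(q1=0.7, q2=0.7, ph=120))
report = evaluate_records(records, ph=120)
print(f"test week, PH=120: RMSE {report.rmse:.1f} mg/dL, "
      f"EGA A {report.ega['A']:.1f}%, hypoglycaemia MCC {report.mcc:.2f}")
```

Output:

```
identified SI=0.00340, tmaxI=140.0 min, tmaxG=79.9 min (training MARD 18.6%)
test week, PH=120: RMSE 35.5 mg/dL, EGA A 53.3%, hypoglycaemia MCC 0.13
```

The identified values minimise two-hour-ahead forecast error on the
training week (they are forecast parameters, not unbiased physiological
estimates — `tmaxI` drifting toward the slow end of its admissible box is
characteristic, see `docs/methods.md`).  On the held-out week, a
two-hour-ahead RMSE of ~35 mg/dL with half the forecasts in the error
grid's clinically-accurate A region and a positive hypoglycaemia MCC means
the forecaster still carries usable meal/insulin information at a horizon
where autoregressive baselines have decayed to the mean (the ARX
comparator scores MCC ≈ 0 there).

The same workflow is available from the shell:

```sh
glucast simulate --subjects 10 --days 14 --seed 42 --out-dir data/
glucast identify --cgm data/subject00_cgm.csv --events data/subject00_events.csv \
                 --ph 120 --out params.yaml
glucast forecast --cgm data/subject00_cgm.csv --events data/subject00_events.csv \
                 --params params.yaml --ph 120 --out forecasts.csv
glucast evaluate --forecasts forecasts.csv --out report.json
glucast benchmark --subjects 10 --ph 30,60,90,120 --methods pm,arx --out table.csv
```

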