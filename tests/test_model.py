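"""Composite model: derivatives, Euler integration, meal-class shifts."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import glucast
from glucast import (EventSchedule, ExogenousInput, MealEvent, Bolus,
                     ModelState, PatientParameters, derivatives,
                     effective_tmaxg, euler_step, simulate)
from glucast.params import UU_PER_ML_PER_MU_PER_ML


def basal_state(p):
    return ModelState(g=p.gb)


class TestDerivatives:
    def test_basal_steady_state_has_zero_derivatives(self, default_params):
        d = derivatives(basal_state(default_params), default_params, ExogenousInput())
        assert np.allclose(d.as_array(), 0.0)

    def test_gut_chain_balance(self, default_params):
        # equal compartments: second gut equation balances exactly
        s = ModelState(g=120.0, ra1=50.0, ra=50.0)
        d = derivatives(s, default_params, ExogenousInput())
        assert d.ra == 0.0

    def test_matches_independent_hand_evaluation(self):
        # population constants; state and input chosen arbitrarily
        p = PatientParameters(sg=0.02, ke=1.5, p2=0.02, ag=0.85, v=0.9, vi=1.2,
                              si=0.003, gb=110.0, w=70.0, tmax_i=80.0, tmax_g=70.0)
        s = ModelState(g=150.0, x=0.01, s1=200.0, s2=100.0, i=5.0, ra1=80.0, ra=40.0)
        inp = ExogenousInput(u_cho=60000.0, u_ins=300.0, abs_class="medium")
        d = derivatives(s, p, inp)
        # independent evaluation, written out term by term
        expected = [
            -(0.02 + 0.01) * 150.0 + 0.02 * 110.0 + 40.0 / (0.9 * 70.0),
            -0.02 * 0.01 + 0.02 * 0.003 * 5.0,
            300.0 - 200.0 / 80.0,
            (200.0 - 100.0) / 80.0,
            -1.5 * 5.0 + UU_PER_ML_PER_MU_PER_ML * 100.0 / (1.2 * 70.0 * 80.0),
            -(80.0 - 0.85 * 60000.0) / 70.0,
            -(40.0 - 80.0) / 70.0,
        ]
        np.testing.assert_allclose(d.as_array(), expected, rtol=1e-12)

    def test_nonfinite_state_rejected(self, default_params):
        s = ModelState(g=np.nan)
        with pytest.raises(ValueError):
            derivatives(s, default_params, ExogenousInput())


class TestEffectiveTmaxg:
    @pytest.mark.parametrize("cls,expected", [
        ("fast", 65.0), ("medium", 85.0), ("slow", 105.0),
    ])
    def test_class_shifts(self, cls, expected):
        p = PatientParameters(tmax_g=85.0)
        assert effective_tmaxg(p, cls) == expected

    def test_nonpositive_result_rejected(self):
        p = PatientParameters()
        p.tl = 70.0  # mutate past construction-time validation
        with pytest.raises(ValueError):
            effective_tmaxg(p, "fast")

    def test_unknown_class_rejected(self, default_params):
        with pytest.raises(ValueError):
            effective_tmaxg(default_params, "instant")


class TestEulerStep:
    def test_steady_state_fixed_point(self, default_params):
        s = basal_state(default_params)
        s2 = euler_step(s, default_params, ExogenousInput())
        np.testing.assert_array_equal(s.as_array(), s2.as_array())

    def test_meal_impulse_enters_first_compartment_only(self, default_params):
        s = basal_state(default_params)
        inp = ExogenousInput(u_cho=60000.0, abs_class="medium")
        s2 = euler_step(s, default_params, inp, dt=1.0)
        expected_ra1 = default_params.ag * 60000.0 / default_params.tmax_g
        assert s2.ra1 == pytest.approx(expected_ra1)
        assert s2.ra == 0.0

    def test_dt_must_be_positive(self, default_params):
        with pytest.raises(ValueError):
            euler_step(basal_state(default_params), default_params,
                       ExogenousInput(), dt=0.0)


class TestSimulate:
    def test_steady_state_held_for_24h(self, default_params):
        sched = EventSchedule(horizon_min=1440)
        traj = simulate(basal_state(default_params), default_params, sched)
        assert traj.shape == (1441, 7)
        assert np.max(np.abs(traj[:, 0] - default_params.gb)) < 1e-9

    def test_fast_meal_ra_peaks_before_slow(self, default_params):
        for cls, other in (("fast", "slow"),):
            t_peak = {}
            for c in (cls, other):
                sched = EventSchedule(meals=[MealEvent(10, 60, c)], horizon_min=600)
                traj = simulate(basal_state(default_params), default_params, sched)
                t_peak[c] = int(np.argmax(traj[:, 6]))
            assert t_peak[cls] < t_peak[other]

    def test_bolus_without_meal_depresses_glucose(self, default_params):
        sched = EventSchedule(boluses=[Bolus(10, 0.5)], horizon_min=720)
        traj = simulate(basal_state(default_params), default_params, sched)
        assert traj[:, 0].min() < default_params.gb - 5.0
        i = traj[:, 4]
        peak = int(np.argmax(i))
        assert 10 < peak < 700
        # plasma insulin rises then decays around its peak
        assert i[peak] > i[10] and i[peak] > i[-1]

    def test_mass_bookkeeping_with_full_bioavailability(self):
        p = PatientParameters(ag=1.0)
        grams = 80.0
        sched = EventSchedule(meals=[MealEvent(5, grams, "medium")], horizon_min=2000)
        traj = simulate(basal_state(p), p, sched)
        auc = np.trapezoid(traj[:, 6], dx=1.0)
        assert auc == pytest.approx(grams * 1000.0, rel=0.01)

    def test_insulin_cascade_peaks_in_order(self, default_params):
        sched = EventSchedule(boluses=[Bolus(5, 0.4)], horizon_min=900)
        traj = simulate(basal_state(default_params), default_params, sched)
        peaks = [int(np.argmax(traj[:, k])) for k in (2, 3, 4)]  # S1, S2, I
        assert peaks[0] < peaks[1] < peaks[2]
        for k in (2, 3, 4):
            y = traj[:, k]
            pk = int(np.argmax(y))
            assert np.all(np.diff(y[6:pk + 1]) >= -1e-9)  # unimodal rise
            assert np.all(np.diff(y[pk:]) <= 1e-9)        # then decay

    def test_euler_matches_adaptive_integrator(self, default_params):
        """1-min forward Euler against an adaptive-step oracle on a 24-h,
        3-meal scenario: glucose RMSE below 1 mg/dL."""
        p = default_params
        sched = EventSchedule(
            meals=[MealEvent(7 * 60, 70, "fast"), MealEvent(13 * 60, 100, "medium"),
                   MealEvent(19 * 60, 80, "medium")],
            boluses=[Bolus(7 * 60, 0.30), Bolus(13 * 60, 0.42), Bolus(19 * 60, 0.34)],
            horizon_min=1440,
        )
        traj = simulate(basal_state(p), p, sched)
        ucho, uins, tmaxi, tmg = sched.to_input_arrays(p, 1440)
        pv = p.to_vector()

        def rhs(t, x):
            k = min(int(t), 1439)
            g, xa, s1, s2, i, ra1, ra = x
            return [
                -(pv[0] + xa) * g + pv[0] * pv[2] + ra / (pv[3] * pv[5]),
                -pv[7] * xa + pv[7] * pv[1] * i,
                uins[k] - s1 / tmaxi[k],
                (s1 - s2) / tmaxi[k],
                -pv[6] * i + UU_PER_ML_PER_MU_PER_ML * s2 / (pv[4] * pv[5] * tmaxi[k]),
                -(ra1 - pv[8] * ucho[k]) / tmg[k],
                -(ra - ra1) / tmg[k],
            ]

        sol = solve_ivp(rhs, (0, 1440), [p.gb, 0, 0, 0, 0, 0, 0],
                        t_eval=np.arange(1441), method="LSODA",
                        rtol=1e-8, atol=1e-8, max_step=1.0)
        rmse = np.sqrt(np.mean((traj[:, 0] - sol.y[0]) ** 2))
        assert rmse < 1.0

    def test_short_horizon_rejected(self, default_params):
        with pytest.raises(ValueError):
            simulate(basal_state(default_params), default_params,
                     EventSchedule(horizon_min=0))
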