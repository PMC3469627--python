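import numpy as np
import pytest

import copdsim as cs
from copdsim import natural_history as nh


class TestClassifyDiagnosis:
    def test_mild_symptomatic_partition(self, defaults):
        """1,000 symptomatic mild: uptake .37, sens .92 -> 340.4/29.6/630."""
        part = nh.classify_diagnosis(1000.0, 0.0, 0.0, defaults.disease)
        assert part.tp == pytest.approx(340.4)
        assert part.fn == pytest.approx(29.6)
        assert part.ud == pytest.approx(630.0)

    def test_non_copd_symptomatic_partition(self, defaults):
        """1,000 symptomatic non-COPD: uptake .37, spec .84 -> 310.8/59.2."""
        part = nh.classify_diagnosis(0.0, 0.0, 1000.0, defaults.disease)
        assert part.tn == pytest.approx(310.8)
        assert part.fp == pytest.approx(59.2)

    def test_perfect_test_leaves_only_asymptomatic_undiagnosed(self, defaults):
        p = defaults.copy().disease
        p.spirometry_uptake = 1.0
        p.spirometry_sensitivity = 1.0
        part = nh.classify_diagnosis(700.0, 300.0, 0.0, p)
        assert part.tp == pytest.approx(700.0)
        assert part.fn == 0.0
        assert part.ud == pytest.approx(300.0)

    def test_partition_conserves_inputs(self, defaults):
        part = nh.classify_diagnosis(321.0, 123.0, 456.0, defaults.disease)
        assert part.tp + part.fn + part.ud == pytest.approx(321.0 + 123.0)
        untested = 456.0 - (part.tn + part.fp)
        assert untested == pytest.approx(456.0 * (1 - 0.37))

    def test_uptake_monotonicity_in_tp(self, defaults):
        p = defaults.copy().disease
        tps = []
        for u in np.linspace(0.0, 1.0, 11):
            p.spirometry_uptake = float(u)
            tps.append(float(nh.classify_diagnosis(1000.0, 0.0, 0.0, p).tp))
        assert all(b >= a for a, b in zip(tps, tps[1:]))

    def test_negative_input_rejected(self, defaults):
        with pytest.raises(ValueError):
            nh.classify_diagnosis(-1.0, 0.0, 0.0, defaults.disease)


class TestStepDisease:
    def _state_with(self, **stocks):
        st = nh.DiseaseState.zeros()
        for name, (idx, v) in stocks.items():
            getattr(st, name)[idx] = v
        return st

    def test_mild_progression_hazard_is_reciprocal_time(self, defaults):
        """1,000 UD mild male current smokers, 22y mean time -> 45.45/yr,
        arriving in moderate as diagnosed."""
        st = self._state_with(mild_ud=((0, 2, 0), 1000.0))
        out = nh.step_disease(st, defaults.disease, dt=1.0)
        assert out.moderate[0, 2, 0] == pytest.approx(1000.0 / 22.0)
        assert out.mild_ud[0, 2, 0] == pytest.approx(1000.0 * (1 - 1 / 22.0))
        assert out.mild_fn.sum() == out.mild_tp.sum() == 0.0

    def test_moderate_progression(self, defaults):
        """2,100 moderate women previous smokers, 21y -> 100 enter severe."""
        st = self._state_with(moderate=((1, 1, 1), 2100.0))
        out = nh.step_disease(st, defaults.disease, dt=1.0)
        assert out.severe[1, 1, 1] == pytest.approx(100.0)

    def test_infinite_progression_time_freezes_state(self, defaults):
        p = defaults.copy().disease
        p.progression_times = np.full_like(p.progression_times, 1e12)
        st = self._state_with(mild_tp=((0, 0, 0), 500.0),
                              moderate=((0, 0, 0), 300.0))
        out = nh.step_disease(st, p, dt=1.0)
        assert out.mild_tp[0, 0, 0] == pytest.approx(500.0)
        assert out.moderate[0, 0, 0] == pytest.approx(300.0, rel=1e-9)

    def test_progression_conserves_persons(self, defaults):
        st = self._state_with(mild_tp=((0, 1, 0), 10.0),
                              mild_fn=((0, 1, 0), 20.0),
                              mild_ud=((0, 1, 0), 30.0),
                              moderate=((0, 1, 0), 40.0),
                              severe=((0, 1, 0), 50.0))
        out = nh.step_disease(st, defaults.disease, dt=0.25)
        assert out.population().sum() == pytest.approx(150.0)


class TestMildIncidence:
    def test_balance_examples(self):
        # growth of 1,000 at 17% target, no outflows -> 170 incident cases
        assert nh.incidence_balance(1000.0, 0.0, 0.17) == pytest.approx(170.0)
        # static population, zero outflows -> zero incidence
        assert nh.incidence_balance(0.0, 0.0, 0.17) == 0.0
        # static population, 50 progressed out -> 50 replacements
        assert nh.incidence_balance(0.0, 50.0, 0.17) == pytest.approx(50.0)

    def test_target_above_one_rejected(self):
        with pytest.raises(ValueError):
            nh.incidence_balance(10.0, 0.0, 1.2)

    def test_topup_restores_target_prevalence(self, defaults):
        state = nh.initial_state(defaults)
        # knock mild stocks down by progression and refill
        state = nh.step_disease(state, defaults.disease, dt=1.0)
        inc = nh.mild_incidence_to_hold_prevalence(state, defaults.disease,
                                                   warn=False)
        state = nh.apply_mild_incidence(state, inc, defaults.disease)
        prev = state.mild() / state.population()
        np.testing.assert_allclose(prev,
                                   defaults.disease.mild_prevalence(),
                                   atol=1e-12)


class TestInitialState:
    def test_diagnosis_partition_sums(self, defaults):
        state = nh.initial_state(defaults)
        pop = defaults.demography.initial_population()
        dist = defaults.disease.stage_distribution
        np.testing.assert_allclose(state.mild(), pop * dist[..., 1])
        np.testing.assert_allclose(state.tn + state.fp + state.untested,
                                   pop * dist[..., 0])
        np.testing.assert_allclose(state.population(), pop)

    def test_moderate_and_severe_have_no_ud_or_fn(self, defaults):
        # the state carries no UD/FN compartments beyond mild by construction;
        # a full projection must keep it that way (all progressors diagnosed)
        res = cs.simulate(cs.default_demography(ps=defaults))
        a = res.annual
        assert (a.mild_tp + a.mild_fn + a.mild_ud).iloc[-1] == pytest.approx(
            a.mild.iloc[-1])


def test_subgroup_mild_prevalence_constant_over_horizon(calibrated):
    """The published constancy: subgroup mild prevalence never drifts more
    than 0.1% absolute from its target across the whole projection."""
    res = cs.simulate(calibrated, track_subgroups=True)
    dis = res.by_subgroup["disease"]
    pop = res.by_subgroup["population"]
    target = calibrated.disease.mild_prevalence()
    mild = dis[dis.compartment.isin(["mild_tp", "mild_fn", "mild_ud"])]
    mild_tot = mild.groupby(["year", "sex", "age_band", "smoking"],
                            sort=False).persons.sum()
    pop_tot = pop.set_index(["year", "sex", "age_band", "smoking"]).persons
    prev = (mild_tot / pop_tot).unstack(["sex", "age_band", "smoking"])
    from copdsim.params import AGE_BANDS, SEXES, SMOKING
    for i, sex in enumerate(SEXES):
        for a, band in enumerate(AGE_BANDS):
            for k, smoke in enumerate(SMOKING):
                dev = (prev[(sex, band, smoke)] - target[i, a, k]).abs().max()
                assert dev < 1e-3, (sex, band, smoke, dev)
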