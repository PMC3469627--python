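import numpy as np
import pytest

import copdsim as cs
from copdsim import events as ev
from copdsim import health_econ as he
from copdsim import natural_history as nh

ZERO_MU = np.zeros((2, 4, 3))


class TestUnitCostIdentity:
    """Maintenance + rate x episode-mix identity against the published
    per-patient totals (printed to the dollar; the moderate-direct,
    severe-direct and severe-indirect cells carry a $1 print-rounding
    artifact, hence the +/- $1 comparison)."""

    @pytest.mark.parametrize("stage,component,published", [
        ("mild", "direct", 572), ("moderate", "direct", 1167),
        ("severe", "direct", 1796), ("mild", "indirect", 143),
        ("moderate", "indirect", 583), ("severe", "indirect", 1497),
    ])
    def test_per_patient_totals(self, defaults, stage, component, published):
        got = he.annual_cost_per_patient(stage, defaults.events,
                                         defaults.economics, component)
        assert abs(round(got) - published) <= 1

    def test_exact_cells(self, defaults):
        assert round(he.annual_cost_per_patient(
            "mild", defaults.events, defaults.economics, "direct")) == 572
        assert round(he.annual_cost_per_patient(
            "moderate", defaults.events, defaults.economics,
            "indirect")) == 583


class TestDiscounting:
    def test_published_identity(self, defaults):
        """7.33B accrued in 2035 discounts to 3.61B at 3% (base 2011)."""
        got = he.discount(7.33e9, 2035, defaults.economics)
        assert got == pytest.approx(3.61e9, rel=2e-3)

    def test_base_year_unchanged(self, defaults):
        assert he.discount(123.4, 2011, defaults.economics) == 123.4

    def test_one_year(self, defaults):
        assert he.discount(100.0, 2012, defaults.economics) == pytest.approx(
            97.087, abs=1e-3)

    def test_before_base_year_rejected(self, defaults):
        with pytest.raises(ValueError):
            he.discount(1.0, 2010, defaults.economics)

    def test_multiplicative_order_independent(self, defaults):
        ec = defaults.economics
        a = he.discount(he.discount(100.0, 2013, ec), 2011, ec)
        two_then_none = he.discount(100.0, 2013, ec)
        assert a == pytest.approx(two_then_none)


class TestAccrueCosts:
    def _tally(self, state, defaults, dt=1.0):
        return ev.tally_events(state, defaults.events, ZERO_MU, dt)

    def test_undiagnosed_mild_generate_no_maintenance(self, defaults):
        st = nh.DiseaseState.zeros()
        st.mild_ud[0, 0, 0] = 100.0
        tally = ev.EventTally(minor=np.zeros((3, 2, 4, 3)),
                              major=np.zeros((3, 2, 4, 3)),
                              copd_deaths=np.zeros((3, 2, 4, 3)),
                              background_deaths=ZERO_MU)
        inc = he.accrue_costs(st, tally, defaults.economics, dt=1.0)
        assert inc.direct_cost == 0.0
        assert inc.indirect_cost == 0.0

    def test_false_positives_pay_mild_maintenance(self, defaults):
        st = nh.DiseaseState.zeros()
        st.fp[1, 2, 2] = 100.0
        tally = self._tally(nh.DiseaseState.zeros(), defaults)
        inc = he.accrue_costs(st, tally, defaults.economics, dt=1.0)
        assert inc.direct_cost == pytest.approx(100.0 * 144.0)
        assert inc.indirect_cost == pytest.approx(100.0 * 36.0)

    def test_episodes_cost_regardless_of_diagnosis(self, defaults):
        """10 major episodes among undiagnosed patients: 10 x 6,501 direct."""
        st = nh.DiseaseState.zeros()
        tally = ev.EventTally(minor=np.zeros((3, 2, 4, 3)),
                              major=np.zeros((3, 2, 4, 3)),
                              copd_deaths=np.zeros((3, 2, 4, 3)),
                              background_deaths=ZERO_MU)
        tally.major[0, 0, 0, 0] = 10.0
        inc = he.accrue_costs(st, tally, defaults.economics, dt=1.0)
        assert inc.direct_cost == pytest.approx(65_010.0)

    def test_diagnosed_patient_year_matches_unit_identity(self, defaults):
        st = nh.DiseaseState.zeros()
        st.moderate[0, 1, 0] = 1000.0
        inc = he.accrue_costs(st, self._tally(st, defaults),
                              defaults.economics, dt=1.0)
        expected = 1000.0 * (
            he.annual_cost_per_patient("moderate", defaults.events,
                                       defaults.economics, "direct")
            + he.annual_cost_per_patient("moderate", defaults.events,
                                         defaults.economics, "indirect"))
        assert inc.total_cost == pytest.approx(expected)


class TestAccrueQalys:
    def test_chronic_loss_is_reference_minus_stage_utility(self, defaults):
        """One moderate patient aged 60-69 for one year: 0.828 - 0.72."""
        st = nh.DiseaseState.zeros()
        st.moderate[0, 2, 0] = 1.0
        tally = ev.tally_events(nh.DiseaseState.zeros(), defaults.events,
                                ZERO_MU, 1.0)
        inc = he.accrue_qalys(st, tally, defaults.utilities, dt=1.0)
        assert inc.qaly_chronic == pytest.approx(0.828 - 0.72)

    def test_zero_loss_when_reference_equals_chronic(self, defaults):
        up = defaults.copy().utilities
        up.reference_by_age = np.full(4, 0.72)
        up.chronic_by_stage = np.array([0.72, 0.72, 0.72])
        st = nh.DiseaseState.zeros()
        st.moderate[0, 0, 0] = 50.0
        tally = ev.tally_events(nh.DiseaseState.zeros(), defaults.events,
                                ZERO_MU, 1.0)
        inc = he.accrue_qalys(st, tally, up, dt=1.0)
        assert inc.qaly_chronic == 0.0

    def test_major_episode_loss_with_one_month_duration(self, defaults):
        """Severe major episode, one month: (0.67 - 0.408) / 12."""
        up = defaults.copy().utilities
        up.major_episode_duration = 1.0 / 12.0
        tally = ev.EventTally(minor=np.zeros((3, 2, 4, 3)),
                              major=np.zeros((3, 2, 4, 3)),
                              copd_deaths=np.zeros((3, 2, 4, 3)),
                              background_deaths=ZERO_MU)
        tally.major[2, 0, 0, 0] = 1.0
        inc = he.accrue_qalys(nh.DiseaseState.zeros(), tally, up, dt=1.0)
        assert inc.qaly_exacerbation == pytest.approx((0.67 - 0.408) / 12.0,
                                                      abs=1e-4)

    def test_mild_70plus_decrement_clamped_at_zero(self, defaults):
        # reference 0.79 < mild chronic 0.81: COPD cannot improve utility
        st = nh.DiseaseState.zeros()
        st.mild_ud[0, 3, 0] = 1000.0
        tally = ev.tally_events(nh.DiseaseState.zeros(), defaults.events,
                                ZERO_MU, 1.0)
        inc = he.accrue_qalys(st, tally, defaults.utilities, dt=1.0)
        assert inc.qaly_chronic == 0.0

    def test_death_annuity_spans_horizon(self, defaults):
        undisc, disc = he.death_qaly_annuities(
            defaults.utilities, defaults.economics, 2011, 2035,
            np.zeros(4))
        # no aging: a 70+ death in 2011 loses 25 x 0.79 reference QALYs
        assert undisc[3, 0] == pytest.approx(25 * 0.79)
        # discounted strictly below undiscounted, both decline toward horizon
        assert disc[3, 0] < undisc[3, 0]
        assert undisc[3, -1] == pytest.approx(0.79)


class TestNetMonetaryBenefit:
    def test_published_rows_within_input_rounding(self, defaults):
        ec = defaults.economics
        # smoking-screen row: 0.16M QALYs + 1.41B -> printed 9.39B
        assert he.net_monetary_benefit(1.41e9, 0.16e6, ec) == pytest.approx(
            9.39e9, abs=0.3e9)
        # exacerbation-test row: 3.83M QALYs + 34.46B -> printed 225.72B
        assert he.net_monetary_benefit(34.46e9, 3.83e6, ec) == pytest.approx(
            225.72e9, abs=0.3e9)

    def test_zero_deltas(self, defaults):
        assert he.net_monetary_benefit(0.0, 0.0, defaults.economics) == 0.0

    def test_linearity(self, defaults):
        ec = defaults.economics
        a = he.net_monetary_benefit(2.0e9, 0.5e6, ec)
        assert he.net_monetary_benefit(4.0e9, 1.0e6, ec) == pytest.approx(2 * a)


def test_indirect_share_consistency(defaults):
    """Published indirect units imply roughly 20/33/45% indirect shares of
    total per-patient cost across mild/moderate/severe."""
    shares = []
    for stage in ("mild", "moderate", "severe"):
        d = he.annual_cost_per_patient(stage, defaults.events,
                                       defaults.economics, "direct")
        i = he.annual_cost_per_patient(stage, defaults.events,
                                       defaults.economics, "indirect")
        shares.append(i / (d + i))
    assert shares[0] == pytest.approx(0.20, abs=0.02)
    assert shares[1] == pytest.approx(0.33, abs=0.02)
    assert shares[2] == pytest.approx(0.45, abs=0.02)


def test_discounted_never_exceeds_undiscounted(base_run):
    a = base_run.annual
    assert (a.total_cost_disc <= a.total_cost + 1e-6).all()
    assert (a.qaly_lost_disc <= a.qaly_lost + 1e-9).all()
    # strictly below after the base year at a positive discount rate
    assert (a.total_cost_disc.iloc[1:] < a.total_cost.iloc[1:]).all()
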