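import numpy as np
import pytest

from asthma_adherence.engine import (
    CohortTrace,
    _state_utilities,
    costs,
    count_exacerbations,
    discount_factor,
    life_years,
    qalys,
    run_cohort,
    summarize,
    write_trace,
)
from asthma_adherence.parameters import (
    ControlState,
    default_parameters,
    random_plausible_parameters,
)

from conftest import constant_mortality_life_table, toy_microsim_parameters

EXAC = int(ControlState.EXACERBATION)
DEAD = int(ControlState.DEAD)


class TestDiscountFactor:
    def test_cycle_zero(self):
        assert discount_factor(0, 0.035, 52) == 1.0

    def test_one_year(self):
        assert discount_factor(52, 0.035, 52) == pytest.approx(
            0.966183574879227053, abs=1e-12
        )

    def test_twenty_years(self):
        assert discount_factor(1040, 0.035, 52) == pytest.approx(
            0.502565884431669830, abs=1e-12
        )

    def test_negative_cycle_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(-1, 0.035, 52)


def _toy_two_state_params():
    """Single alive control state (uncontrolled) with weekly exacerbation
    entry 0.1, recovery straight back, no death; 10 cycles."""
    p = default_parameters(tagged=False)
    p.initial_distribution = np.array([0.0, 0.0, 1.0])
    p.full_adherence_transitions = np.array(
        [
            [0.0, 0.0, 0.0, 0.0],
            [0.0, 0.0, 0.0, 0.0],
            [0.0, 0.0, 0.0, 0.1],
        ]
    )
    p.exacerbation_recovery = np.array([0.0, 0.0, 1.0])
    p.zero_adherence_odds_ratios = np.array([1.0, 1.0, 1.0])
    p.exacerbation_case_fatality = 0.0
    p.horizon_years = 10.0 / 52.0
    return p


def _two_state_hand_recursion(n_cycles=10, p_entry=0.1):
    """Independent brute-force recursion over (uncontrolled, exacerbation)."""
    p_u, p_e = 1.0, 0.0
    occupancy = [(p_u, p_e)]
    incident = []
    for _ in range(n_cycles):
        incident.append(p_u * p_entry)
        p_u, p_e = p_u * (1.0 - p_entry) + p_e, p_u * p_entry
        occupancy.append((p_u, p_e))
    return occupancy, incident


class TestRunCohort:
    def test_initial_row(self, params, life_table):
        t = run_cohort(params, 0.5, life_table)
        np.testing.assert_array_equal(t.occupancy[0, :3], params.initial_distribution)
        assert t.occupancy[0, EXAC] == 0.0
        assert t.occupancy[0, DEAD] == 0.0

    def test_cycle_count_and_ages(self, params, life_table):
        t = run_cohort(params, 0.5, life_table)
        assert t.n_cycles == 1040
        assert t.occupancy.shape == (1041, 5)
        assert t.ages[0] == params.cohort_start_age
        assert t.ages[-1] == pytest.approx(params.cohort_start_age + 20.0)

    def test_rows_sum_to_one(self, params, life_table):
        t = run_cohort(params, 0.7, life_table)
        np.testing.assert_allclose(t.occupancy.sum(axis=1), 1.0, atol=1e-9)

    def test_dead_occupancy_monotone(self, params, life_table):
        t = run_cohort(params, 0.3, life_table)
        assert np.all(np.diff(t.occupancy[:, DEAD]) >= -1e-15)

    def test_incident_nonnegative(self, params, life_table):
        t = run_cohort(params, 0.3, life_table)
        assert np.all(t.incident_exacerbations >= 0.0)

    def test_no_transitions_no_mortality_gives_full_horizon(
        self, params, zero_mortality_life_table
    ):
        params.full_adherence_transitions[:] = 0.0
        t = run_cohort(params, 1.0, zero_mortality_life_table)
        assert life_years(t) == pytest.approx(20.0, abs=1e-12)
        np.testing.assert_array_equal(t.occupancy[-1], t.occupancy[0])

    def test_two_state_toy_matches_hand_recursion(self, zero_mortality_life_table):
        p = _toy_two_state_params()
        t = run_cohort(p, 1.0, zero_mortality_life_table)
        occupancy, incident = _two_state_hand_recursion()
        assert t.n_cycles == 10
        for c, (p_u, p_e) in enumerate(occupancy):
            assert t.occupancy[c, 2] == pytest.approx(p_u, abs=1e-12)
            assert t.occupancy[c, EXAC] == pytest.approx(p_e, abs=1e-12)
        np.testing.assert_allclose(t.incident_exacerbations, incident, atol=1e-12)
        assert count_exacerbations(t) == pytest.approx(sum(incident), abs=1e-12)


class TestAllDeadTrace:
    def _trace(self, n_cycles=10):
        occ = np.zeros((n_cycles + 1, 5))
        occ[:, DEAD] = 1.0
        return CohortTrace(
            occupancy=occ,
            incident_exacerbations=np.zeros(n_cycles),
            ages=40.0 + np.arange(n_cycles + 1) / 52.0,
            adherence=0.5,
            cycles_per_year=52,
        )

    def test_all_outcomes_zero(self, params):
        t = self._trace()
        s = summarize(t, params, 0.5)
        assert s.total_exacerbations == 0.0
        assert s.life_years == 0.0
        assert s.qalys_discounted == 0.0
        assert s.cost_total == 0.0


class TestLifeYears:
    def test_geometric_series_closed_form(self, params):
        params.full_adherence_transitions[:] = 0.0
        params.initial_distribution = np.array([1.0, 0.0, 0.0])
        q_annual = 0.2
        lt = constant_mortality_life_table(q_annual)
        t = run_cohort(params, 1.0, lt)
        s = (1.0 - q_annual) ** (1.0 / 52.0)
        n = t.n_cycles
        expected = (1.0 - s**n) / (1.0 - s) / 52.0
        assert life_years(t) == pytest.approx(expected, abs=1e-9)

    def test_bounded_by_horizon(self, params, life_table):
        t = run_cohort(params, 0.5, life_table)
        assert 0.0 < life_years(t) <= params.horizon_years


class TestQalys:
    def _make_unit_utility(self, p):
        p.utilities.controlled = 1.0
        p.utilities.partially_controlled = 1.0
        p.utilities.uncontrolled = 1.0
        p.utilities.exacerbation_admitted = 1.0
        p.utilities.exacerbation_nonadmitted = 1.0
        p.utility_age_adjustment = p.utility_age_adjustment[:1]

    def test_rate_zero_unit_utilities_equal_life_years(self, params, life_table):
        self._make_unit_utility(params)
        t = run_cohort(params, 0.5, life_table)
        assert qalys(t, params, rate_annual=0.0) == pytest.approx(
            life_years(t), abs=1e-12
        )

    def test_linearity_in_utilities(self, params, life_table):
        t = run_cohort(params, 0.5, life_table)
        full = qalys(t, params, rate_annual=0.0)
        for name in (
            "controlled",
            "partially_controlled",
            "uncontrolled",
            "exacerbation_admitted",
            "exacerbation_nonadmitted",
        ):
            setattr(params.utilities, name, getattr(params.utilities, name) / 2.0)
        assert qalys(t, params, rate_annual=0.0) == pytest.approx(full / 2.0, abs=1e-12)

    def test_exacerbation_utility_mixture(self, params):
        params.utilities.exacerbation_admitted = 0.5
        params.utilities.exacerbation_nonadmitted = 0.7
        params.admitted_fraction = 0.39
        assert _state_utilities(params)[EXAC] == pytest.approx(0.622, abs=1e-12)

    def test_discounting_reduces_qalys(self, params, life_table):
        t = run_cohort(params, 0.5, life_table)
        assert qalys(t, params, rate_annual=0.035) < qalys(t, params, rate_annual=0.0)

    def test_discount_zero_identity_against_trace_arithmetic(self, params, life_table):
        # independent accumulation straight off the trace arrays
        t = run_cohort(params, 0.6, life_table)
        u = _state_utilities(params)
        total = 0.0
        for c in range(t.n_cycles):
            adj = params.utility_adjustment(float(int(t.ages[c])))
            total += float(t.occupancy[c] @ u) * adj / 52.0
        assert qalys(t, params, rate_annual=0.0) == pytest.approx(total, rel=1e-12)


class TestCosts:
    def test_zero_adherence_zero_maintenance(self, params, life_table):
        t = run_cohort(params, 0.0, life_table)
        assert costs(t, params, 0.0).maintenance == 0.0

    def test_outpatient_controlled_half_year(self, params, zero_mortality_life_table):
        params.full_adherence_transitions[:] = 0.0
        params.initial_distribution = np.array([1.0, 0.0, 0.0])
        params.costs.outpatient_visit = 100.0
        params.horizon_years = 26.0 / 52.0
        t = run_cohort(params, 1.0, zero_mortality_life_table)
        c = costs(t, params, 1.0, rate_annual=0.0)
        # 26 cycles x (1/26 visits per cycle) x 100
        assert c.outpatient == pytest.approx(100.0, abs=1e-9)

    def test_no_incident_exacerbations_no_episode_costs(
        self, params, zero_mortality_life_table
    ):
        params.full_adherence_transitions[:, EXAC] = 0.0
        t = run_cohort(params, 1.0, zero_mortality_life_table)
        c = costs(t, params, 1.0)
        assert c.exacerbation_nonadmitted == 0.0
        assert c.exacerbation_admitted == 0.0

    def test_maintenance_linear_in_adherence(self, params, life_table):
        t = run_cohort(params, 0.5, life_table)
        half = costs(t, params, 0.5).maintenance
        full = costs(t, params, 1.0).maintenance
        assert half == pytest.approx(full / 2.0, rel=1e-12)

    def test_total_is_sum_of_components(self, params, life_table):
        t = run_cohort(params, 0.5, life_table)
        c = costs(t, params, 0.5)
        assert c.total == pytest.approx(
            c.maintenance
            + c.outpatient
            + c.rescue
            + c.exacerbation_nonadmitted
            + c.exacerbation_admitted
        )

    def test_discounting_reduces_costs(self, params, life_table):
        t = run_cohort(params, 0.5, life_table)
        assert costs(t, params, 0.5, rate_annual=0.035).total < costs(
            t, params, 0.5, rate_annual=0.0
        ).total


class TestSummarize:
    def test_toy_instance_all_fields(self, zero_mortality_life_table):
        p = _toy_two_state_params()
        p.discount_rate_annual = 0.0
        p.utility_age_adjustment = p.utility_age_adjustment[:1]
        t = run_cohort(p, 1.0, zero_mortality_life_table)
        s = summarize(t, p, 1.0)

        occupancy, incident = _two_state_hand_recursion()
        exp_exac = sum(incident)
        exp_ly = 10.0 / 52.0
        u_mix = (
            p.admitted_fraction * p.utilities.exacerbation_admitted
            + (1.0 - p.admitted_fraction) * p.utilities.exacerbation_nonadmitted
        )
        exp_qaly = (
            sum(
                p_u * p.utilities.uncontrolled + p_e * u_mix
                for p_u, p_e in occupancy[:10]
            )
            / 52.0
        )
        episode = (
            p.admitted_fraction * p.costs.exacerbation_admitted
            + (1.0 - p.admitted_fraction) * p.costs.exacerbation_nonadmitted
        )
        exp_cost = (
            exp_exac * episode
            + sum(
                p_u
                * (
                    p.costs.maintenance_weekly
                    + p.costs.outpatient_visit / p.outpatient_interval_weeks[2]
                    + p.costs.rescue_weekly[2]
                )
                + p_e * p.costs.rescue_weekly[EXAC]
                for p_u, p_e in occupancy[:10]
            )
        )
        assert s.total_exacerbations == pytest.approx(exp_exac, abs=1e-12)
        assert s.life_years == pytest.approx(exp_ly, abs=1e-12)
        assert s.qalys_discounted == pytest.approx(exp_qaly, abs=1e-12)
        assert s.cost_total == pytest.approx(exp_cost, rel=1e-12)

    def test_monotone_direction_in_adherence(self, params, life_table):
        grid = np.arange(0.1, 1.01, 0.1)
        summaries = [
            summarize(run_cohort(params, a, life_table), params, a) for a in grid
        ]
        exacs = [s.total_exacerbations for s in summaries]
        qys = [s.qalys_discounted for s in summaries]
        assert all(b <= a + 1e-12 for a, b in zip(exacs, exacs[1:]))
        assert all(b >= a - 1e-12 for a, b in zip(qys, qys[1:]))


class TestMassConservation:
    @pytest.mark.parametrize("seed", range(60))
    def test_random_parameterizations(self, seed, life_table):
        p = random_plausible_parameters(seed, tagged=False)
        p.horizon_years = 5.0
        a = float(np.random.default_rng(seed).uniform(0, 1))
        t = run_cohort(p, a, life_table)
        np.testing.assert_allclose(t.occupancy.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(np.diff(t.occupancy[:, DEAD]) >= -1e-15)
        assert np.all(t.incident_exacerbations >= 0.0)


class TestMicrosimAgreement:
    def test_cohort_matches_paths(self, life_table):
        from _microsim import simulate_paths

        p = toy_microsim_parameters()
        p.horizon_years = 2.0
        a = 0.6
        t = run_cohort(p, a, life_table)
        sim = simulate_paths(p, a, life_table, n_paths=20000, seed=11)

        for cycle in (10, 52, 104):
            for state in range(5):
                se = max(sim.se_occupancy(cycle, state), 1e-6)
                assert abs(sim.occupancy[cycle, state] - t.occupancy[cycle, state]) <= 3 * se

        mean, se = sim._mean_se(sim.exacerbations)
        assert abs(mean - count_exacerbations(t)) <= 3 * max(se, 1e-9)
        mean, se = sim._mean_se(sim.life_years)
        assert abs(mean - life_years(t)) <= 3 * max(se, 1e-9)
        mean, se = sim._mean_se(sim.qalys_undiscounted)
        assert abs(mean - qalys(t, p, rate_annual=0.0)) <= 3 * max(se, 1e-9)


def test_write_trace(tmp_path, params, life_table):
    params.horizon_years = 0.5
    t = run_cohort(params, 0.5, life_table)
    path = tmp_path / "trace.tsv"
    write_trace(t, params, path)
    lines = path.read_text().splitlines()
    assert lines[0].startswith("cycle\tage\tcontrolled")
    assert len(lines) == t.n_cycles + 2
    row1 = lines[1].split("\t")
    assert float(row1[2]) == params.initial_distribution[0]
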