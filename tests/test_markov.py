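"""Markov engine: allocation, transitions, accrual, conservation, limits."""

import copy

import numpy as np
import pytest

from quitcost.markov import (
    N_DISEASE_STATES,
    N_STATUS,
    ParamBatch,
    accrue,
    apply_quit_attempt,
    build_initial_cohort,
    run_cohort,
    transition,
)
from quitcost.params import DISEASE_IDS, STRATUM_KEYS, InterventionProfile


def _profile(p_abstain=0.2, p_depression=0.0, p_selfharm=0.0, cost=0.0):
    return InterventionProfile(
        intervention_id="toy", licensed=True, course_cost=cost,
        p_abstain=p_abstain, p_depression=p_depression, p_selfharm=p_selfharm)


class TestInitialCohort:
    def test_zero_prevalence_allocates_by_share(self, toy_ps):
        ps = copy.deepcopy(toy_ps)
        for s in ps.strata:
            s.cohort_share = 1.0 / 6.0
        occ = build_initial_cohort(ParamBatch.from_parameter_sets([ps]))
        per_stratum = occ.sum(axis=(2, 3))[0]
        assert per_stratum == pytest.approx(np.full(6, 10_000 / 6))
        assert occ[0, :, 0, 0].sum() == pytest.approx(10_000)  # all healthy smokers

    def test_prevalence_moves_share_into_disease_state(self, toy_ps):
        ps = copy.deepcopy(toy_ps)
        ps.diseases["copd"].prevalence["male_35_64"] = 0.1
        occ = build_initial_cohort(ParamBatch.from_parameter_sets([ps]))
        s = STRATUM_KEYS.index("male_35_64")
        d = DISEASE_IDS.index("copd") + 1
        assert occ[0, s, 0, d] == pytest.approx(0.1 * 10_000)
        assert occ[0, s, 0, 0] == pytest.approx(0.9 * 10_000)

    def test_default_set_sums_to_cohort_size(self, default_ps):
        occ = build_initial_cohort(ParamBatch.from_parameter_sets([default_ps]))
        assert occ.sum() == pytest.approx(10_000)
        assert occ[:, :, 1:, :].sum() == 0.0  # no quitters at entry


class TestQuitAttempt:
    def _apply(self, ps, profile):
        batch = ParamBatch.from_parameter_sets([ps])
        occ = build_initial_cohort(batch)
        deaths = np.zeros((1, 6))
        one = lambda x: np.array([float(x)])
        return apply_quit_attempt(occ, deaths, batch, one(profile.p_abstain),
                                  one(profile.p_depression), one(profile.p_selfharm),
                                  one(profile.course_cost))

    def test_zero_abstinence_creates_no_quitters(self, toy_ps):
        occ, deaths, cost, dq = self._apply(toy_ps, _profile(p_abstain=0.0))
        assert occ[:, :, 1:, :].sum() == 0.0
        assert deaths.sum() == 0.0

    def test_full_abstinence_moves_everyone_to_counter_one(self, toy_ps):
        occ, deaths, cost, dq = self._apply(toy_ps, _profile(p_abstain=1.0))
        assert occ[0, :, 1, :].sum() == pytest.approx(10_000)
        assert occ[0, :, 0, :].sum() == 0.0

    def test_expected_nonfatal_selfharm_costs(self, toy_ps):
        # 0.5% of 10,000 members with no fatalities → 50 events' one-off cost
        ps = copy.deepcopy(toy_ps)
        ps.adverse_events.cost_selfharm = 2_500.0
        ps.adverse_events.disutility_selfharm = 0.15
        occ, deaths, cost, dq = self._apply(ps, _profile(p_selfharm=0.005))
        assert cost[0] == pytest.approx(50 * 2_500.0)
        assert dq[0] == pytest.approx(50 * 0.15)
        assert deaths.sum() == 0.0

    def test_fatal_selfharm_moves_members_to_dead(self, toy_ps):
        ps = copy.deepcopy(toy_ps)
        ps.adverse_events.fatal_fraction_selfharm = 0.4
        occ, deaths, cost, dq = self._apply(ps, _profile(p_selfharm=0.01))
        assert deaths.sum() == pytest.approx(10_000 * 0.01 * 0.4)
        assert occ.sum() + deaths.sum() == pytest.approx(10_000)


class TestTransition:
    def test_relapse_expectation_from_published_rate(self, toy_ps):
        # 1,000 quitters at counter 2 under the 0.13 short-run relapse rate
        ps = copy.deepcopy(toy_ps)
        ps.relapse.p_relapse_short = 0.13
        batch = ParamBatch.from_parameter_sets([ps])
        occ = np.zeros((1, 6, N_STATUS, N_DISEASE_STATES))
        s = STRATUM_KEYS.index("male_35_64")
        occ[0, s, 2, 0] = 1_000.0
        occ2, deaths, clamps = transition(occ, np.zeros((1, 6)), batch, cycle=1)
        assert occ2[0, s, 0, 0] == pytest.approx(130.0)
        assert occ2[0, s, 3, 0] == pytest.approx(870.0)  # counter advanced 2 → 3
        assert clamps == 0

    def test_all_rates_zero_only_advances_counters(self, toy_ps):
        batch = ParamBatch.from_parameter_sets([toy_ps])
        occ = np.zeros((1, 6, N_STATUS, N_DISEASE_STATES))
        s = STRATUM_KEYS.index("male_35_64")
        occ[0, s, 0, 0] = 400.0
        occ[0, s, 4, 0] = 600.0
        occ2, deaths, _ = transition(occ.copy(), np.zeros((1, 6)), batch, cycle=1)
        assert occ2[0, s, 0, 0] == 400.0
        assert occ2[0, s, 5, 0] == 600.0
        assert deaths.sum() == 0.0

    def test_overflowing_probability_is_clamped_and_counted(self, toy_ps):
        ps = copy.deepcopy(toy_ps)
        ps.diseases["copd"].incidence["male_35_64"] = 0.2
        ps.diseases["copd"].rr_smoker = 8.0  # 1.6 > 1 before clamping
        batch = ParamBatch.from_parameter_sets([ps])
        occ = np.zeros((1, 6, N_STATUS, N_DISEASE_STATES))
        s = STRATUM_KEYS.index("male_35_64")
        occ[0, s, 0, 0] = 100.0
        occ2, deaths, clamps = transition(occ, np.zeros((1, 6)), batch, cycle=1)
        assert clamps > 0
        assert occ2.sum() + deaths.sum() == pytest.approx(100.0)
        assert np.all(occ2 >= -1e-12)

    def test_dead_never_decreases_under_random_parameters(self, default_ps):
        # absorbing-death property over a 50-cycle random sweep
        rng = np.random.default_rng(20)
        ps = copy.deepcopy(default_ps)
        for d in ps.diseases.values():
            for k in STRATUM_KEYS:
                d.incidence[k] = float(rng.uniform(0, 0.05))
                d.excess_mortality[k] = float(rng.uniform(0, 0.2))
        batch = ParamBatch.from_parameter_sets([ps])
        occ = build_initial_cohort(batch)
        deaths = np.zeros((1, 6))
        prev_dead = 0.0
        for cycle in range(1, 51):
            occ, deaths, _ = transition(occ, deaths, batch, cycle)
            dead = deaths.sum()
            assert dead >= prev_dead - 1e-9
            assert occ.sum() + dead == pytest.approx(10_000, abs=1e-6)
            assert np.all(occ >= -1e-9)
            prev_dead = dead


class TestAccrue:
    def test_unit_utility_gives_cohort_size_qalys(self, toy_ps):
        batch = ParamBatch.from_parameter_sets([toy_ps])
        occ = build_initial_cohort(batch)
        cost_u, qaly_u, cost_d, qaly_d = accrue(occ, batch, cycle=1)
        assert qaly_u[0] == pytest.approx(10_000)
        assert cost_u[0] == 0.0

    def test_discounting_closed_form(self, toy_ps):
        ps = copy.deepcopy(toy_ps)
        ps.economics.discount_rate = 0.035
        batch = ParamBatch.from_parameter_sets([ps])
        occ = build_initial_cohort(batch)
        cost_u, qaly_u, cost_d, qaly_d = accrue(occ, batch, cycle=1)
        assert qaly_d[0] == pytest.approx(qaly_u[0] / 1.035)

    def test_mixed_occupancy_matches_hand_computation(self, toy_ps):
        ps = copy.deepcopy(toy_ps)
        ps.diseases["copd"].annual_cost = 1_000.0
        ps.diseases["copd"].utility_value = 0.7
        ps.diseases["stroke"].annual_cost = 3_000.0
        ps.diseases["stroke"].utility_value = 0.6
        ps.economics.baseline_utility = {k: 0.9 for k in STRATUM_KEYS}
        batch = ParamBatch.from_parameter_sets([ps])
        occ = np.zeros((1, 6, N_STATUS, N_DISEASE_STATES))
        s = STRATUM_KEYS.index("female_18_34")
        occ[0, s, 0, 0] = 3.0                               # healthy smokers
        occ[0, s, 1, DISEASE_IDS.index("copd") + 1] = 2.0   # COPD quitters
        occ[0, s, 0, DISEASE_IDS.index("stroke") + 1] = 5.0
        cost_u, qaly_u, _, _ = accrue(occ, batch, cycle=1)
        assert cost_u[0] == pytest.approx(2 * 1_000 + 5 * 3_000)
        assert qaly_u[0] == pytest.approx(3 * 0.9 + 2 * 0.7 + 5 * 0.6)


class TestRunCohort:
    def test_immortal_disease_free_identity(self, toy_ps):
        # zero discount, unit utility, zero mortality, 10 cycles → 10 QALYs
        cost, qaly, trace = run_cohort(_profile(), toy_ps, max_cycles=10)
        assert qaly == pytest.approx(10.0)
        assert cost == pytest.approx(0.0)

    def test_higher_abstinence_never_lowers_qalys(self, default_ps):
        ps = copy.deepcopy(default_ps)
        ps.adverse_events.fatal_fraction_selfharm = 0.0
        qalys = []
        for p_abstain in (0.05, 0.2, 0.4, 0.6, 0.9):
            _, q, _ = run_cohort(_profile(p_abstain=p_abstain), ps, keep_trace=False)
            qalys.append(q)
        assert all(b >= a - 1e-9 for a, b in zip(qalys, qalys[1:]))

    def test_raising_disease_rr_lowers_qalys_and_raises_costs(self, default_ps):
        # isolate a single disease: competing first-event states and
        # mortality-truncated accrual can otherwise mask the direct effect
        lo = copy.deepcopy(default_ps)
        for did, d in lo.diseases.items():
            for k in STRATUM_KEYS:
                d.excess_mortality[k] = 0.0
                if did != "copd":
                    d.incidence[k] = 0.0
                    d.prevalence[k] = 0.0
        hi = copy.deepcopy(lo)
        hi.diseases["copd"].rr_smoker *= 1.5
        hi.diseases["copd"].rr_recent_quitter *= 1.5
        hi.diseases["copd"].rr_long_quitter *= 1.5
        c_lo, q_lo, _ = run_cohort(_profile(), lo, keep_trace=False)
        c_hi, q_hi, _ = run_cohort(_profile(), hi, keep_trace=False)
        assert q_hi <= q_lo
        assert c_hi >= c_lo

    def test_conservation_every_cycle_of_default_run(self, default_ps):
        profiles = _profile(p_abstain=0.212, p_depression=0.0775,
                            p_selfharm=0.00506)
        _, _, trace = run_cohort(profiles, default_ps)
        assert trace.conservation_error(10_000) < 1e-6

    def test_three_state_toy_matches_matrix_product_oracle(self, toy_ps):
        # smoker / quitter / dead toy vs an explicit transition-matrix product
        ps = copy.deepcopy(toy_ps)
        a, r, m = 0.3, 0.13, 0.02
        ps.relapse.p_relapse_short = r
        ps.relapse.p_relapse_long = r
        ps.relapse.p_relapse_10plus = r
        for s in ps.strata:
            s.all_cause_mortality = m
        _, _, trace = run_cohort(_profile(p_abstain=a), ps, max_cycles=3)

        T = np.array([
            [(1 - m), 0.0, m],                          # smoker
            [r * (1 - m), (1 - r) * (1 - m), m],        # quitter
            [0.0, 0.0, 1.0],                            # dead
        ])
        state = np.array([1 - a, a, 0.0]) * 10_000      # cycle-1 state
        for cycle in (1, 2, 3):
            occ = trace.occupancy[cycle]
            assert occ[:, 0, :].sum() == pytest.approx(state[0], abs=1e-10)
            assert occ[:, 1:, :].sum() == pytest.approx(state[1], abs=1e-10)
            assert trace.deaths[cycle].sum() == pytest.approx(state[2], abs=1e-10)
            state = state @ T

    def test_batched_and_single_runs_agree(self, default_ps):
        from quitcost.markov import run_cohort_batch

        prof = _profile(p_abstain=0.25, p_depression=0.05, p_selfharm=0.004,
                        cost=150.0)
        c1, q1, _ = run_cohort(prof, default_ps, keep_trace=False)
        batch = ParamBatch.from_parameter_sets([default_ps, default_ps])
        arrs = {k: np.array([v, v]) for k, v in (
            ("p_abstain", prof.p_abstain), ("p_depression", prof.p_depression),
            ("p_selfharm", prof.p_selfharm), ("course_cost", prof.course_cost))}
        costs, qalys = run_cohort_batch(batch, arrs)
        assert costs == pytest.approx([c1, c1])
        assert qalys == pytest.approx([q1, q1])
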