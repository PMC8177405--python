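"""CEA outputs: frontier vs brute force, net benefit, CEAC, rank-o-grams."""

import numpy as np
import pandas as pd
import pytest

from quitcost.benchmarks import all_interventions_summary
from quitcost.cea import (
    DOMINATED,
    EXT_DOMINATED,
    ON_FRONTIER,
    NetBenefitMatrix,
    ceac,
    efficiency_frontier,
    expected_outcomes,
    net_benefit,
    rankogram,
)


def brute_force_statuses(cost: np.ndarray, qaly: np.ndarray) -> list[str]:
    """Exhaustive pairwise-and-mixture dominance oracle.

    An option is dominated if some single option is no worse on both axes
    and strictly better on one; otherwise extendedly dominated if some
    convex combination of two options is strictly cheaper-or-equal AND
    strictly more effective (one strict); otherwise on the frontier.
    """
    n = len(cost)
    statuses = []
    for k in range(n):
        dominated = any(
            cost[j] <= cost[k] and qaly[j] >= qaly[k]
            and (cost[j] < cost[k] or qaly[j] > qaly[k])
            for j in range(n) if j != k)
        if dominated:
            statuses.append(DOMINATED)
            continue
        ext = False
        for i in range(n):
            for j in range(n):
                if k in (i, j) or i == j:
                    continue
                for lam in np.linspace(0.0, 1.0, 2001):
                    c = lam * cost[i] + (1 - lam) * cost[j]
                    q = lam * qaly[i] + (1 - lam) * qaly[j]
                    if c <= cost[k] and q >= qaly[k] and (c < cost[k] or q > qaly[k]):
                        ext = True
                        break
                if ext:
                    break
            if ext:
                break
        statuses.append(EXT_DOMINATED if ext else ON_FRONTIER)
    return statuses


def _matrix(costs, qalys, ids=None):
    costs = np.atleast_2d(np.asarray(costs, dtype=float))
    qalys = np.atleast_2d(np.asarray(qalys, dtype=float))
    if ids is None:
        ids = tuple(f"i{j}" for j in range(costs.shape[1]))
    return NetBenefitMatrix(tuple(ids), costs, qalys)


class TestExpectedOutcomes:
    def test_single_draw_is_identity(self):
        m = _matrix([[10.0, 20.0]], [[1.0, 2.0]])
        out = expected_outcomes(m)
        assert list(out.mean_cost) == [10.0, 20.0]
        assert list(out.mean_qaly) == [1.0, 2.0]

    def test_two_symmetric_draws_give_midpoint(self):
        m = _matrix([[10.0], [20.0]], [[1.0], [3.0]])
        out = expected_outcomes(m)
        assert out.mean_cost[0] == 15.0
        assert out.mean_qaly[0] == 2.0

    def test_empty_matrix_rejected(self):
        m = _matrix(np.empty((0, 2)), np.empty((0, 2)))
        with pytest.raises(ValueError):
            expected_outcomes(m)


class TestEfficiencyFrontier:
    def test_single_point_is_frontier_without_icer(self):
        rep = efficiency_frontier(pd.DataFrame(
            {"intervention": ["only"], "mean_cost": [5.0], "mean_qaly": [1.0]}))
        assert rep.frontier == ["only"]
        assert np.isnan(rep.icer_of("only"))

    def test_benchmark_means_give_two_arm_frontier(self):
        # on the reported 14-arm means, only the cheapest NRT arm and
        # low-dose e-cigarettes survive; the e-cigarette ICER is ~£56/QALY
        rep = efficiency_frontier(all_interventions_summary())
        assert rep.frontier == ["nrt_low", "ecig_low"]
        statuses = rep.table.status.value_counts()
        assert statuses[DOMINATED] == 12
        assert rep.icer_of("ecig_low") == pytest.approx((10_279 - 10_259) / (11.290 - 10.934))
        assert round(rep.icer_of("ecig_low")) == 56

    def test_textbook_extended_dominance_case(self):
        # middle option's ICER exceeds the next one's → extendedly dominated
        pts = pd.DataFrame({
            "intervention": ["a", "b", "c"],
            "mean_cost": [0.0, 10.0, 12.0],
            "mean_qaly": [0.0, 0.1, 1.0],
        })
        rep = efficiency_frontier(pts)
        assert rep.status_of("b") == EXT_DOMINATED
        assert rep.frontier == ["a", "c"]
        assert rep.icer_of("c") == pytest.approx(12.0)

    def test_frontier_icers_strictly_increase(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = rng.integers(2, 15)
            pts = pd.DataFrame({
                "intervention": [f"i{j}" for j in range(n)],
                "mean_cost": rng.uniform(0, 100, n),
                "mean_qaly": rng.uniform(0, 10, n),
            })
            rep = efficiency_frontier(pts)
            icers = rep.table.loc[rep.table.status == ON_FRONTIER, "icer"].dropna()
            assert (np.diff(icers) > 0).all() if len(icers) > 1 else True

    @pytest.mark.parametrize("trial", range(25))
    def test_matches_brute_force_oracle_on_random_instances(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(2, 15))
        cost = rng.uniform(0, 100, n)
        qaly = rng.uniform(0, 10, n)
        pts = pd.DataFrame({"intervention": [f"i{j}" for j in range(n)],
                            "mean_cost": cost, "mean_qaly": qaly})
        rep = efficiency_frontier(pts)
        got = rep.table.set_index("intervention").status
        want = brute_force_statuses(cost, qaly)
        for j in range(n):
            assert got[f"i{j}"] == want[j], f"i{j}: {got[f'i{j}']} != {want[j]}"


class TestNetBenefit:
    def test_zero_wtp_is_negative_cost_difference(self):
        m = _matrix([[5.0, 8.0], [7.0, 12.0]], [[1.0, 2.0], [1.5, 2.5]])
        out = net_benefit(m, 0.0, "i0").set_index("intervention")
        assert out.loc["i1", "enb"] == pytest.approx(-( (8 + 12) / 2 - (5 + 7) / 2 ))
        assert out.loc["i0", "enb"] == 0.0

    def test_identical_draws_give_zero_increment(self):
        draws = np.array([[3.0, 3.0], [4.0, 4.0]])
        m = _matrix(draws, draws * 0.1)
        out = net_benefit(m, 10.0, "i0")
        assert np.allclose(out.enb, 0.0)

    def test_four_draw_hand_example(self):
        costs = np.array([[0, 10], [0, 20], [0, 30], [0, 40]], dtype=float)
        qalys = np.array([[0, 1], [0, 2], [0, 3], [0, 4]], dtype=float)
        m = _matrix(costs, qalys)
        out = net_benefit(m, 20.0, "i0").set_index("intervention")
        # per-draw INB for i1: 20q − c = 10, 20, 30, 40 → mean 25, sd 12.9099
        assert out.loc["i1", "enb"] == pytest.approx(25.0)
        se = np.std([10, 20, 30, 40], ddof=1) / 2.0
        assert out.loc["i1", "enb_hi"] - out.loc["i1", "enb"] == \
            pytest.approx(1.959963984540054 * se)

    def test_unknown_reference_rejected(self):
        m = _matrix([[1.0]], [[1.0]])
        with pytest.raises(ValueError, match="nope"):
            net_benefit(m, 1.0, "nope")

    def test_translation_invariance_of_the_optimum(self):
        rng = np.random.default_rng(3)
        m = _matrix(rng.uniform(0, 100, (200, 5)), rng.uniform(0, 10, (200, 5)))
        lam = 30.0
        best_by_mean_nb = np.argmax(m.nb(lam).mean(axis=0))
        for ref in m.intervention_ids:
            out = net_benefit(m, lam, ref)
            assert np.argmax(out.enb.to_numpy()) == best_by_mean_nb


class TestCeac:
    def test_single_intervention_probability_one_everywhere(self):
        m = _matrix([[4.0], [6.0]], [[1.0], [2.0]])
        out = ceac(m, [0, 10, 1000])
        assert np.allclose(out.probability, 1.0)

    def test_two_interventions_step_at_crossover_threshold(self):
        # B costs 10 more and gains 1 QALY → optimal above λ = 10
        m = _matrix([[0.0, 10.0]], [[0.0, 1.0]])
        out = ceac(m, [5.0, 10.0, 15.0]).pivot(index="wtp", columns="intervention",
                                               values="probability")
        assert out.loc[5.0, "i0"] == 1.0
        assert out.loc[15.0, "i1"] == 1.0
        assert out.loc[10.0, "i0"] == 0.5  # exact tie split equally

    def test_curves_sum_to_one_on_default_style_run(self):
        rng = np.random.default_rng(8)
        m = _matrix(rng.uniform(0, 100, (500, 7)), rng.uniform(0, 10, (500, 7)))
        out = ceac(m, np.linspace(0, 50_000, 11))
        sums = out.groupby("wtp").probability.sum()
        assert np.allclose(sums, 1.0, atol=1e-12)


class TestRankogram:
    def test_deterministic_ordering_gives_permutation_matrix(self):
        m = _matrix([[0.0, 0.0, 0.0]], [[3.0, 1.0, 2.0]])
        matrix, summary = rankogram(m, 1.0)
        assert matrix.loc["i0", "rank_1"] == 1.0
        assert matrix.loc["i2", "rank_2"] == 1.0
        assert matrix.loc["i1", "rank_3"] == 1.0
        assert matrix.to_numpy().sum() == pytest.approx(3.0)

    def test_matrix_is_doubly_stochastic(self):
        rng = np.random.default_rng(9)
        m = _matrix(rng.uniform(0, 100, (300, 6)), rng.uniform(0, 10, (300, 6)))
        matrix, _ = rankogram(m, 25.0)
        assert np.allclose(matrix.sum(axis=0), 1.0)
        assert np.allclose(matrix.sum(axis=1), 1.0)

    def test_three_intervention_four_draw_enumeration(self):
        # per-draw NB orderings enumerated by hand (λ = 1, zero costs)
        qalys = np.array([
            [3.0, 2.0, 1.0],   # ranks 1,2,3
            [1.0, 3.0, 2.0],   # ranks 3,1,2
            [2.0, 3.0, 1.0],   # ranks 2,1,3
            [3.0, 2.0, 1.0],   # ranks 1,2,3
        ])
        m = _matrix(np.zeros_like(qalys), qalys)
        matrix, summary = rankogram(m, 1.0)
        want = pd.DataFrame(
            [[0.5, 0.25, 0.25], [0.5, 0.5, 0.0], [0.0, 0.25, 0.75]],
            index=["i0", "i1", "i2"],
            columns=["rank_1", "rank_2", "rank_3"])
        pd.testing.assert_frame_equal(matrix, want, check_names=False)
        med = summary.set_index("intervention").median_rank
        assert med["i0"] == 1.5
        assert med["i1"] == 1.5
        assert med["i2"] == 3.0

    def test_tied_draws_spread_mass_equally(self):
        m = _matrix([[0.0, 0.0]], [[1.0, 1.0]])
        matrix, summary = rankogram(m, 1.0)
        assert np.allclose(matrix.to_numpy(), 0.5)
        assert np.allclose(summary.median_rank, 1.5)
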