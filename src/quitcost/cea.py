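"""Decision outputs from per-draw, per-intervention (cost, QALY) pairs.

Implements the standard cost-effectiveness toolkit: expected outcomes,
the efficiency frontier with strict and extended dominance, sequential
ICERs, incremental expected net benefit against a reference arm,
cost-effectiveness acceptability curves (CEACs), and rank-o-grams with
median rank and interquartile range.

Net benefit at willingness-to-pay λ is NB = QALY·λ − cost, always
recomputed from the stored cost/QALY draws (never cached across λ).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["NetBenefitMatrix", "FrontierReport", "expected_outcomes",
           "efficiency_frontier", "net_benefit", "ceac", "rankogram"]

ON_FRONTIER = "on-frontier"
DOMINATED = "dominated"
EXT_DOMINATED = "extendedly dominated"


@dataclass
class NetBenefitMatrix:
    """draws × interventions cost and QALY matrices (per cohort member)."""

    intervention_ids: tuple[str, ...]
    costs: np.ndarray   # (n_draws, n_interventions), GBP
    qalys: np.ndarray   # (n_draws, n_interventions)

    def __post_init__(self):
        self.costs = np.asarray(self.costs, dtype=float)
        self.qalys = np.asarray(self.qalys, dtype=float)
        if self.costs.shape != self.qalys.shape:
            raise ValueError("cost and QALY matrices must align")
        if self.costs.shape[1] != len(self.intervention_ids):
            raise ValueError("matrix width must match the intervention roster")

    @property
    def n_draws(self) -> int:
        return self.costs.shape[0]

    def nb(self, wtp: float) -> np.ndarray:
        """Net-benefit draws at a willingness-to-pay threshold."""
        return self.qalys * wtp - self.costs

    def subset(self, intervention_ids) -> "NetBenefitMatrix":
        idx = [self.intervention_ids.index(i) for i in intervention_ids]
        return NetBenefitMatrix(tuple(intervention_ids),
                                self.costs[:, idx], self.qalys[:, idx])


@dataclass
class FrontierReport:
    """Interventions ordered by mean cost with dominance status and ICERs.

    ``table`` columns: intervention, mean_cost, mean_qaly, status, icer
    (NaN off the frontier and for the least-cost frontier anchor).
    """

    table: pd.DataFrame

    @property
    def frontier(self) -> list[str]:
        t = self.table
        return list(t.loc[t.status == ON_FRONTIER, "intervention"])

    def status_of(self, intervention: str) -> str:
        return self.table.set_index("intervention").loc[intervention, "status"]

    def icer_of(self, intervention: str) -> float:
        return float(self.table.set_index("intervention").loc[intervention, "icer"])


def expected_outcomes(m: NetBenefitMatrix) -> pd.DataFrame:
    """Per-intervention mean cost and mean QALYs over draws."""
    if m.n_draws < 1:
        raise ValueError("need at least one draw")
    return pd.DataFrame({
        "intervention": list(m.intervention_ids),
        "mean_cost": m.costs.mean(axis=0),
        "mean_qaly": m.qalys.mean(axis=0),
    })


def efficiency_frontier(points: pd.DataFrame) -> FrontierReport:
    """Dominance analysis on per-intervention (mean cost, mean QALY) points.

    Standard algorithm: sort by cost (ties keep the higher-QALY member
    first); mark strictly dominated options (another option is no more
    costly and no less effective, strictly better on one axis); then
    iteratively remove extended dominance until sequential ICERs strictly
    increase. The first (least costly) frontier member has no ICER.
    """
    pts = points.sort_values(["mean_cost", "mean_qaly"],
                             ascending=[True, False], kind="mergesort").reset_index(drop=True)
    n = len(pts)
    cost = pts["mean_cost"].to_numpy()
    qaly = pts["mean_qaly"].to_numpy()
    status = np.array([ON_FRONTIER] * n, dtype=object)

    # strict (simple) dominance, with exact ties collapsing to one label
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if (cost[j] <= cost[i] and qaly[j] >= qaly[i]
                    and (cost[j] < cost[i] or qaly[j] > qaly[i])):
                status[i] = DOMINATED
                break
            if cost[j] == cost[i] and qaly[j] == qaly[i] and j < i:
                status[i] = DOMINATED  # exact tie: keep the first label only
                break

    # extended dominance: enforce increasing sequential ICERs
    while True:
        live = [i for i in range(n) if status[i] == ON_FRONTIER]
        removed = False
        for k in range(1, len(live) - 1):
            prev_i, i, next_i = live[k - 1], live[k], live[k + 1]
            icer_here = (cost[i] - cost[prev_i]) / (qaly[i] - qaly[prev_i])
            icer_next = (cost[next_i] - cost[i]) / (qaly[next_i] - qaly[i])
            if icer_here >= icer_next:
                status[i] = EXT_DOMINATED
                removed = True
                break
        if not removed:
            break

    icers = np.full(n, np.nan)
    live = [i for i in range(n) if status[i] == ON_FRONTIER]
    for k in range(1, len(live)):
        i, prev_i = live[k], live[k - 1]
        icers[i] = (cost[i] - cost[prev_i]) / (qaly[i] - qaly[prev_i])

    pts = pts.assign(status=status, icer=icers)
    return FrontierReport(table=pts)


def net_benefit(
    m: NetBenefitMatrix,
    wtp: float,
    reference: str,
) -> pd.DataFrame:
    """Incremental expected net benefit vs a reference arm, with 95% interval.

    Per draw, INB_i = NB_i − NB_ref; the table reports its mean and the
    normal-approximation 95% interval of that mean (±1.96·SE). The
    reference row is identically zero.
    """
    if reference not in m.intervention_ids:
        raise ValueError(f"unknown reference intervention {reference!r}")
    nb = m.nb(wtp)
    inb = nb - nb[:, [m.intervention_ids.index(reference)]]
    mean = inb.mean(axis=0)
    if m.n_draws > 1:
        se = inb.std(axis=0, ddof=1) / np.sqrt(m.n_draws)
    else:
        se = np.zeros(inb.shape[1])
    z = 1.959963984540054
    return pd.DataFrame({
        "intervention": list(m.intervention_ids),
        "enb": mean,
        "enb_lo": mean - z * se,
        "enb_hi": mean + z * se,
    })


def ceac(m: NetBenefitMatrix, wtp_grid) -> pd.DataFrame:
    """Probability each intervention is optimal at each threshold.

    At every λ, the fraction of draws in which the intervention attains the
    maximum net benefit; exact ties split equally, so the curves sum to one
    at every λ. Returns a long frame (wtp, intervention, probability).
    """
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    if wtp_grid.size == 0:
        raise ValueError("willingness-to-pay grid must be nonempty")
    rows = []
    for lam in wtp_grid:
        nb = m.nb(lam)
        best = nb.max(axis=1, keepdims=True)
        winners = (nb == best).astype(float)
        winners /= winners.sum(axis=1, keepdims=True)
        prob = winners.mean(axis=0)
        for iid, p in zip(m.intervention_ids, prob):
            rows.append({"wtp": lam, "intervention": iid, "probability": p})
    return pd.DataFrame(rows)


def rankogram(m: NetBenefitMatrix, wtp: float) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank-probability matrix plus per-intervention median rank and IQR.

    Rank 1 is the highest net benefit in a draw. Ties receive the mean of
    the tied rank positions, with their probability mass spread equally
    over those positions, keeping the matrix doubly stochastic. Median and
    quartile ranks summarize each intervention's per-draw (mean) ranks.

    Returns (matrix, summary): the matrix frame is interventions × ranks;
    the summary has columns intervention, median_rank, rank_q25, rank_q75.
    """
    from scipy.stats import rankdata

    nb = m.nb(wtp)
    n, k = nb.shape
    avg_ranks = rankdata(-nb, axis=1, method="average")          # (n, k)
    min_ranks = rankdata(-nb, axis=1, method="min").astype(int)
    max_ranks = rankdata(-nb, axis=1, method="max").astype(int)

    prob = np.zeros((k, k))
    span = max_ranks - min_ranks + 1                             # tie-group width
    weight = 1.0 / span
    for i in range(k):
        for r0, r1, w in zip(min_ranks[:, i], max_ranks[:, i], weight[:, i]):
            prob[i, r0 - 1:r1] += w
    prob /= n

    matrix = pd.DataFrame(prob, index=list(m.intervention_ids),
                          columns=[f"rank_{r}" for r in range(1, k + 1)])
    summary = pd.DataFrame({
        "intervention": list(m.intervention_ids),
        "median_rank": np.median(avg_ranks, axis=0),
        "rank_q25": np.percentile(avg_ranks, 25, axis=0),
        "rank_q75": np.percentile(avg_ranks, 75, axis=0),
    })
    return matrix, summary
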