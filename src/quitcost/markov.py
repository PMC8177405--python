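"""Markov cohort engine for a 10,000-smoker quit-attempt cohort.

State space per stratum: smoking status (smoker, or quitter with a
years-since-quit tunnel counter 1–9 and an absorbing ≥10 class) crossed
with disease state (none, or exactly one of five smoking-related
diseases); death is absorbing and tracked separately. Cycle length is one
year (all inputs are annual probabilities) with no half-cycle correction.

Within a cycle, events apply in a fixed order: relapse, disease incidence,
mortality, then counter/age advance. Disease incidence and excess
mortality are scaled by the smoking-status risk ratio (smoker; recent
quitter <5 years; long-term quitter ≥5 years); relapse reclassifies status
immediately. Members age one year per cycle from their band's integer
mean entry age (26 / 50 / 72) and adopt the next age band's rates on
crossing a boundary; at the maximum age (default 100) a stratum stops
transitioning and accruing.

The engine is deterministic expected-value cohort arithmetic (no
microsimulation) and carries an optional leading draw axis so a whole
probabilistic sensitivity analysis runs as vectorized array operations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .params import (
    AGE_BANDS,
    BAND_START_AGE,
    DISEASE_IDS,
    SEXES,
    AdverseEventParams,
    InterventionProfile,
    ParameterSet,
    stratum_key,
)

logger = logging.getLogger(__name__)

__all__ = ["ParamBatch", "CohortTrace", "build_initial_cohort",
           "apply_quit_attempt", "transition", "accrue", "run_cohort",
           "run_cohort_batch", "N_STATUS", "N_DISEASE_STATES"]

N_STATUS = 11          # 0 = smoker, 1..9 = quit-year counter, 10 = quit ≥10 y
N_DISEASE_STATES = 6   # 0 = disease-free, 1..5 = the five diseases
_RECENT_MAX = 4        # quit-year counter <5 → recent quitter

_SEX_IDX = np.array([0, 0, 0, 1, 1, 1])
_BAND0_IDX = np.array([0, 1, 2, 0, 1, 2])
_START_AGE = np.array([BAND_START_AGE[b] for b in AGE_BANDS] * 2)
# risk-ratio class per status: 0 smoker, 1 recent quitter, 2 long-term
_STATUS_CLASS = np.array([0] + [1] * 4 + [2] * 6)


@dataclass
class ParamBatch:
    """Numeric model inputs with a leading draw axis (B,...).

    Built from one ParameterSet (B = 1) or a list of PSA realizations.
    Structural settings (cohort size, discounting, horizon) come from the
    first set — they are policy choices, not sampled quantities.
    """

    n_draws: int
    cohort_size: float
    discount_rate: float
    horizon: int
    shares: np.ndarray           # (S,)
    asc_mort: np.ndarray         # (B, 2, 3) all-cause mortality by sex × band
    base_util: np.ndarray        # (B, 2, 3)
    incidence: np.ndarray        # (B, 5, 2, 3)
    prevalence: np.ndarray       # (B, 5, 2, 3)
    excess_mort: np.ndarray      # (B, 5, 2, 3)
    rr: np.ndarray               # (B, 5, 3) smoker / recent / long-term
    disease_cost: np.ndarray     # (B, 5)
    disease_util: np.ndarray     # (B, 5)
    relapse: np.ndarray          # (B, 3) short / long / 10plus
    ae_disutility_depression: np.ndarray   # (B,)
    ae_cost_depression: np.ndarray
    ae_disutility_selfharm: np.ndarray
    ae_cost_selfharm: np.ndarray
    ae_fatal_fraction: np.ndarray

    @classmethod
    def from_parameter_sets(cls, sets: Sequence[ParameterSet]) -> "ParamBatch":
        B = len(sets)
        first = sets[0]
        S = len(first.strata)
        keys = [stratum_key(s, b) for s in SEXES for b in AGE_BANDS]

        def table(getter) -> np.ndarray:
            out = np.empty((B, 2, 3))
            for i, ps in enumerate(sets):
                vals = getter(ps)
                out[i] = np.array([vals[k] for k in keys]).reshape(2, 3)
            return out

        shares = np.empty(S)
        strata_by_key = {s.key: s for s in first.strata}
        for j, k in enumerate(keys):
            shares[j] = strata_by_key[k].cohort_share

        asc = np.empty((B, 2, 3))
        for i, ps in enumerate(sets):
            by_key = {s.key: s.all_cause_mortality for s in ps.strata}
            asc[i] = np.array([by_key[k] for k in keys]).reshape(2, 3)

        D = len(DISEASE_IDS)
        inc = np.empty((B, D, 2, 3))
        prev = np.empty((B, D, 2, 3))
        exc = np.empty((B, D, 2, 3))
        rr = np.empty((B, D, 3))
        dcost = np.empty((B, D))
        dutil = np.empty((B, D))
        for i, ps in enumerate(sets):
            for d, did in enumerate(DISEASE_IDS):
                dp = ps.diseases[did]
                inc[i, d] = np.array([dp.incidence[k] for k in keys]).reshape(2, 3)
                prev[i, d] = np.array([dp.prevalence[k] for k in keys]).reshape(2, 3)
                exc[i, d] = np.array([dp.excess_mortality[k] for k in keys]).reshape(2, 3)
                rr[i, d] = (dp.rr_smoker, dp.rr_recent_quitter, dp.rr_long_quitter)
                dcost[i, d] = dp.annual_cost
                dutil[i, d] = dp.utility_value

        rel = np.array([[ps.relapse.p_relapse_short, ps.relapse.p_relapse_long,
                         ps.relapse.p_relapse_10plus] for ps in sets])

        def ae_vec(fld: str) -> np.ndarray:
            return np.array([getattr(ps.adverse_events, fld) for ps in sets], dtype=float)

        return cls(
            n_draws=B,
            cohort_size=float(first.economics.cohort_size),
            discount_rate=float(first.economics.discount_rate),
            horizon=int(first.economics.horizon),
            shares=shares,
            asc_mort=asc,
            base_util=table(lambda ps: ps.economics.baseline_utility),
            incidence=inc, prevalence=prev, excess_mort=exc, rr=rr,
            disease_cost=dcost, disease_util=dutil, relapse=rel,
            ae_disutility_depression=ae_vec("disutility_depression"),
            ae_cost_depression=ae_vec("cost_depression"),
            ae_disutility_selfharm=ae_vec("disutility_selfharm"),
            ae_cost_selfharm=ae_vec("cost_selfharm"),
            ae_fatal_fraction=ae_vec("fatal_fraction_selfharm"),
        )

    def band_at(self, cycle: int) -> np.ndarray:
        """Current age-band index per stratum (clipped at the oldest band)."""
        ages = _START_AGE + cycle
        return np.clip(np.searchsorted([35, 65], ages, side="right"), 0, 2)

    def active_at(self, cycle: int) -> np.ndarray:
        """Strata still inside the modelled horizon at this cycle."""
        return (_START_AGE + cycle) <= self.horizon

    def max_cycles(self) -> int:
        return int(self.horizon - _START_AGE.min())

    def gather(self, arr: np.ndarray, cycle: int) -> np.ndarray:
        """(B, 2, 3) sex×band table → (B, S) per-stratum values at a cycle."""
        return arr[:, _SEX_IDX, self.band_at(cycle)]

    def gather_disease(self, arr: np.ndarray, cycle: int) -> np.ndarray:
        """(B, 5, 2, 3) table → (B, 5, S) per-stratum values at a cycle."""
        return arr[:, :, _SEX_IDX, self.band_at(cycle)]


@dataclass
class CohortTrace:
    """Per-cycle record of a single cohort run.

    ``occupancy`` has shape (n_cycles+1, S, N_STATUS, N_DISEASE_STATES)
    when kept; cost/QALY vectors are indexed by cycle (entry 0 is zero —
    accrual starts in cycle 1, which also carries the one-off intervention
    cost and adverse-event consequences).
    """

    occupancy: np.ndarray | None
    deaths: np.ndarray               # (n_cycles+1, S)
    cost_undiscounted: np.ndarray    # (n_cycles+1,)
    cost_discounted: np.ndarray
    qaly_undiscounted: np.ndarray
    qaly_discounted: np.ndarray
    clamp_warnings: int = 0

    @property
    def n_cycles(self) -> int:
        return len(self.cost_discounted) - 1

    def conservation_error(self, initial_size: float) -> float:
        """Worst |occupancy + deaths − initial size| over all cycles."""
        if self.occupancy is None:
            raise ValueError("trace was run without occupancy snapshots")
        totals = self.occupancy.sum(axis=(1, 2, 3)) + self.deaths.sum(axis=1)
        return float(np.max(np.abs(totals - initial_size)))

    def to_frame(self):
        """Tidy per-cycle export (cycle, stratum, status, disease, occupancy)."""
        import pandas as pd

        if self.occupancy is None:
            raise ValueError("trace was run without occupancy snapshots")
        cyc, s, t, d = np.indices(self.occupancy.shape)
        keys = [stratum_key(sx, b) for sx in SEXES for b in AGE_BANDS]
        status = ["smoker"] + [f"quit_y{i}" for i in range(1, 10)] + ["quit_10plus"]
        disease = ["none", *DISEASE_IDS]
        return pd.DataFrame({
            "cycle": cyc.ravel(),
            "stratum": np.array(keys)[s.ravel()],
            "status": np.array(status)[t.ravel()],
            "disease": np.array(disease)[d.ravel()],
            "occupancy": self.occupancy.ravel(),
        })


# ---------------------------------------------------------------------------
# engine steps (all batched: occupancy is (B, S, N_STATUS, N_DISEASE_STATES))
# ---------------------------------------------------------------------------


def build_initial_cohort(batch: ParamBatch) -> np.ndarray:
    """Cycle-0 occupancy: all smokers, allocated by share and prevalence."""
    B, S = batch.n_draws, len(batch.shares)
    occ = np.zeros((B, S, N_STATUS, N_DISEASE_STATES))
    n_s = batch.shares * batch.cohort_size                      # (S,)
    prev = batch.gather_disease(batch.prevalence, 0)            # (B, 5, S)
    total = prev.sum(axis=1)                                    # (B, S)
    scale = np.where(total > 1.0, 1.0 / np.maximum(total, 1e-300), 1.0)
    prev = prev * scale[:, None, :]
    occ[:, :, 0, 1:] = (prev * n_s[None, None, :]).transpose(0, 2, 1)
    occ[:, :, 0, 0] = n_s[None, :] * (1.0 - prev.sum(axis=1))
    return occ


def apply_quit_attempt(
    occ: np.ndarray,
    deaths: np.ndarray,
    batch: ParamBatch,
    p_abstain: np.ndarray,
    p_depression: np.ndarray,
    p_selfharm: np.ndarray,
    course_cost: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """First-cycle intervention effects on the whole treated cohort.

    Fatal self-harm kills ``fatal_fraction × p_selfharm`` of every state;
    depression and nonfatal self-harm generate one-off costs and QALY
    decrements proportional to the treated cohort; the abstaining fraction
    of surviving smokers enters the quit tunnel at counter 1; the course
    cost is charged once per treated member. Returns the cycle-1 occupancy,
    updated deaths, and the (undiscounted) one-off cost and QALY loss.
    """
    n_treated = occ.sum(axis=(1, 2, 3))                          # (B,)
    dep_events = n_treated * p_depression
    sh_fatal_frac = p_selfharm * batch.ae_fatal_fraction
    sh_nonfatal = n_treated * p_selfharm * (1.0 - batch.ae_fatal_fraction)

    event_cost = (course_cost * n_treated
                  + dep_events * batch.ae_cost_depression
                  + sh_nonfatal * batch.ae_cost_selfharm)
    event_qaly_loss = (dep_events * batch.ae_disutility_depression
                       + sh_nonfatal * batch.ae_disutility_selfharm)

    per_stratum = occ.sum(axis=(2, 3))                           # (B, S)
    occ = occ * (1.0 - sh_fatal_frac)[:, None, None, None]
    deaths = deaths + per_stratum * sh_fatal_frac[:, None]

    moved = occ[:, :, 0, :] * p_abstain[:, None, None]
    occ[:, :, 1, :] += moved
    occ[:, :, 0, :] -= moved
    return occ, deaths, event_cost, event_qaly_loss


def transition(
    occ: np.ndarray,
    deaths: np.ndarray,
    batch: ParamBatch,
    cycle: int,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Advance one cycle: relapse → incidence → mortality → counters.

    Probabilities that exceed 1 after risk-ratio scaling are clamped, and
    the number of clamped cells is returned for warning accounting. Strata
    past the modelled horizon are frozen (no transitions).
    """
    B, S = occ.shape[:2]
    active = batch.active_at(cycle).astype(float)                # (S,)
    clamps = 0

    # 1) relapse: quitters revert to smoking by tunnel class
    rel_by_status = np.zeros((B, N_STATUS))
    rel_by_status[:, 1:5] = batch.relapse[:, [0]]
    rel_by_status[:, 5:10] = batch.relapse[:, [1]]
    rel_by_status[:, 10] = batch.relapse[:, 2]
    rel = rel_by_status[:, None, :, None] * active[None, :, None, None]
    moved = occ * rel
    occ = occ - moved
    occ[:, :, 0, :] += moved.sum(axis=2)

    # 2) incidence among the disease-free, scaled by smoking-status RR
    inc_rates = batch.gather_disease(batch.incidence, cycle)     # (B, 5, S)
    rr_status = batch.rr[:, :, _STATUS_CLASS]                    # (B, 5, T)
    p_inc = inc_rates[:, :, :, None] * rr_status[:, :, None, :]  # (B, 5, S, T)
    p_inc = p_inc * active[None, None, :, None]
    total = p_inc.sum(axis=1)                                    # (B, S, T)
    over = total > 1.0
    if over.any():
        clamps += int(over.sum())
        p_inc = p_inc * np.where(over, 1.0 / np.maximum(total, 1e-300), 1.0)[:, None, :, :]
    new_cases = occ[:, :, :, 0][:, None, :, :] * p_inc           # (B, 5, S, T)
    occ[:, :, :, 1:] += new_cases.transpose(0, 2, 3, 1)
    occ[:, :, :, 0] -= new_cases.sum(axis=1)

    # 3) mortality: background plus RR-scaled disease excess
    asc = batch.gather(batch.asc_mort, cycle)                    # (B, S)
    exc = batch.gather_disease(batch.excess_mort, cycle)         # (B, 5, S)
    p_die = np.empty((B, S, N_STATUS, N_DISEASE_STATES))
    p_die[...] = asc[:, :, None, None]
    p_die[:, :, :, 1:] += (exc[:, :, :, None] * rr_status[:, :, None, :]).transpose(0, 2, 3, 1)
    over = p_die > 1.0
    if over.any():
        clamps += int(over.sum())
        p_die = np.minimum(p_die, 1.0)
    p_die = p_die * active[None, :, None, None]
    dying = occ * p_die
    deaths = deaths + dying.sum(axis=(2, 3))
    occ = occ - dying

    # 4) advance quit-year counters (10+ is absorbing)
    occ[:, :, 10, :] += occ[:, :, 9, :]
    for t in range(9, 1, -1):
        occ[:, :, t, :] = occ[:, :, t - 1, :]
    occ[:, :, 1, :] = 0.0
    return occ, deaths, clamps


def accrue(
    occ: np.ndarray,
    batch: ParamBatch,
    cycle: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Annual cost and QALY of the post-transition occupancy.

    Disease-free members accrue the stratum's baseline utility at their
    current age band; diseased members accrue the disease utility and
    annual cost. Returns (cost, qaly) both undiscounted and discounted at
    (1 + r)^(−cycle). Strata past the horizon accrue nothing.
    """
    active = batch.active_at(cycle).astype(float)
    by_disease = occ[:, :, :, 1:].sum(axis=2)                    # (B, S, 5)
    by_disease = by_disease * active[None, :, None]
    cost = (by_disease * batch.disease_cost[:, None, :]).sum(axis=(1, 2))

    healthy = occ[:, :, :, 0].sum(axis=2) * active[None, :]      # (B, S)
    util = batch.gather(batch.base_util, cycle)                  # (B, S)
    qaly = (healthy * util).sum(axis=1)
    qaly = qaly + (by_disease * batch.disease_util[:, None, :]).sum(axis=(1, 2))

    df = (1.0 + batch.discount_rate) ** (-cycle)
    return cost, qaly, cost * df, qaly * df


# ---------------------------------------------------------------------------
# full runs
# ---------------------------------------------------------------------------


def _simulate(
    batch: ParamBatch,
    p_abstain: np.ndarray,
    p_depression: np.ndarray,
    p_selfharm: np.ndarray,
    course_cost: np.ndarray,
    max_cycles: int | None = None,
    keep_trace: bool = False,
) -> tuple[np.ndarray, np.ndarray, CohortTrace | None]:
    """Run the cohort to extinction or the horizon; totals are per member."""
    n_cycles = batch.max_cycles() if max_cycles is None else int(max_cycles)
    B, S = batch.n_draws, len(batch.shares)

    occ = build_initial_cohort(batch)
    deaths = np.zeros((B, S))
    cost_u = np.zeros((B, n_cycles + 1))
    cost_d = np.zeros((B, n_cycles + 1))
    qaly_u = np.zeros((B, n_cycles + 1))
    qaly_d = np.zeros((B, n_cycles + 1))
    snapshots = [occ.copy()] if keep_trace else None
    death_track = [deaths.copy()] if keep_trace else None
    clamp_total = 0

    occ, deaths, ev_cost, ev_qaly_loss = apply_quit_attempt(
        occ, deaths, batch, p_abstain, p_depression, p_selfharm, course_cost)
    df1 = (1.0 + batch.discount_rate) ** (-1.0)
    c_u, q_u, c_d, q_d = accrue(occ, batch, 1)
    cost_u[:, 1] = c_u + ev_cost
    qaly_u[:, 1] = q_u - ev_qaly_loss
    cost_d[:, 1] = c_d + ev_cost * df1
    qaly_d[:, 1] = q_d - ev_qaly_loss * df1
    if keep_trace:
        snapshots.append(occ.copy())
        death_track.append(deaths.copy())

    for cycle in range(1, n_cycles):
        occ, deaths, clamps = transition(occ, deaths, batch, cycle)
        clamp_total += clamps
        c_u, q_u, c_d, q_d = accrue(occ, batch, cycle + 1)
        cost_u[:, cycle + 1] = c_u
        qaly_u[:, cycle + 1] = q_u
        cost_d[:, cycle + 1] = c_d
        qaly_d[:, cycle + 1] = q_d
        if keep_trace:
            snapshots.append(occ.copy())
            death_track.append(deaths.copy())
        if occ.sum() < 1e-9:
            break

    if clamp_total:
        logger.warning("clamped %d transition probabilities above 1", clamp_total)
    survivors = occ.sum()
    if survivors > 1e-6:
        logger.info("horizon reached with %.1f survivors (per batch)", survivors)

    n_kept = len(snapshots) if keep_trace else n_cycles + 1
    trace = None
    if keep_trace:
        trace = CohortTrace(
            occupancy=np.stack([s[0] for s in snapshots]) if B == 1
            else np.stack(snapshots),
            deaths=np.stack([d[0] for d in death_track]) if B == 1
            else np.stack(death_track),
            cost_undiscounted=cost_u[0, :n_kept] if B == 1 else cost_u[:, :n_kept],
            cost_discounted=cost_d[0, :n_kept] if B == 1 else cost_d[:, :n_kept],
            qaly_undiscounted=qaly_u[0, :n_kept] if B == 1 else qaly_u[:, :n_kept],
            qaly_discounted=qaly_d[0, :n_kept] if B == 1 else qaly_d[:, :n_kept],
            clamp_warnings=clamp_total,
        )
    total_cost = cost_d.sum(axis=1) / batch.cohort_size
    total_qaly = qaly_d.sum(axis=1) / batch.cohort_size
    return total_cost, total_qaly, trace


def run_cohort(
    profile: InterventionProfile,
    ps: ParameterSet,
    max_cycles: int | None = None,
    keep_trace: bool = True,
) -> tuple[float, float, CohortTrace | None]:
    """Lifetime run for one intervention under one parameter set.

    Returns (discounted cost per member, discounted QALYs per member,
    trace). ``max_cycles`` overrides the age-based horizon for analytic
    limit checks.
    """
    batch = ParamBatch.from_parameter_sets([ps])
    one = lambda x: np.array([float(x)])
    cost, qaly, trace = _simulate(
        batch, one(profile.p_abstain), one(profile.p_depression),
        one(profile.p_selfharm), one(profile.course_cost),
        max_cycles=max_cycles, keep_trace=keep_trace)
    return float(cost[0]), float(qaly[0]), trace


def run_cohort_batch(
    batch: ParamBatch,
    profile_arrays: Mapping[str, np.ndarray],
    max_cycles: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Batched lifetime run: draw-length (cost, QALY) per-member vectors."""
    cost, qaly, _ = _simulate(
        batch,
        np.asarray(profile_arrays["p_abstain"], dtype=float),
        np.asarray(profile_arrays["p_depression"], dtype=float),
        np.asarray(profile_arrays["p_selfharm"], dtype=float),
        np.asarray(profile_arrays["course_cost"], dtype=float),
        max_cycles=max_cycles, keep_trace=False)
    return cost, qaly
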