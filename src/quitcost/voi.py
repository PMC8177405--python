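"""Expected value of (partial) perfect information from PSA output.

EVPI is computed directly from the net-benefit draws:
E[max_i NB_i] − max_i E[NB_i]. EVPPI for a parameter subset uses a
regression metamodel: for each intervention, the conditional expectation
of its net benefit given the subset is estimated with an additive cubic
B-spline smooth (subsets of up to four parameters) or, for larger
subsets, the same smooth on the leading principal components of the
standardized parameter draws. EVPPI is then
mean(max_i fitted_i) − max_i(mean fitted_i), clipped at zero.

Population figures scale per-person values by the annual number of
quit attempts and an undiscounted 1–5 year horizon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import EconomicParams

logger = logging.getLogger(__name__)

__all__ = ["evpi", "evppi", "population_voi", "voi_report", "VoiReport",
           "DEFAULT_SUBSETS"]

_MAX_ADDITIVE_PARAMS = 32  # beyond this, fall back to a principal-component smooth
_PCA_COMPONENTS = 8


def _spline_df(n_params: int) -> int:
    """Basis size per regressor: richer for small subsets, leaner for large
    ones to keep the observations-per-coefficient ratio healthy."""
    return 6 if n_params <= 4 else 4


def evpi(m, wtp: float) -> float:
    """Per-person expected value of perfect information (GBP).

    The expected gain from resolving all parameter uncertainty before
    choosing: mean over draws of the per-draw best net benefit, minus the
    net benefit of the on-average best intervention. Non-negative by
    Jensen's inequality.
    """
    if m.n_draws < 2:
        raise ValueError("EVPI needs at least two draws")
    nb = m.nb(wtp)
    return float(nb.max(axis=1).mean() - nb.mean(axis=0).max())


def population_voi(per_person: float, population: int, years: int) -> float:
    """Population value in £ million: per-person × population × years / 1e6.

    Undiscounted across the 1–5-year relevance horizon; report tables round
    to the nearest million.
    """
    if population <= 0 or years <= 0:
        raise ValueError("population and years must be positive")
    return per_person * population * years / 1e6


def _spline_basis(x: np.ndarray, df: int) -> np.ndarray:
    """Cubic B-spline design columns for one standardized regressor."""
    from statsmodels.gam.smooth_basis import BSplines

    bs = BSplines(x.reshape(-1, 1), df=[df], degree=[3], include_intercept=False)
    return bs.basis


def _metamodel_design(params: np.ndarray) -> np.ndarray:
    """Additive spline design over every subset column (PCA only as a
    fallback for very large subsets, where the additive basis would
    outgrow the draw count)."""
    x = np.asarray(params, dtype=float)
    if x.ndim == 1:
        x = x.reshape(-1, 1)
    sd = x.std(axis=0)
    keep = sd > 1e-12
    x = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    if x.shape[1] == 0:
        return np.ones((len(params), 1))
    if x.shape[1] > _MAX_ADDITIVE_PARAMS:
        # principal-component smooth: spline basis on the leading components
        from sklearn.decomposition import PCA

        x = PCA(n_components=_PCA_COMPONENTS, svd_solver="full").fit_transform(x)
        x = (x - x.mean(axis=0)) / x.std(axis=0)
    df = _spline_df(x.shape[1])
    cols = [np.ones((x.shape[0], 1))]
    cols.extend(_spline_basis(x[:, j], df) for j in range(x.shape[1]))
    return np.hstack(cols)


def evppi(m, parameter_draws, wtp: float) -> float:
    """Per-person expected value of perfect information on a parameter subset.

    ``parameter_draws`` is a draws × subset array (or DataFrame) row-aligned
    with the net-benefit draws. Constant or empty subsets carry no
    information and return 0. The estimate is a regression-metamodel
    approximation and inherits smoother bias; it is clipped at zero.
    """
    x = np.asarray(parameter_draws, dtype=float)
    if x.ndim == 1:
        x = x.reshape(-1, 1)
    if x.shape[0] != m.n_draws:
        raise ValueError("parameter draws must be row-aligned with the net-benefit draws")
    if x.shape[1] == 0 or np.all(x.std(axis=0) <= 1e-12):
        logger.info("EVPPI subset is empty or constant; returning 0")
        return 0.0

    nb = m.nb(wtp)
    design = _metamodel_design(x)
    fitted = np.empty_like(nb)
    for j in range(nb.shape[1]):
        y = nb[:, j]
        if y.std() <= 1e-12:
            fitted[:, j] = y
            continue
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        fitted[:, j] = design @ coef
    value = fitted.max(axis=1).mean() - fitted.mean(axis=0).max()
    return float(max(value, 0.0))


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

#: Named parameter subsets of the standard report, as column selectors over
#: the PSA parameter frame (prefix match on dotted paths). The two
#: "head-to-head" rows restrict the decision to standard NRT vs standard
#: varenicline before computing EVPPI, mirroring the value of a trial
#: comparing the two leading arms.
DEFAULT_SUBSETS: dict[str, dict] = {
    "all_costs": {"contains": ("annual_cost", "adverse_events.cost_")},
    "all_utilities": {"contains": ("utility_value", "disutility_", "baseline_utility.")},
    "all_costs_and_utilities": {"contains": ("annual_cost", "adverse_events.cost_",
                                             "utility_value", "disutility_",
                                             "baseline_utility.")},
    "all_abstinence_probabilities": {"contains": ("p_abstain", "log_or_abstinence.")},
    "all_mane_probabilities": {"contains": ("p_depression", "p_selfharm",
                                            "log_or_mane.")},
    "head_to_head_probs_costs_utilities": {
        "contains": ("p_abstain", "p_depression", "p_selfharm",
                     "annual_cost", "adverse_events.cost_", "utility_value",
                     "disutility_", "baseline_utility."),
        "columns": ("log_or_abstinence.varenicline_std", "log_or_mane.varenicline_std"),
        "restrict": ("nrt_std", "varenicline_std")},
    "head_to_head_probs_only": {
        "contains": ("p_abstain", "p_depression", "p_selfharm"),
        "columns": ("log_or_abstinence.varenicline_std", "log_or_mane.varenicline_std"),
        "restrict": ("nrt_std", "varenicline_std")},
}


def _select_columns(frame: pd.DataFrame, selector: dict) -> list[str]:
    cols: list[str] = [c for c in selector.get("columns", ()) if c in frame.columns]
    for c in frame.columns:
        if any(c.startswith(p) for p in selector.get("prefixes", ())):
            cols.append(c)
        elif any(token in c for token in selector.get("contains", ())):
            cols.append(c)
    return sorted(set(cols))


@dataclass
class VoiReport:
    """EVPI/EVPPI table: per-person £ and 1-/5-year population £ million."""

    wtp: float
    table: pd.DataFrame
    subset_columns: dict[str, list[str]] = field(default_factory=dict)


def voi_report(
    m,
    parameter_frame: pd.DataFrame,
    economics: EconomicParams,
    subsets: dict[str, dict] | None = None,
    wtp: float | None = None,
) -> VoiReport:
    """The standard value-of-information table.

    First row: total EVPI. Then one EVPPI row per named subset, each with
    per-person value and undiscounted 1- and 5-year population scalings
    (rounded to the nearest £ million in the population columns).
    """
    if subsets is None:
        subsets = DEFAULT_SUBSETS
    if wtp is None:
        wtp = economics.wtp
    pop = economics.population_per_year

    rows = []
    used: dict[str, list[str]] = {}

    def add_row(name: str, per_person: float):
        rows.append({
            "subset": name,
            "per_person_gbp": per_person,
            "population_1y_million": round(population_voi(per_person, pop, 1)),
            "population_5y_million": round(population_voi(per_person, pop, 5)),
        })

    total = evpi(m, wtp)
    add_row("all (EVPI)", total)

    for name, selector in subsets.items():
        cols = _select_columns(parameter_frame, selector)
        if not cols:
            raise KeyError(f"subset {name!r} selects no sampled parameters")
        used[name] = cols
        target = m
        if "restrict" in selector:
            target = m.subset(selector["restrict"])
        add_row(name, evppi(target, parameter_frame[cols].to_numpy(), wtp))

    return VoiReport(wtp=wtp, table=pd.DataFrame(rows), subset_columns=used)
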