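"""Map baseline standard-NRT risks and relative-effect draws to profiles.

Relative treatment effects from the network meta-analysis are applied on
the log-odds scale: p = expit(logit(p_base) + log OR). This is the
standard mapping for binary-outcome NMA and keeps every mapped probability
inside (0, 1); a risk-ratio alternative is available for sensitivity.

Interventions without observed neuropsychiatric-harm (MANE) evidence
inherit a donor arm's draw column, preserving cross-draw correlation:
low-dose NRT and low-dose e-cigarettes share standard NRT's harms (same
active ingredient), high-dose e-cigarettes share high-dose NRT's, low-dose
bupropion shares standard bupropion's, and varenicline low + NRT standard
shares varenicline standard + NRT standard's. One pooled MANE effect
drives both the depression and the self-harm probability.
"""

from __future__ import annotations

import numpy as np
from scipy import special

from .params import (
    INTERVENTIONS,
    LICENSED_INTERVENTIONS,
    REFERENCE_INTERVENTION,
    BaselineRisks,
    InterventionProfile,
    RelativeEffectSlice,
)
from .synthetic import RelativeEffects

__all__ = [
    "DEFAULT_HARM_MAP",
    "HarmMappingError",
    "apply_relative_effect",
    "apply_relative_risk",
    "resolve_mane_column",
    "resolve_mane_log_or",
    "build_profiles",
]

#: intervention lacking MANE evidence → donor intervention whose draws it shares
DEFAULT_HARM_MAP: dict[str, str] = {
    "nrt_low": "nrt_std",
    "ecig_low": "nrt_std",
    "ecig_high": "nrt_high",
    "bupropion_low": "bupropion_std",
    "varenicline_low_nrt_std": "varenicline_std_nrt_std",
}


class HarmMappingError(KeyError):
    """An intervention has neither observed MANE evidence nor a donor."""


def apply_relative_effect(p_base, log_or):
    """Apply a log odds ratio to a baseline probability (vectorized).

    Returns expit(logit(p_base) + log_or); strictly increasing in log_or
    and exactly invertible by negating the log-OR.
    """
    p_base = np.asarray(p_base, dtype=float)
    if np.any((p_base <= 0.0) | (p_base >= 1.0)):
        raise ValueError("p_base must lie strictly inside (0, 1)")
    log_or = np.asarray(log_or, dtype=float)
    mapped = special.expit(special.logit(p_base) + log_or)
    # a null effect is the exact identity (reference-arm fixed point)
    out = np.where(log_or == 0.0, p_base, mapped)
    return float(out) if out.ndim == 0 else out


def apply_relative_risk(p_base, log_rr):
    """Risk-ratio alternative (sensitivity only): p_base·exp(log_rr), capped <1."""
    p_base = np.asarray(p_base, dtype=float)
    if np.any((p_base <= 0.0) | (p_base >= 1.0)):
        raise ValueError("p_base must lie strictly inside (0, 1)")
    out = np.minimum(p_base * np.exp(np.asarray(log_rr, dtype=float)), 1.0 - 1e-12)
    return float(out) if out.ndim == 0 else out


def resolve_mane_column(
    intervention_id: str,
    effects: RelativeEffects,
    harm_map: dict[str, str] | None = None,
) -> np.ndarray:
    """The MANE log-OR draw vector for one intervention.

    The intervention's own column when observed, else its donor's column
    (shared draws — correlation with the donor is preserved by
    construction).
    """
    if harm_map is None:
        harm_map = DEFAULT_HARM_MAP
    if intervention_id not in effects.intervention_ids:
        raise HarmMappingError(f"unknown intervention {intervention_id!r}")
    if intervention_id in effects.mane_observed:
        return effects.log_or_mane[:, effects.column(intervention_id)]
    donor = harm_map.get(intervention_id)
    if donor is None:
        raise HarmMappingError(
            f"no MANE evidence and no harm-assumption donor for {intervention_id!r}")
    if donor not in effects.mane_observed:
        raise HarmMappingError(
            f"donor {donor!r} for {intervention_id!r} has no observed MANE column")
    return effects.log_or_mane[:, effects.column(donor)]


def resolve_mane_log_or(
    intervention_id: str,
    slice_: RelativeEffectSlice,
    harm_map: dict[str, str] | None = None,
) -> float:
    """Single-draw counterpart of :func:`resolve_mane_column`."""
    if harm_map is None:
        harm_map = DEFAULT_HARM_MAP
    v = slice_.log_or_mane.get(intervention_id)
    if v is not None:
        return v
    donor = harm_map.get(intervention_id)
    if donor is None:
        raise HarmMappingError(
            f"no MANE evidence and no harm-assumption donor for {intervention_id!r}")
    dv = slice_.log_or_mane.get(donor)
    if dv is None:
        raise HarmMappingError(
            f"donor {donor!r} for {intervention_id!r} has no observed MANE value")
    return dv


def build_profiles(
    slice_: RelativeEffectSlice,
    baseline: BaselineRisks,
    course_costs: dict[str, float],
    harm_map: dict[str, str] | None = None,
    scale: str = "odds",
) -> list[InterventionProfile]:
    """One-year event profiles for the full 14-intervention roster.

    The reference arm (standard NRT) reproduces the baseline risks exactly;
    every other arm maps the baselines through its abstinence log-OR and
    its (own or donated) MANE log-OR. The single MANE effect is applied
    separately to the depression and the self-harm baseline.
    """
    mapper = apply_relative_effect if scale == "odds" else apply_relative_risk
    profiles = []
    for iid in INTERVENTIONS:
        if iid not in slice_.log_or_abstinence:
            raise HarmMappingError(f"missing abstinence effect for {iid!r}")
        lor_a = slice_.log_or_abstinence[iid]
        lor_m = resolve_mane_log_or(iid, slice_, harm_map)
        profiles.append(InterventionProfile(
            intervention_id=iid,
            licensed=iid in LICENSED_INTERVENTIONS,
            course_cost=course_costs[iid],
            p_abstain=mapper(baseline.p_abstain_nrt_std, lor_a),
            p_depression=mapper(baseline.p_depression_nrt_std, lor_m),
            p_selfharm=mapper(baseline.p_selfharm_nrt_std, lor_m),
        ))
    return profiles


def build_profile_arrays(
    effects: RelativeEffects,
    p_abstain_base: np.ndarray,
    p_depression_base: np.ndarray,
    p_selfharm_base: np.ndarray,
    course_costs: dict[str, float],
    harm_map: dict[str, str] | None = None,
) -> dict[str, dict[str, np.ndarray]]:
    """Batched profiles: per intervention, draw-length probability vectors.

    Baselines may themselves vary by draw (PSA-sampled). Used by the
    pipeline to feed the draw-batched Markov engine.
    """
    out: dict[str, dict[str, np.ndarray]] = {}
    for j, iid in enumerate(effects.intervention_ids):
        lor_a = effects.log_or_abstinence[:, j]
        lor_m = resolve_mane_column(iid, effects, harm_map)
        out[iid] = {
            "p_abstain": apply_relative_effect(p_abstain_base, lor_a),
            "p_depression": apply_relative_effect(p_depression_base, lor_m),
            "p_selfharm": apply_relative_effect(p_selfharm_base, lor_m),
            "course_cost": np.full_like(lor_a, course_costs[iid]),
        }
    return out
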