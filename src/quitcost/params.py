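"""Domain types, validation, and parameter-file I/O.

Every symbol the pipeline consumes lives here: the cohort strata, the five
smoking-related disease blocks (COPD, lung cancer, coronary heart disease,
stroke, asthma), baseline risks on standard-dose nicotine replacement
therapy (NRT), relapse probabilities by years since quitting, one-off
adverse-event consequences, economic settings, and a realized slice of the
network-meta-analysis relative effects.

All probabilities are annual, all monetary values GBP at 2019 prices.
Parameter files are single YAML documents; see ``docs/parameter_schema.md``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

__all__ = [
    "SEXES",
    "AGE_BANDS",
    "STRATUM_KEYS",
    "DISEASE_IDS",
    "LICENSED_INTERVENTIONS",
    "UNLICENSED_INTERVENTIONS",
    "INTERVENTIONS",
    "REFERENCE_INTERVENTION",
    "BAND_START_AGE",
    "Stratum",
    "DiseaseParams",
    "BaselineRisks",
    "RelapseParams",
    "AdverseEventParams",
    "EconomicParams",
    "InterventionProfile",
    "RelativeEffectSlice",
    "ParameterSet",
    "Violation",
    "SchemaError",
    "ValidationError",
    "validate",
    "load_parameters",
    "write_parameters",
    "stratum_key",
]

SEXES = ("male", "female")
AGE_BANDS = ("18-34", "35-64", "65+")

#: integer mean age assigned to every member of a band at cohort entry;
#: drives annual ageing and band-boundary crossing in the Markov engine
BAND_START_AGE = {"18-34": 26, "35-64": 50, "65+": 72}

_BAND_TOKEN = {"18-34": "18_34", "35-64": "35_64", "65+": "65_plus"}
_TOKEN_BAND = {v: k for k, v in _BAND_TOKEN.items()}


def stratum_key(sex: str, age_band: str) -> str:
    """Canonical flat key for a (sex, age band) stratum, e.g. ``male_18_34``."""
    return f"{sex}_{_BAND_TOKEN[age_band]}"


STRATUM_KEYS = tuple(stratum_key(s, b) for s in SEXES for b in AGE_BANDS)

DISEASE_IDS = ("copd", "lung_cancer", "chd", "stroke", "asthma")

LICENSED_INTERVENTIONS = (
    "nrt_low",
    "nrt_std",
    "nrt_high",
    "bupropion_low",
    "bupropion_std",
    "varenicline_low",
    "varenicline_std",
)
UNLICENSED_INTERVENTIONS = (
    "ecig_low",
    "ecig_high",
    "bupropion_std_nrt_high",
    "varenicline_low_nrt_std",
    "varenicline_std_nrt_std",
    "varenicline_std_nrt_high",
    "varenicline_std_bupropion_std",
)
#: the full 14-intervention roster: 7 licensed, 2 e-cigarette, 5 combinations
INTERVENTIONS = LICENSED_INTERVENTIONS + UNLICENSED_INTERVENTIONS

#: baseline-risk reference; relative effects are log odds ratios vs this arm
REFERENCE_INTERVENTION = "nrt_std"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Stratum:
    """One sex × age-band cohort cell.

    ``cohort_share`` is the fraction of the 10,000-smoker cohort starting in
    this cell; shares sum to one across the six strata.
    ``all_cause_mortality`` is the annual background death probability.
    """

    sex: str
    age_band: str
    cohort_share: float
    all_cause_mortality: float

    @property
    def key(self) -> str:
        return stratum_key(self.sex, self.age_band)


@dataclass
class DiseaseParams:
    """Epidemiology, cost, and utility of one smoking-related disease.

    ``incidence`` / ``prevalence`` / ``excess_mortality`` map stratum key →
    annual probability (prevalence: proportion of the smoking cohort that
    starts in the disease state). The three risk ratios scale incidence and
    excess mortality for smokers, recent quitters (<5 years since quitting)
    and long-term quitters (≥5 years) relative to the never-smoker reference.
    """

    disease_id: str
    incidence: dict[str, float]
    prevalence: dict[str, float]
    excess_mortality: dict[str, float]
    rr_smoker: float
    rr_recent_quitter: float
    rr_long_quitter: float
    annual_cost: float
    utility_value: float


@dataclass
class BaselineRisks:
    """One-year event probabilities on standard-dose NRT (the reference arm)."""

    p_abstain_nrt_std: float
    p_depression_nrt_std: float
    p_selfharm_nrt_std: float


@dataclass
class RelapseParams:
    """Annual relapse probabilities by years since quitting (<5, 5–10, ≥10)."""

    p_relapse_short: float
    p_relapse_long: float
    p_relapse_10plus: float


@dataclass
class AdverseEventParams:
    """One-off consequences of intervention-attributable depression/self-harm.

    Depression and nonfatal self-harm carry a one-off cost and QALY
    decrement in the intervention year; a fraction of self-harm events is
    fatal and moves cohort members to the dead state.
    """

    disutility_depression: float
    cost_depression: float
    disutility_selfharm: float
    cost_selfharm: float
    fatal_fraction_selfharm: float


@dataclass
class EconomicParams:
    """Discounting, decision threshold, cohort and PSA sizes.

    ``horizon`` is the maximum age simulated (cohort members alive at that
    age stop accruing); ``baseline_utility`` maps stratum key → utility
    weight of a disease-free smoker.
    """

    discount_rate: float = 0.035
    wtp: float = 20_000.0
    population_per_year: int = 274_021
    cohort_size: int = 10_000
    psa_draws: int = 5_000
    horizon: int = 100
    baseline_utility: dict[str, float] = field(default_factory=dict)


@dataclass
class InterventionProfile:
    """Per-intervention one-year probabilities plus the one-off course cost."""

    intervention_id: str
    licensed: bool
    course_cost: float
    p_abstain: float
    p_depression: float
    p_selfharm: float


@dataclass
class RelativeEffectSlice:
    """One realized draw (or the deterministic means) of the relative effects.

    Log odds ratios vs standard-dose NRT. ``log_or_mane`` entries are None
    for interventions without observed neuropsychiatric-harm evidence; the
    effect-mapping stage fills them from donor arms (see HarmAssumptionMap).
    """

    log_or_abstinence: dict[str, float]
    log_or_mane: dict[str, float | None]


@dataclass
class ParameterSet:
    """One complete, internally consistent set of model inputs.

    Either the deterministic means or a single probabilistic-sensitivity-
    analysis realization.
    """

    strata: list[Stratum]
    diseases: dict[str, DiseaseParams]
    baseline_risks: BaselineRisks
    relapse: RelapseParams
    adverse_events: AdverseEventParams
    economics: EconomicParams
    course_costs: dict[str, float]
    relative_effects: RelativeEffectSlice


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Violation:
    """Machine-readable invariant violation: where, which rule, what value."""

    path: str
    rule: str
    value: Any

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return f"{self.path}: {self.rule} (got {self.value!r})"


class SchemaError(ValueError):
    """A parameter file is structurally incomplete or malformed."""


class ValidationError(ValueError):
    """A structurally complete parameter set breaks an invariant."""

    def __init__(self, violations: Sequence[Violation]):
        self.violations = list(violations)
        super().__init__(
            "parameter set failed validation:\n"
            + "\n".join(f"  - {v}" for v in violations)
        )


def _check_prob(out: list[Violation], path: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        out.append(Violation(path, "probability must be in [0, 1]", value))


def _check_open_prob(out: list[Violation], path: str, value: float) -> None:
    if not (0.0 < value < 1.0):
        out.append(Violation(path, "probability must be in (0, 1)", value))


def _check_nonneg(out: list[Violation], path: str, value: float) -> None:
    if not value >= 0.0:
        out.append(Violation(path, "must be non-negative", value))


def validate(ps: ParameterSet) -> list[Violation]:
    """Check every invariant; return a list of violations (empty iff valid).

    Reports, never raises — callers that want an exception use
    :class:`ValidationError` themselves.
    """
    v: list[Violation] = []

    # strata
    keys = [s.key for s in ps.strata]
    if sorted(keys) != sorted(STRATUM_KEYS):
        v.append(Violation("strata", "must contain each sex × age-band cell exactly once", keys))
    share_sum = sum(s.cohort_share for s in ps.strata)
    if abs(share_sum - 1.0) > 1e-6:
        v.append(Violation("strata", "cohort shares must sum to 1", share_sum))
    for s in ps.strata:
        _check_prob(v, f"strata[{s.key}].cohort_share", s.cohort_share)
        _check_prob(v, f"strata[{s.key}].all_cause_mortality", s.all_cause_mortality)

    # diseases
    if sorted(ps.diseases) != sorted(DISEASE_IDS):
        v.append(Violation("diseases", "must contain exactly the five modelled diseases", sorted(ps.diseases)))
    for did, d in ps.diseases.items():
        base = f"diseases[{did}]"
        for fld in ("incidence", "prevalence", "excess_mortality"):
            table: Mapping[str, float] = getattr(d, fld)
            if sorted(table) != sorted(STRATUM_KEYS):
                v.append(Violation(f"{base}.{fld}", "must be keyed by every stratum", sorted(table)))
                continue
            for k, p in table.items():
                _check_prob(v, f"{base}.{fld}[{k}]", p)
        for fld in ("rr_smoker", "rr_recent_quitter", "rr_long_quitter"):
            if not getattr(d, fld) > 0:
                v.append(Violation(f"{base}.{fld}", "risk ratio must be positive", getattr(d, fld)))
        _check_nonneg(v, f"{base}.annual_cost", d.annual_cost)
        _check_prob(v, f"{base}.utility_value", d.utility_value)

    # baseline risks
    for fld in ("p_abstain_nrt_std", "p_depression_nrt_std", "p_selfharm_nrt_std"):
        _check_open_prob(v, f"baseline_risks.{fld}", getattr(ps.baseline_risks, fld))

    # relapse
    r = ps.relapse
    for fld in ("p_relapse_short", "p_relapse_long", "p_relapse_10plus"):
        _check_prob(v, f"relapse.{fld}", getattr(r, fld))
    if not (r.p_relapse_short >= r.p_relapse_long >= r.p_relapse_10plus):
        v.append(Violation("relapse", "relapse probabilities must decline with time since quitting",
                           (r.p_relapse_short, r.p_relapse_long, r.p_relapse_10plus)))

    # adverse events
    ae = ps.adverse_events
    for fld in ("disutility_depression", "cost_depression", "disutility_selfharm", "cost_selfharm"):
        _check_nonneg(v, f"adverse_events.{fld}", getattr(ae, fld))
    _check_prob(v, "adverse_events.fatal_fraction_selfharm", ae.fatal_fraction_selfharm)

    # economics
    ec = ps.economics
    _check_nonneg(v, "economics.discount_rate", ec.discount_rate)
    if not ec.wtp > 0:
        v.append(Violation("economics.wtp", "willingness-to-pay must be positive", ec.wtp))
    for fld in ("population_per_year", "cohort_size", "psa_draws", "horizon"):
        val = getattr(ec, fld)
        if not (isinstance(val, int) and val > 0):
            v.append(Violation(f"economics.{fld}", "must be a positive integer", val))
    if sorted(ec.baseline_utility) != sorted(STRATUM_KEYS):
        v.append(Violation("economics.baseline_utility", "must be keyed by every stratum",
                           sorted(ec.baseline_utility)))
    else:
        for k, u in ec.baseline_utility.items():
            _check_prob(v, f"economics.baseline_utility[{k}]", u)

    # course costs and relative effects over the 14-intervention roster
    if sorted(ps.course_costs) != sorted(INTERVENTIONS):
        v.append(Violation("course_costs", "must cover the 14-intervention roster", sorted(ps.course_costs)))
    else:
        for iid, c in ps.course_costs.items():
            _check_nonneg(v, f"course_costs[{iid}]", c)

    re = ps.relative_effects
    if sorted(re.log_or_abstinence) != sorted(INTERVENTIONS):
        v.append(Violation("relative_effects.log_or_abstinence", "must cover the roster",
                           sorted(re.log_or_abstinence)))
    else:
        ref = re.log_or_abstinence.get(REFERENCE_INTERVENTION)
        if ref != 0.0:
            v.append(Violation(f"relative_effects.log_or_abstinence[{REFERENCE_INTERVENTION}]",
                               "reference arm must be exactly 0", ref))
        for iid, lor in re.log_or_abstinence.items():
            if lor is None or not (-50 < lor < 50):
                v.append(Violation(f"relative_effects.log_or_abstinence[{iid}]", "must be finite", lor))
    if sorted(re.log_or_mane) != sorted(INTERVENTIONS):
        v.append(Violation("relative_effects.log_or_mane", "must cover the roster", sorted(re.log_or_mane)))
    else:
        ref = re.log_or_mane.get(REFERENCE_INTERVENTION)
        if ref != 0.0:
            v.append(Violation(f"relative_effects.log_or_mane[{REFERENCE_INTERVENTION}]",
                               "reference arm must be exactly 0", ref))
        for iid, lor in re.log_or_mane.items():
            if lor is not None and not (-50 < lor < 50):
                v.append(Violation(f"relative_effects.log_or_mane[{iid}]", "must be finite or None", lor))

    return v


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_TOP_LEVEL = ("strata", "diseases", "baseline_risks", "relapse",
              "adverse_events", "economics", "course_costs", "relative_effects")


def _require(mapping: Mapping[str, Any], key: str, where: str) -> Any:
    if key not in mapping:
        raise SchemaError(f"missing field '{key}' in {where}")
    return mapping[key]


def _build(cls, data: Mapping[str, Any], where: str):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.default is dataclasses.MISSING and f.default_factory is dataclasses.MISSING:
            kwargs[f.name] = _require(data, f.name, where)
        elif f.name in data:
            kwargs[f.name] = data[f.name]
    extra = set(data) - {f.name for f in dataclasses.fields(cls)}
    if extra:
        raise SchemaError(f"unknown field(s) {sorted(extra)} in {where}")
    return cls(**kwargs)


def parameter_set_from_dict(doc: Mapping[str, Any]) -> ParameterSet:
    """Build a :class:`ParameterSet` from a parsed configuration document."""
    for key in _TOP_LEVEL:
        _require(doc, key, "parameter file")

    strata = [_build(Stratum, s, "strata entry") for s in doc["strata"]]

    diseases: dict[str, DiseaseParams] = {}
    for did in DISEASE_IDS:
        block = _require(doc["diseases"], did, "diseases")
        diseases[did] = _build(DiseaseParams, {"disease_id": did, **block}, f"diseases.{did}")

    re_doc = doc["relative_effects"]
    slice_ = RelativeEffectSlice(
        log_or_abstinence={k: float(x) for k, x in _require(re_doc, "log_or_abstinence", "relative_effects").items()},
        log_or_mane={k: (None if x is None else float(x))
                     for k, x in _require(re_doc, "log_or_mane", "relative_effects").items()},
    )

    return ParameterSet(
        strata=strata,
        diseases=diseases,
        baseline_risks=_build(BaselineRisks, doc["baseline_risks"], "baseline_risks"),
        relapse=_build(RelapseParams, doc["relapse"], "relapse"),
        adverse_events=_build(AdverseEventParams, doc["adverse_events"], "adverse_events"),
        economics=_build(EconomicParams, doc["economics"], "economics"),
        course_costs={k: float(c) for k, c in doc["course_costs"].items()},
        relative_effects=slice_,
    )


def parameter_set_to_dict(ps: ParameterSet) -> dict[str, Any]:
    """Inverse of :func:`parameter_set_from_dict` (round-trip safe)."""
    doc = {
        "strata": [dataclasses.asdict(s) for s in ps.strata],
        "diseases": {},
        "baseline_risks": dataclasses.asdict(ps.baseline_risks),
        "relapse": dataclasses.asdict(ps.relapse),
        "adverse_events": dataclasses.asdict(ps.adverse_events),
        "economics": dataclasses.asdict(ps.economics),
        "course_costs": dict(ps.course_costs),
        "relative_effects": dataclasses.asdict(ps.relative_effects),
    }
    for did, d in ps.diseases.items():
        block = dataclasses.asdict(d)
        block.pop("disease_id")
        doc["diseases"][did] = block
    return doc


def load_parameters(path: str | Path) -> ParameterSet:
    """Load and validate a YAML parameter file.

    Raises :class:`SchemaError` on missing/unknown fields and
    :class:`ValidationError` when an invariant is broken.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise SchemaError(f"parameter file {path} is not a mapping document")
    ps = parameter_set_from_dict(doc)
    violations = validate(ps)
    if violations:
        raise ValidationError(violations)
    return ps


def write_parameters(ps: ParameterSet, path: str | Path) -> None:
    """Serialize a parameter set to YAML (round-trips through load)."""
    with open(path, "w") as fh:
        yaml.safe_dump(parameter_set_to_dict(ps), fh, sort_keys=True)
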