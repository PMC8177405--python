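"""End-to-end orchestration: PSA → Markov runs → CEA and VoI reports.

Three analysis presets mirror the reported scenarios:

* ``base`` — the 7 UK-licensed interventions, adverse events included;
* ``all`` — the full 14-intervention roster;
* ``no_adverse_events`` — all 14 arms with depression/self-harm
  probabilities, costs, and disutilities zeroed, so differences are driven
  by abstinence alone.

Everything is deterministic under (seed, config): identical runs produce
byte-identical CSV outputs.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cea import (NetBenefitMatrix, ceac, efficiency_frontier,
                  expected_outcomes, net_benefit, rankogram)
from .effects import build_profile_arrays
from .markov import ParamBatch, run_cohort_batch
from .params import (INTERVENTIONS, LICENSED_INTERVENTIONS, ParameterSet,
                     load_parameters)
from .synthetic import (PsaDrawSet, default_psa_specs,
                        generate_default_parameters, psa_parameter_frame,
                        sample_psa)
from .voi import voi_report

__all__ = ["RunConfig", "ResultBundle", "run_pipeline", "write_reports",
           "SCENARIOS"]

SCENARIOS = ("base", "all", "no_adverse_events")

_DEFAULT_WTP_GRID = tuple(range(0, 50_001, 2_500))


@dataclass
class RunConfig:
    """One pipeline invocation: scenario, seeding, sizes, reference arm."""

    scenario: str = "base"
    seed: int = 0
    psa_draws: int = 5_000
    wtp: float = 20_000.0
    reference: str = "nrt_low"
    parameter_file: str | None = None
    wtp_grid: tuple = _DEFAULT_WTP_GRID

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}, got {self.scenario!r}")
        if self.psa_draws < 1:
            raise ValueError("psa_draws must be >= 1")


@dataclass
class ResultBundle:
    """Everything a run produces, pre-formatting."""

    config: RunConfig
    net_benefit_matrix: NetBenefitMatrix
    cea_table: pd.DataFrame
    ceac_table: pd.DataFrame
    rank_matrix: pd.DataFrame
    rank_summary: pd.DataFrame
    voi_table: pd.DataFrame
    psa_summary: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def _scenario_roster(scenario: str) -> tuple[str, ...]:
    return LICENSED_INTERVENTIONS if scenario == "base" else INTERVENTIONS


def run_pipeline(cfg: RunConfig, ps: ParameterSet | None = None) -> ResultBundle:
    """Run the full probabilistic analysis for one scenario."""
    t0 = time.perf_counter()
    if ps is None:
        ps = (load_parameters(cfg.parameter_file) if cfg.parameter_file
              else generate_default_parameters())

    specs = default_psa_specs(ps)
    draws = sample_psa(ps, specs, n=cfg.psa_draws, seed=cfg.seed)
    batch = ParamBatch.from_parameter_sets(draws.realizations)

    sv = draws.sampled_values
    profiles = build_profile_arrays(
        draws.relative_effects,
        p_abstain_base=sv["baseline_risks.p_abstain_nrt_std"],
        p_depression_base=sv["baseline_risks.p_depression_nrt_std"],
        p_selfharm_base=sv["baseline_risks.p_selfharm_nrt_std"],
        course_costs=ps.course_costs,
    )

    if cfg.scenario == "no_adverse_events":
        zero = np.zeros(cfg.psa_draws)
        for arrs in profiles.values():
            arrs["p_depression"] = zero
            arrs["p_selfharm"] = zero
        batch.ae_cost_depression = zero
        batch.ae_cost_selfharm = zero
        batch.ae_disutility_depression = zero
        batch.ae_disutility_selfharm = zero

    roster = _scenario_roster(cfg.scenario)
    costs = np.empty((cfg.psa_draws, len(roster)))
    qalys = np.empty((cfg.psa_draws, len(roster)))
    for j, iid in enumerate(roster):
        costs[:, j], qalys[:, j] = run_cohort_batch(batch, profiles[iid])
    nbm = NetBenefitMatrix(tuple(roster), costs, qalys)

    # CEA outputs
    means = expected_outcomes(nbm)
    frontier = efficiency_frontier(means)
    enb = net_benefit(nbm, cfg.wtp, cfg.reference)
    rank_matrix, rank_summary = rankogram(nbm, cfg.wtp)
    cea_table = (frontier.table
                 .merge(enb, on="intervention")
                 .merge(rank_summary, on="intervention"))

    ceac_table = ceac(nbm, np.asarray(cfg.wtp_grid, dtype=float))

    # VoI outputs
    frame = psa_parameter_frame(draws)
    voi = voi_report(nbm, frame, ps.economics, wtp=cfg.wtp)

    psa_summary = pd.DataFrame({
        "intervention": list(roster),
        "mean_cost": costs.mean(axis=0),
        "sd_cost": costs.std(axis=0, ddof=1) if cfg.psa_draws > 1 else 0.0,
        "mean_qaly": qalys.mean(axis=0),
        "sd_qaly": qalys.std(axis=0, ddof=1) if cfg.psa_draws > 1 else 0.0,
    })

    manifest = {
        "package": "quitcost",
        "version": __version__,
        "scenario": cfg.scenario,
        "seed": cfg.seed,
        "psa_draws": cfg.psa_draws,
        "wtp": cfg.wtp,
        "reference": cfg.reference,
        "n_interventions": len(roster),
        "wall_time_s": round(time.perf_counter() - t0, 3),
    }
    return ResultBundle(
        config=cfg, net_benefit_matrix=nbm, cea_table=cea_table,
        ceac_table=ceac_table, rank_matrix=rank_matrix,
        rank_summary=rank_summary, voi_table=voi.table,
        psa_summary=psa_summary, manifest=manifest,
    )


def _rounded_cea_table(t: pd.DataFrame) -> pd.DataFrame:
    """Report rounding: costs and ICERs to £1, QALYs to 3 decimals."""
    out = t.copy()
    out["mean_cost"] = out["mean_cost"].round(0)
    out["mean_qaly"] = out["mean_qaly"].round(3)
    out["icer"] = out["icer"].round(0)
    for c in ("enb", "enb_lo", "enb_hi"):
        out[c] = out[c].round(0)
    return out


def write_reports(bundle: ResultBundle, out_dir: str | Path,
                  overwrite: bool = False) -> list[Path]:
    """Write the CSV tables and a JSON manifest; refuse to clobber.

    Files: cea_table.csv, ceac.csv, rankogram.csv, voi_table.csv,
    psa_summary.csv, manifest.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {
        "cea_table.csv": _rounded_cea_table(bundle.cea_table),
        "ceac.csv": bundle.ceac_table,
        "rankogram.csv": bundle.rank_matrix.reset_index(names="intervention"),
        "voi_table.csv": bundle.voi_table,
        "psa_summary.csv": bundle.psa_summary,
    }
    existing = [n for n in [*files, "manifest.json"] if (out / n).exists()]
    if existing and not overwrite:
        raise FileExistsError(
            f"refusing to overwrite {existing} in {out} (pass overwrite=True)")

    written = []
    for name, frame in files.items():
        path = out / name
        frame.to_csv(path, index=False, float_format="%.10g")
        written.append(path)
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(bundle.manifest, indent=2, sort_keys=True) + "\n")
    written.append(mpath)
    return written
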