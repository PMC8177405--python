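"""Benchmark cost-effectiveness summaries for the 14-intervention comparison.

Reported per-smoker mean discounted lifetime costs (GBP) and QALYs for the
full UK roster, used to exercise the dominance analysis end-to-end and in
the worked example. These are externally reported decision-analysis
summary values — not outputs of this package's synthetic pipeline — so
they carry no uncertainty here and are only meaningful as frontier inputs.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["all_interventions_summary"]

_ALL_INTERVENTIONS = [
    # (intervention, mean_cost, mean_qaly)
    ("nrt_low", 10_259.0, 10.934),
    ("ecig_low", 10_279.0, 11.290),
    ("bupropion_low", 10_283.0, 11.038),
    ("nrt_std", 10_292.0, 11.119),
    ("bupropion_std", 10_304.0, 11.033),
    ("nrt_high", 10_309.0, 11.092),
    ("ecig_high", 10_319.0, 11.189),
    ("bupropion_std_nrt_high", 10_346.0, 11.128),
    ("varenicline_std", 10_413.0, 11.127),
    ("varenicline_std_bupropion_std", 10_437.0, 11.281),
    ("varenicline_low", 10_440.0, 10.959),
    ("varenicline_std_nrt_high", 10_467.0, 11.117),
    ("varenicline_low_nrt_std", 10_587.0, 11.273),
    ("varenicline_std_nrt_std", 10_587.0, 11.280),
]


def all_interventions_summary() -> pd.DataFrame:
    """Per-intervention (mean_cost, mean_qaly) benchmark for all 14 arms."""
    return pd.DataFrame(_ALL_INTERVENTIONS,
                        columns=["intervention", "mean_cost", "mean_qaly"])
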