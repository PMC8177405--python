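# quitcost

A Markov cohort cost-effectiveness model of smoking-cessation aids for a UK
smoking population, with intervention-attributable neuropsychiatric adverse
events, probabilistic sensitivity analysis (PSA), dominance-aware
cost-effectiveness reporting, and value-of-information (VoI) analysis.

## Who this is for

Health-economic modellers and methodologists who want a tested, scriptable
implementation of the standard decision-analytic pipeline for smoking
cessation: fourteen interventions (nicotine replacement therapy [NRT] at
low/standard/high dose, bupropion at low/standard dose, varenicline at
low/standard dose, e-cigarettes at low/high dose, and five combination
therapies), compared on lifetime discounted costs and quality-adjusted life
years (QALYs) from a UK NHS perspective.

## The model

A cohort of 10,000 adult smokers makes one quit attempt. Each member is a
smoker or a quitter with a years-since-quit counter, crossed with one of
five smoking-related disease states (COPD, lung cancer, coronary heart
disease, stroke, asthma) or disease-free; death is absorbing. Cycles are
annual. Per cycle, in order: quitters relapse (annual probability 0.13 for
<5 years since quitting, 0.03 for 5–10 years, 0.0009 beyond); disease-free
members acquire disease at a never-smoker incidence scaled by a
smoking-status risk ratio; members die from background mortality plus
risk-ratio-scaled disease excess mortality. Intervention `i` changes the
one-year sustained-abstinence probability via a log odds ratio applied to
the 21.2% standard-NRT baseline:

    p_i = expit( logit(p_NRT-std) + logOR_i )

and likewise maps one pooled "major adverse neuropsychiatric event" (MANE)
log odds ratio onto the baseline depression (8274/106,759 ≈ 7.75%) and
self-harm (540/106,759 ≈ 0.5%) probabilities. Depression and nonfatal
self-harm carry one-off costs and QALY decrements in the intervention year;
a configurable fraction of self-harm is fatal. Costs and QALYs are
discounted at 3.5% per year over a lifetime horizon (to age 100).

Decision outputs follow the standard toolkit: net benefit
`NB(λ) = QALY·λ − cost` at a willingness-to-pay of λ = £20,000/QALY,
efficiency frontier with strict and extended dominance and sequential
ICERs, cost-effectiveness acceptability curves, rank-o-grams, and per-person
EVPI/EVPPI scaled to the 274,021 smokers attempting to quit in England per
year. EVPPI uses an additive spline regression metamodel of net benefit on
the parameter subset.

The full input tables behind published analyses of this kind are not
available in machine-readable form, so the package ships a **synthetic-data
generator** that anchors every headline quantity above exactly and fills
the remaining epidemiology, costs, and utilities with documented,
clearly-labelled plausible UK defaults (see `docs/methods.md`). PSA draws
probabilities from Beta distributions, costs from Gamma, risk ratios from
lognormal, and relative effects from a correlated multivariate normal on
the log-OR scale.

## Worked example

Dominance analysis on the benchmark 14-arm mean cost/QALY summary:

```python
>>> from quitcost.benchmarks import all_interventions_summary
>>> from quitcost.cea import efficiency_frontier
>>> rep = efficiency_frontier(all_interventions_summary())
>>> rep.table.head(4)[["intervention", "mean_cost", "mean_qaly", "status", "icer"]].round({"icer": 1})
    intervention  mean_cost  mean_qaly       status  icer
0        nrt_low    10259.0     10.934  on-frontier   NaN
1       ecig_low    10279.0     11.290  on-frontier  56.2
2  bupropion_low    10283.0     11.038    dominated   NaN
3        nrt_std    10292.0     11.119    dominated   NaN
```

Low-dose e-cigarettes cost £20 more and gain 0.356 QALYs versus low-dose
NRT — an ICER of £56/QALY — and dominate the other twelve arms.

A full licensed-only probabilistic run on the synthetic defaults
(1,000 draws, seed 1; `quitcost run --psa-draws 1000 --seed 1` writes the
same tables as CSV):

```python
>>> from quitcost.pipeline import RunConfig, run_pipeline
>>> bundle = run_pipeline(RunConfig(scenario="base", seed=1, psa_draws=1000))
>>> cols = ["intervention", "mean_cost", "mean_qaly", "status", "enb", "median_rank"]
>>> print(bundle.cea_table[cols].round({"mean_cost": 0, "mean_qaly": 3, "enb": 0}).to_string(index=False))
   intervention  mean_cost  mean_qaly               status    enb  median_rank
        nrt_low     8434.0     11.644          on-frontier    0.0          6.0
  bupropion_low     8459.0     11.665          on-frontier  406.0          5.0
  bupropion_std     8512.0     11.688          on-frontier  814.0          4.0
        nrt_std     8514.0     11.680            dominated  634.0          4.0
varenicline_low     8531.0     11.684            dominated  706.0          4.0
       nrt_high     8609.0     11.708 extendedly dominated 1113.0          3.0
varenicline_std     8640.0     11.731          on-frontier 1543.0          2.0
```

Here `enb` is the expected net benefit at £20,000/QALY incremental to
low-dose NRT: standard-dose varenicline buys the most net benefit (+£1,543
per smoker) and holds the best median cost-effectiveness rank (2). The
companion VoI table reports a per-person EVPI of £472 on these synthetic
inputs, dominated by uncertainty in the abstinence effects (EVPPI £468).

All numbers above are on the synthetic default inputs; they illustrate the
pipeline, not any published estimate.

## Layout

| Module | Role |
| --- | --- |
| `quitcost.params` | domain types, validation, YAML parameter files |
| `quitcost.synthetic` | synthetic defaults, distribution fitting, PSA and NMA draw generation |
| `quitcost.effects` | log-odds effect mapping and harm-assumption donors |
| `quitcost.markov` | draw-batched cohort engine |
| `quitcost.cea` | frontier/ICER, net benefit, CEAC, rank-o-grams |
| `quitcost.voi` | EVPI, regression-metamodel EVPPI, population scaling |
| `quitcost.pipeline`, `quitcost.cli` | scenario presets, report writing, `quitcost` CLI |
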