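# Methods

## Model structure

The engine is a deterministic expected-value Markov cohort model (no
microsimulation): occupancy mass moves between states according to annual
probabilities, so a run is exact conditional on its inputs, and all
uncertainty enters through the probabilistic sensitivity analysis (PSA).

State space, per sex × age-band stratum:

* **smoking status** — smoker, or quitter with a years-since-quit counter
  (1–9 explicitly, then an absorbing "≥10 years" class). The counter drives
  two things: the relapse probability tier (<5 years: `p_relapse_short`;
  5–10: `p_relapse_long`; ≥10: `p_relapse_10plus`) and the risk-ratio class
  (smoker / recent quitter <5 y / long-term quitter ≥5 y).
* **disease** — none, or exactly one of COPD, lung cancer, coronary heart
  disease, stroke, asthma. Disease states are mutually exclusive and
  first-event: the first disease acquired is kept for life (the classic
  BENESCO-family simplification; comorbidity is not modelled). Asthma is
  treated as a chronic annual-cost/utility state like the others.
* **dead** — absorbing; tracked as a separate mass so that
  occupancy + cumulative deaths equals the initial cohort size every cycle
  (checked to 1e-6 in tests).

Cycle length is one year — every input rate is annual — and there is no
half-cycle correction. Within a cycle events apply in a fixed order:
relapse → disease incidence → mortality → counter/age advance. Relapse
reclassifies smoking status immediately (a relapsing quitter faces smoker
risk ratios in the same cycle); the alternative, lagged reclassification,
was considered and rejected as harder to reason about with no data to
prefer it.

Incidence and disease excess mortality are stored as never-smoker
reference rates and scaled by the same per-disease risk ratios
(smoker ≥ recent ≥ long-term ≥ 1). Using one set of risk ratios for
prevalence-like and mortality-like quantities is an explicit simplification
carried over from the modelling tradition this package follows. Scaled
probabilities can exceed 1 with extreme inputs; they are clamped at 1 and
every clamp is counted and logged — a clamp count of zero on the default
inputs is part of the test suite's expectations.

Members enter at the integer mean age of their band (26 / 50 / 72), age
one year per cycle, and adopt the next band's rates when they cross 35 or
65. At the maximum age (default 100) a stratum stops transitioning and
accruing; survivors at the horizon are simply censored (logged, not an
error).

### The quit attempt (cycle 1)

The whole treated cohort is charged the one-off course cost and exposed to
the adverse-event probabilities, unconditional on quit success. Depression
and nonfatal self-harm generate one-off costs and one-off QALY decrements
(not utility multipliers — with a one-year event horizon the two
parameterizations are equivalent up to scaling, and the one-off decrement
keeps the PSA specification simple); fatal self-harm
(`fatal_fraction_selfharm × p_selfharm`) moves members directly to dead.
The abstaining fraction of surviving smokers enters the quit tunnel at
counter 1. Failed quitters remain smokers until death — subsequent quit
attempts are out of scope.

### Accrual and discounting

After each transition, disease-free members accrue the stratum's baseline
utility at their current age band and diseased members the disease utility
and annual cost; both are discounted at `(1 + r)^(-cycle)` with r = 0.035.
Per-member totals are cohort totals divided by the 10,000-member cohort
size.

## Effect mapping

Relative effects are applied on the log-odds scale:
`p = expit(logit(p_base) + logOR)`. The scale on which such effects should
be applied is genuinely open (odds, risk, or risk difference); log-odds was
chosen because it is the native scale of a binary-outcome network
meta-analysis and guarantees mapped probabilities stay in (0, 1). A
risk-ratio mapping (`apply_relative_risk`) is available for sensitivity
analysis. A single pooled "major adverse neuropsychiatric events" effect
drives both the depression and the self-harm probability; no per-outcome
split is attempted.

Arms without observed MANE evidence inherit a donor arm's draw column
(sharing draws preserves correlation): NRT low and e-cigarette low →
NRT standard; e-cigarette high → NRT high; bupropion low → bupropion
standard; varenicline low + NRT standard → varenicline standard + NRT
standard. The map is a configuration object and can be overridden.

## Synthetic inputs

The generator emulates the statistical shape of the model's input tables.
Anchored exactly: 21.2% one-year abstinence on standard NRT; depression
8274/106,759 (the counts are kept rather than the rounded 7%); self-harm
540/106,759; relapse 0.13 / 0.03 / 0.0009 with their published 95%
intervals; 3.5% discounting; £20,000/QALY; 274,021 annual quit attempts;
10,000-member cohort; 5,000 PSA draws; mapped abstinence anchors 0.44
(0.17–0.74), 0.44 (0.23–0.67) and 0.32 (0.12–0.63) for the two
varenicline+NRT combinations and low-dose e-cigarettes.

Everything else — per-stratum disease epidemiology, costs, utilities,
course costs, the remaining abstinence anchors, all MANE anchors, and the
5% fatal fraction of self-harm — is a synthetic default chosen to be
plausible for a UK smoking cohort, labelled as such in the source, and
never presented as an external estimate. Consequences: passing tests show
the pipeline's mechanics and invariants are right, not that its outputs
match any published cost/QALY total; headline totals from published
analyses are reproduced structurally (roster, dominance labels, report
layout) but not numerically.

Sampling families: Beta for probabilities and utilities (utilities are
bounded in [0, 1]; moment-matched, SD 0.03 for utilities, CV 10% for
epidemiological rates), Gamma for costs (CV 20%, the conventional family
for right-skewed cost data), lognormal (CV 10%) for risk ratios with an
order-preserving truncation so the smoker ≥ recent ≥ long-term ≥ 1
ordering survives sampling, and Beta with source-study pseudo-counts for
the three baseline risks. One-off course costs are treated as known prices
and not sampled. Which fields are sampled is configurable per field.

`fit_beta_from_mean_ci` matches the mean exactly and tunes the
concentration to the 95% interval; because a fixed-mean Beta has one free
parameter, an arbitrarily asymmetric interval cannot always be attained —
the fit is accepted when the worst percentile residual is below 25% of the
interval width, and raises a fitting error (reporting the best residual)
otherwise.

Relative-effect draws are multivariate normal on the log-OR scale. The
log-OR standard deviation comes from the anchor interval on the logit
scale; the mean is bias-corrected by Gauss–Hermite quadrature so the
induced mapped-probability mean reproduces the anchor exactly (the naive
mean is biased toward 0.5 under a normal log-OR). Cross-arm correlation
defaults to an exchangeable 0.3 — posterior correlations of a real
evidence network are unavailable, and 0.3 mimics the shared-evidence
structure of indirect comparisons; it is a parameter, not a claim.

All generation is driven by `numpy` `SeedSequence` spawning, so identical
(seed, n, specs) give bitwise-identical draw sets.

## Decision analysis

Net benefit is always recomputed from the stored cost/QALY draws. The
frontier algorithm is the standard one (sort by mean cost, remove strict
dominance, iteratively remove extended dominance until sequential ICERs
increase); it is tested for exact agreement with a brute-force
pairwise-and-mixture oracle on random instances up to 14 arms. Cost ties
keep the higher-QALY member; exact ties collapse to one label. Expected
net benefit is reported incrementally to low-dose NRT by default (the
reference is a flag); its 95% interval is the normal-approximation
interval of the mean (±1.96·SE), which at 5,000 draws is indistinguishable
from a bootstrap percentile interval and is deterministic. CEAC ties are
split equally so curves sum to one; rank-o-gram ties receive the mean of
the tied positions with probability mass spread across them, keeping the
rank matrix doubly stochastic. Report tables round costs and ICERs to £1
and QALYs to three decimals.

## Value of information

EVPI is computed directly from the net-benefit draws. EVPPI uses a
regression metamodel: per intervention, an additive cubic B-spline smooth
of net benefit on the standardized subset columns, fit by ordinary least
squares (basis dimension 6 per column for subsets of ≤4 parameters, 4
above that to keep the observations-per-coefficient ratio healthy), then
`mean(max fitted) − max(mean fitted)`, clipped at zero. An additive basis
over *all* columns was chosen over a principal-component smooth because
the net benefit of each arm depends on its own relative-effect column;
leading components of many near-independent columns discard exactly that
signal and were observed to underestimate multi-arm EVPPI severely. A
principal-component smooth remains as fallback for subsets wider than 32
columns. EVPPI estimates are stochastic (they inherit PSA noise and
smoother bias) and can slightly exceed EVPI or break subset monotonicity
at small draw counts; tests allow an explicit 5% estimator tolerance.

The two "head-to-head" report rows restrict the decision to standard NRT
versus standard varenicline before computing EVPPI — the value of a trial
comparing the two leading licensed arms. Population scaling is
`per-person × 274,021 × years / 1e6` (£ million), undiscounted over the
1–5-year relevance horizon, rounded to the nearest million in reports.

## Scenarios and problem sizes

Presets: `base` (7 licensed arms), `all` (14 arms), `no_adverse_events`
(14 arms with depression/self-harm probabilities *and* their one-off
costs/disutilities zeroed, so differences are driven by abstinence alone).

The engine carries a leading draw axis, so a full PSA is a handful of
vectorized array sweeps: the 7-arm, 5,000-draw base case runs in about a
minute on one CPU and is byte-reproducible under a fixed seed. The test
suite and the acceptance script use 200–5,000 draws depending on what each
check needs; the acceptance script's synthetic summary uses 1,000 draws,
enough for stable means while keeping the script quick.

## Known limitations

* One quit attempt per lifetime; no re-quitting after relapse.
* Mutually exclusive first-event disease states; no comorbidity.
* Broad age bands with homogeneous within-band rates; integer mean entry
  age per band.
* Prevalence is applied directly as the smoking cohort's starting disease
  mix (no risk-ratio scaling at entry).
* The synthetic generator reproduces the *structure* of real input tables,
  not their values; absolute cost/QALY totals from this package are not
  comparable to published totals.
* EVPPI is a metamodel estimate, not an unbiased Monte-Carlo quantity.
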