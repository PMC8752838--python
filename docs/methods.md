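# Methods

## Scope and model

`pafburden` implements the comparative-risk-assessment arithmetic used in
national cancer-burden studies. The causal model is deliberately minimal:
for each (risk factor, cancer type, sex) cell, exposure is discretised
into levels with population proportions *pᵢ*, each level multiplies a
common baseline risk by RRᵢ, and the attributable fraction is the
multi-level Levin formula

    PAF = S / (1 + S),   S = Σᵢ pᵢ·ERRᵢ  (non-reference levels).

S/(1+S) equals the exact excess-case fraction of a fully stratified
population (the test suite asserts this against an enumeration oracle to
1e-12), so nothing beyond the discrete stratification is assumed for a
single factor. Across factors the model assumes independence of exposures
and multiplicative joint risk; interactions/synergy are out of scope, and
confidence intervals are not produced — the inputs are point estimates
whose sampling uncertainty the method does not propagate.

## ERR derivation and framings

Published RRs arrive in two framings:

* **harmful** (`ERR = RR − 1`): exposed vs unexposed contrast.
* **reduction** (`ERR = ln(1/RR) / n_units`): the RR describes the
  lower-risk state (e.g. active vs inactive, per n units of activity), so
  the harmful direction is the reciprocal. The per-unit division is
  applied to `ln(1/RR)` — the literal reading of the source convention.
  Because dividing a log by n and taking an n-th root of the ratio differ
  beyond first order, the engine exposes
  `reduction_transform="power"` (`(1/RR)^(1/n) − 1`) so the alternative
  reading is auditable; the default stays `"log"`. Near RR = 1 the two
  framings agree to first order (|ln(1/RR) − (1/RR − 1)| ≤ (RR − 1)²),
  which the suite checks on RR ∈ [0.9, 1.1].

`significant=false` on an RR row forces an effective RR of 1: a
recognised carcinogen link whose risk estimate lacked statistical support
contributes zero excess, explicitly. A *missing* RR row for a linked cell
is a hard data-gap error — silent RR = 1 defaults would make data gaps
indistinguishable from deliberate nulls.

Net-protective inputs (S < 0) are rejected by default, since only the
harmful direction of each factor is considered; `allow_negative_paf=True`
admits signed PAFs for methodological work. A signed PAF S/(1+S) is
unbounded below, so `PafValue` only enforces the upper bound.

## Combination and aggregation

Factors acting on one cancer type combine as `1 − Π(1 − PAF_f)`. This is
algebraically identical to applying each factor's PAF sequentially to the
cases not yet attributed, and is therefore independent of the sequence —
the unique order-free reading of sequential attribution. It is bounded by
[max PAF_f, min(1, Σ PAF_f)] and, under the independence assumption,
matches the joint-removal PAF exactly.

Attributable cases are PAF × incident cases, kept unrounded internally.
Percentages are rounded half-away-from-zero to one decimal **only at
report time**; aggregation always runs on unrounded values.

Subtype handling: when RRs target a subtype, the incidence table carries
the subtype with a `subtype_of` link. Attribution runs on the subtype's
own counts; for reporting, subtype attributable cases roll up into the
parent (capped at the parent's count), and run totals count each case
once by summing top-level diagnoses only. This presumes a subtype's
attribution is not duplicated by separate attribution on its parent —
the configuration should target either the parent or its subtypes for a
given factor, not both.

## Filtering and latency

Diagnoses with annual population incidence below 10 (summed over sexes —
"population" incidence, not per-sex; `per_sex_filter=True` flips this
interpretive choice) are excluded before attribution and logged. The
threshold is configurable (`min_incidence`). Latency is metadata, not
modelling: a factor declares its exposure-data vintage and latency, and
the run aborts unless `incidence_year − exposure_year = latency`. A
20-year sensitivity scenario is therefore just the same pipeline pointed
at an older exposure table.

## Input conventions

Tables are UTF-8 CSV with fixed headers (see `pafburden.tables`); sexes
are the literals `male`/`female`, and single-sex factors simply omit the
other sex's rows. The reference exposure level may be explicit
(`level_id = "reference"`) or implicit; both normalise to an explicit
reference with p = 1 − Σ others. Validation is total: any malformed cell
raises a structured error naming file, row and column, and no partially
constructed input survives.

## The microsimulator

`pafburden.simulate` draws n individuals; each holds one level per factor
(independent across factors and individuals, categorical with the
configured prevalences) and develops each cancer type as an independent
Bernoulli event with probability `baseline × Π_f RR_f(level)` — diagnoses
are counted per event, as registries count them, so one individual can
contribute several. Probabilities exceeding 1 are capped; if more than
0.1% of draws are capped the run aborts with guidance to lower baseline
or relative risks, since capping would bias the truth values.

Under this construction the true PAF of removing a factor subset F is
exactly `1 − 1/Π_{f∈F} E[RR_f]` with `E[RR_f] = Σ pᵢ RRᵢ` — for a single
factor precisely the Levin value. The empirical truth is computed by
re-evaluating outcomes with the subset's RRs removed on *common random
numbers*, which makes the counterfactual case set nested in the factual
one and gives a low-variance paired estimate; its Monte-Carlo standard
error is approximated binomially as √(PAF(1−PAF)/N_cases).

The emitted `exposure.csv` carries the *empirical* level prevalences so
that the tables handed to the pipeline are internally consistent with the
simulated case counts. The seed is recorded as a `# seed=` header line in
every emitted file, and a fixed seed yields byte-identical outputs.

### Default fixture

Three factors × four cancers, n = 10⁶, seed 20180101. Prevalences echo
Danish adult exposure around 2008: 24% current / 26% former smokers,
sex-differentiated alcohol intake (40%+ of men above moderate intake,
roughly a third of women), 33% overweight / 13% obese. Relative risks are
textbook-scale (current smoking: lung 9.0, bladder 2.9; high alcohol:
colon 1.4, breast 1.25; obesity: colon 1.5), and baseline annual risks of
0.5–2 per 1,000 give registry-like case counts (hundreds to thousands of
cases per type) from a million people. Breast cancer has a zero male
baseline, exercising the single-sex path. This fixture is the validation
bed for all recovery checks; it emulates independent exposures with
multiplicative risk and no measurement error, so passing recovery shows
estimator correctness under the model's own assumptions — not robustness
to confounding, exposure misreport, age structure or survival, which real
survey/registry data exhibit and the simulator deliberately omits.

## Numerical choices

* Closed-form comparisons at absolute 1e-12; sums via `math.fsum`.
* Monte-Carlo comparisons at 3 standard errors.
* Proportion-sum tolerance 1e-9 when validating prevalence tables.
* Reported percentages: one decimal, half-away-from-zero (via `Decimal`),
  presentation-only; rerunning aggregation from written tables differs
  from unrounded internals by less than 0.05 percentage points.
* Problem sizes: property tests run hundreds of random configurations;
  recovery checks use n = 2×10⁵ in unit tests and the full n = 10⁶
  fixture in the acceptance suite — at that size the pipeline's worst
  absolute PAF error against analytic truth is a few × 10⁻⁴.

## Known limitations

* No interaction/synergy terms, no confidence intervals, no
  age-standardisation, no projection of future burden.
* Direct-PAF factors are passed through unchanged; their provenance and
  transportability are the user's responsibility.
* The low-incidence filter's per-population reading is an interpretive
  choice (configurable), as is applying it before attribution.
* The combined PAF assumes the single-factor PAFs refer to independent
  exposures; correlated exposures would need joint prevalence data the
  model does not accept.
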