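# pafburden

Estimation of the share of a population's cancer burden attributable to
modifiable risk factors — the *population attributable fraction* (PAF) —
from three tabular inputs: exposure prevalence, relative risks and
registry-style incidence counts. The package is aimed at cancer
epidemiologists and prevention analysts who run comparative risk
assessments of the kind national cancer societies publish: "X% of this
year's cancers would not have occurred without exposure E".

## The model

For one risk factor, one cancer type and one sex, the PAF is the
multi-level Levin formula over the factor's exposure levels
*i = 1 … n*:

```
PAF = Σᵢ pᵢ·ERRᵢ / (1 + Σᵢ pᵢ·ERRᵢ)
```

where *pᵢ* is the proportion of the population at exposure level *i* and
ERRᵢ is the excess relative risk at that level. ERRs come from published
relative risks in one of two framings:

* **harmful** — the RR contrasts exposed vs unexposed: `ERR = RR − 1`;
* **reduction** — the RR describes a lower-risk contrast (e.g. physically
  active vs inactive); the harmful-direction ERR is `ln(1/RR)`, divided
  by the number of exposure units the published RR spans. A
  multiplicative alternative `(1/RR)^(1/n) − 1` is available as an engine
  option for sensitivity analysis.

An association judged not statistically supported is kept in the input
with `significant=false` and enters the calculation with an effective
RR of 1, so it contributes zero excess by design rather than by omission.
Factors with better published attributable fractions than local data
could support (e.g. HPV, occupational exposures, UV) are taken as
**direct PAFs** and passed through unchanged.

Factors acting on the same cancer type are combined so that each factor
attributes only the cases not already attributed by the others:

```
PAF_combined = 1 − Πf (1 − PAF_f)
```

which is order-free. Attributable cases are `PAF × incident cases`;
diagnoses with an annual population incidence below 10 are excluded
before attribution; exposure vintages are bound to the incidence year by
a fixed latency (e.g. 2008 exposure → 2018 incidence under a 10-year
latency, 1998 → 2018 under a 20-year sensitivity scenario).

A built-in microsimulator draws an individual-level population with
independent factors and multiplicative joint risk, for which the true PAF
of any factor subset F has the closed form `1 − 1/Π_f E[RR_f]`. It emits
pipeline-ready tables plus a truth table, so the whole estimator chain
can be validated against known ground truth.

## Worked example

Simulate a million-person population with the default fixture (three
lifestyle factors, four cancer types, Danish-like 2008 prevalences and
registry-scale baseline risks), then run the full table-driven pipeline
on the emitted files:

```python
import tempfile
import pafburden as pb
from pafburden.simulate import run_config_for, simulate_population

cfg = pb.default_config(n_individuals=1_000_000, seed=20180101)
with tempfile.TemporaryDirectory() as d:
    sim = simulate_population(cfg, d)
    res = pb.BurdenModel.from_config(run_config_for(sim)).fit()
print(res.summary())
```

```
Attributable burden summary
===========================
Incidence year:          2018
Total incident cases:    6,690
Attributable cases:      2,944
Overall PAF:             44.0%
Diagnoses excluded (<10): 0

Per-factor burden
-----------------
smoking                     2,532   37.9%
overweight                    306    4.6%
alcohol                       146    2.2%
```

The simulated registry saw 6,690 cancer cases; the pipeline attributes
44.0% of them to the three factors jointly, dominated by smoking. The
estimate agrees with the analytic truth: for smoking → lung cancer the
true PAF is `1 − 1/E[RR] = 0.68031` and the pipeline recovers `0.68060`
from the emitted tables (difference well inside Monte-Carlo error):

```python
pb.analytic_true_paf(cfg, ["smoking"], "lung", "male")   # 0.6803069...
```

The same computation is available from the shell:

```
paf-burden simulate --n 1000000 --seed 20180101 --out sim/
paf-burden compute --config run.yaml --out out/
paf-burden report out/attribution.csv
paf-burden validate sim/exposure.csv --kind exposure
```

where `run.yaml` names the three tables, the incidence year and the
per-factor framing/latency metadata (see `docs/methods.md`).

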