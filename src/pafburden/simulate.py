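"""Individual-level microsimulation with known attributable fractions.

The simulator draws a synthetic population in which each individual holds
one exposure level per risk factor (independently across factors and
individuals) and develops each cancer type as an independent Bernoulli
event with probability ``baseline x prod_f RR_f(level)``. Because the
joint risk is multiplicative over independent factors, the true
attributable fraction of any factor subset F has the closed form

    PAF_F = 1 - 1 / prod_{f in F} E[RR_f],   E[RR_f] = sum_l p_l RR_f(l),

which for a single factor is exactly the Levin formula value. The
simulator therefore provides ground truth — both analytic and empirical
(by re-drawing outcomes with the subset's risks removed, on common random
numbers) — against which the full table-driven pipeline can be checked.

Emitted files use the interchange schemas of :mod:`pafburden.tables`
(exposure/rr/incidence) plus ``truth.csv``; the exposure table carries the
*empirical* prevalences so the tables are internally consistent with the
case counts. Every output begins with a ``# seed=...`` comment line.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import tables as tbl
from .exceptions import ConfigurationError, TableValidationError
from .pipeline import RunConfig, RunOptions
from .types import (
    REFERENCE_LEVEL,
    ExposureDistribution,
    IncidenceRecord,
    RelativeRiskEntry,
)

_PREV_TOL = 1e-9
_CAP_FRACTION = 1e-3

TRUTH_COLUMNS = ["factor_id", "cancer_type_id", "sex", "analytic_paf",
                 "simulated_paf", "mc_standard_error"]


@dataclass(frozen=True)
class SimLevel:
    """One exposure level: its prevalence and per-cancer relative risks."""

    level_id: str
    prevalence: float
    rr: dict = field(default_factory=dict)  # cancer_type_id -> RR

    def __post_init__(self):
        for cancer, rr in self.rr.items():
            if not (rr > 0):
                raise ConfigurationError(
                    f"level {self.level_id!r}: RR for {cancer!r} must be > 0")


@dataclass(frozen=True)
class SimFactor:
    """A simulated risk factor.

    ``levels`` includes the reference level (all RR = 1); prevalences sum
    to 1. ``significant=False`` stamps the emitted RR rows as not
    statistically supported, so the pipeline must zero them out while the
    simulated biology keeps the excess risk — a deliberate discordance
    used to test the forced-null rule.
    """

    factor_id: str
    levels: tuple  # of SimLevel
    prevalence_by_sex: dict = field(default_factory=dict)  # sex -> tuple of p
    significant: bool = True

    def __post_init__(self):
        ids = [lv.level_id for lv in self.levels]
        if REFERENCE_LEVEL not in ids:
            raise ConfigurationError(
                f"factor {self.factor_id!r}: levels must include "
                f"{REFERENCE_LEVEL!r}")
        if len(set(ids)) != len(ids):
            raise ConfigurationError(
                f"factor {self.factor_id!r}: duplicate level ids")
        for prevs in [tuple(lv.prevalence for lv in self.levels),
                      *map(tuple, self.prevalence_by_sex.values())]:
            if abs(sum(prevs) - 1.0) > 1e-6:
                raise ConfigurationError(
                    f"factor {self.factor_id!r}: prevalences sum to "
                    f"{sum(prevs):.6g}, expected 1")
            if any(p < 0 for p in prevs):
                raise ConfigurationError(
                    f"factor {self.factor_id!r}: negative prevalence")
        ref = next(lv for lv in self.levels if lv.level_id == REFERENCE_LEVEL)
        if any(rr != 1.0 for rr in ref.rr.values()):
            raise ConfigurationError(
                f"factor {self.factor_id!r}: reference level must have RR = 1")

    def prevalences(self, sex: str) -> tuple:
        if sex in self.prevalence_by_sex:
            return tuple(self.prevalence_by_sex[sex])
        return tuple(lv.prevalence for lv in self.levels)

    def rr_vector(self, cancer: str) -> tuple:
        """Per-level RR for one cancer (1 where the level declares none)."""
        return tuple(lv.rr.get(cancer, 1.0) for lv in self.levels)


@dataclass(frozen=True)
class SimCancer:
    """A cancer type with its baseline annual risk per person."""

    cancer_type_id: str
    baseline_risk: float = 0.0
    baseline_by_sex: dict = field(default_factory=dict)

    def __post_init__(self):
        for b in (self.baseline_risk, *self.baseline_by_sex.values()):
            if not (0.0 <= b < 1.0):
                raise ConfigurationError(
                    f"cancer {self.cancer_type_id!r}: baseline risk {b} "
                    "outside [0, 1)")

    def baseline(self, sex: str) -> float:
        return self.baseline_by_sex.get(sex, self.baseline_risk)


@dataclass(frozen=True)
class SimulationConfig:
    """Full specification of a synthetic population."""

    n_individuals: int
    seed: int
    factors: tuple  # of SimFactor
    cancers: tuple  # of SimCancer
    sexes: tuple = ("male", "female")
    exposure_year: int = 2008
    latency_years: int = 10

    def __post_init__(self):
        if self.n_individuals < 1:
            raise ConfigurationError("n_individuals must be positive")
        if not self.factors or not self.cancers:
            raise ConfigurationError("config needs at least one factor and "
                                     "one cancer")

    @property
    def incidence_year(self) -> int:
        return self.exposure_year + self.latency_years

    def factor(self, factor_id: str) -> SimFactor:
        for f in self.factors:
            if f.factor_id == factor_id:
                return f
        raise LookupError(f"unknown factor {factor_id!r}")

    def cancer(self, cancer_type_id: str) -> SimCancer:
        for c in self.cancers:
            if c.cancer_type_id == cancer_type_id:
                return c
        raise LookupError(f"unknown cancer type {cancer_type_id!r}")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        factors = tuple(
            SimFactor(
                factor_id=fid,
                levels=tuple(SimLevel(level_id=lid,
                                      prevalence=float(lv.get("prevalence", 0.0)),
                                      rr=dict(lv.get("rr") or {}))
                             for lid, lv in spec["levels"].items()),
                prevalence_by_sex={s: tuple(v) for s, v in
                                   (spec.get("prevalence_by_sex") or {}).items()},
                significant=bool(spec.get("significant", True)))
            for fid, spec in raw["factors"].items())
        cancers = tuple(
            SimCancer(cancer_type_id=cid,
                      baseline_risk=float(spec.get("baseline_risk", 0.0)),
                      baseline_by_sex={s: float(v) for s, v in
                                       (spec.get("baseline_by_sex") or {}).items()})
            for cid, spec in raw["cancers"].items())
        return cls(n_individuals=int(raw["n_individuals"]),
                   seed=int(raw["seed"]), factors=factors, cancers=cancers,
                   sexes=tuple(raw.get("sexes", ("male", "female"))),
                   exposure_year=int(raw.get("exposure_year", 2008)),
                   latency_years=int(raw.get("latency_years", 10)))


def default_config(n_individuals: int = 10 ** 6,
                   seed: int = 20180101) -> SimulationConfig:
    """The standard validation fixture: three lifestyle factors, four
    cancer types, registry-scale baseline risks.

    Prevalences echo Danish adult exposure around 2008 (about a quarter
    current smokers, a third overweight) and baseline annual risks are on
    the order of one to two per thousand, so a million simulated people
    yield case counts comparable to a small national registry year.
    """
    smoking = SimFactor("smoking", levels=(
        SimLevel("current", 0.24, {"lung": 9.0, "bladder": 2.9, "colon": 1.2}),
        SimLevel("former", 0.26, {"lung": 1.8, "bladder": 1.5, "colon": 1.1}),
        SimLevel(REFERENCE_LEVEL, 0.50),
    ))
    alcohol = SimFactor("alcohol", levels=(
        SimLevel("moderate", 0.30, {"colon": 1.10, "breast": 1.08}),
        SimLevel("high", 0.10, {"colon": 1.40, "breast": 1.25}),
        SimLevel(REFERENCE_LEVEL, 0.60),
    ), prevalence_by_sex={"male": (0.34, 0.14, 0.52),
                          "female": (0.26, 0.06, 0.68)})
    overweight = SimFactor("overweight", levels=(
        SimLevel("overweight", 0.33, {"colon": 1.30, "breast": 1.12}),
        SimLevel("obese", 0.13, {"colon": 1.50, "breast": 1.25}),
        SimLevel(REFERENCE_LEVEL, 0.54),
    ))
    cancers = (
        SimCancer("lung", 0.0010),
        SimCancer("colon", 0.0012),
        SimCancer("bladder", 0.0005),
        SimCancer("breast", baseline_by_sex={"male": 0.0, "female": 0.0020}),
    )
    return SimulationConfig(n_individuals=n_individuals, seed=seed,
                            factors=(smoking, alcohol, overweight),
                            cancers=cancers)


# ---------------------------------------------------------------------------
# analytic truth


def expected_rr(factor: SimFactor, cancer_type_id: str, sex: str) -> float:
    """E[RR] = sum_l p_l RR_l for one factor, cancer and sex."""
    prevs = factor.prevalences(sex)
    rrs = factor.rr_vector(cancer_type_id)
    return math.fsum(p * rr for p, rr in zip(prevs, rrs))


def analytic_true_paf(config: SimulationConfig, factor_ids,
                      cancer_type_id: str, sex: str) -> float:
    """True PAF of a factor subset: 1 - 1 / prod_f E[RR_f].

    Exact under the simulator's construction (independent factors,
    multiplicative joint risk). An empty subset yields 0.
    """
    config.cancer(cancer_type_id)  # raises on unknown cancer
    prod = 1.0
    for fid in factor_ids:
        prod *= expected_rr(config.factor(fid), cancer_type_id, sex)
    return 1.0 - 1.0 / prod


# ---------------------------------------------------------------------------
# simulation


@dataclass
class TruePafRecord:
    """Ground truth for one cell: analytic PAF, empirical (joint-removal)
    PAF, and its Monte-Carlo standard error."""

    factor_id: str  # a factor id, or "combined"
    cancer_type_id: str
    sex: str
    analytic_paf: float
    simulated_paf: float
    mc_standard_error: float


@dataclass
class SimulationResult:
    config: SimulationConfig
    paths: dict  # name -> file path (exposure, rr, incidence, truth)
    truth: list  # of TruePafRecord
    n_capped: int = 0


def _sex_counts(config: SimulationConfig) -> dict:
    n, k = config.n_individuals, len(config.sexes)
    base = n // k
    return {s: base + (1 if i < n % k else 0)
            for i, s in enumerate(config.sexes)}


def simulate_population(config: SimulationConfig,
                        outdir: str | os.PathLike) -> SimulationResult:
    """Draw the population, write the four pipeline tables, return truth.

    Reproducible: a given config (including its seed) always produces
    byte-identical files. Individuals whose joint risk exceeds 1 are
    capped; more than 0.1% capped aborts with configuration guidance.
    """
    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    factor_ids = [f.factor_id for f in config.factors]
    subsets = [(fid, (fid,)) for fid in factor_ids]
    subsets.append(("combined", tuple(factor_ids)))

    distributions: list[ExposureDistribution] = []
    incidence: list[IncidenceRecord] = []
    truth: list[TruePafRecord] = []
    n_capped = 0

    for sex, n_sex in _sex_counts(config).items():
        level_idx = {}
        emp_prev = {}
        for f in config.factors:
            prevs = np.asarray(f.prevalences(sex), dtype=float)
            idx = rng.choice(len(f.levels), size=n_sex, p=prevs)
            level_idx[f.factor_id] = idx
            emp_prev[f.factor_id] = np.bincount(idx, minlength=len(f.levels)) / n_sex
            distributions.append(ExposureDistribution(
                factor_id=f.factor_id, sex=sex,
                levels=tuple((lv.level_id, float(emp_prev[f.factor_id][j]))
                             for j, lv in enumerate(f.levels))))
        for c in config.cancers:
            base = c.baseline(sex)
            if base == 0.0:
                continue
            rr_per_factor = {
                f.factor_id: np.asarray(f.rr_vector(c.cancer_type_id))[
                    level_idx[f.factor_id]]
                for f in config.factors}
            p = base * np.prod(list(rr_per_factor.values()), axis=0)
            capped = p > 1.0
            n_capped += int(capped.sum())
            p = np.minimum(p, 1.0)
            u = rng.random(n_sex)
            cases = u < p
            n_obs = int(cases.sum())
            incidence.append(IncidenceRecord(
                cancer_type_id=c.cancer_type_id, sex=sex,
                year=config.incidence_year, cases=n_obs))
            for label, fids in subsets:
                removal = np.prod([rr_per_factor[fid] for fid in fids], axis=0)
                p_cf = np.minimum(p / removal, 1.0)
                n_cf = int((u < p_cf).sum())
                sim_paf = (n_obs - n_cf) / n_obs if n_obs else 0.0
                se = (math.sqrt(max(sim_paf * (1 - sim_paf), 1e-12) / n_obs)
                      if n_obs else float("inf"))
                truth.append(TruePafRecord(
                    factor_id=label, cancer_type_id=c.cancer_type_id, sex=sex,
                    analytic_paf=analytic_true_paf(config, fids,
                                                   c.cancer_type_id, sex),
                    simulated_paf=sim_paf, mc_standard_error=se))

    cap_frac = n_capped / max(
        1, config.n_individuals * sum(1 for c in config.cancers
                                      if any(c.baseline(s) > 0
                                             for s in config.sexes)))
    if cap_frac > _CAP_FRACTION:
        raise ConfigurationError(
            f"joint risk exceeded 1 for {cap_frac:.2%} of draws (> 0.1%); "
            "lower baseline risks or relative risks in the simulation config")

    rr_entries = [
        RelativeRiskEntry(factor_id=f.factor_id,
                          cancer_type_id=c.cancer_type_id, sex=sex,
                          level_id=lv.level_id, rr=lv.rr.get(c.cancer_type_id, 1.0),
                          significant=f.significant)
        for f in config.factors for c in config.cancers
        for sex in config.sexes if c.baseline(sex) > 0
        for lv in f.levels if lv.level_id != REFERENCE_LEVEL]

    paths = {name: os.path.join(outdir, f"{name}.csv")
             for name in ("exposure", "rr", "incidence", "truth")}
    tbl.write_exposure_table(distributions, paths["exposure"],
                             {fid: config.exposure_year for fid in factor_ids})
    tbl.write_rr_table(rr_entries, paths["rr"])
    tbl.write_incidence_table(incidence, paths["incidence"])
    write_truth_table(truth, paths["truth"])
    for p in paths.values():
        _prepend_line(p, f"# seed={config.seed}")
    return SimulationResult(config=config, paths=paths, truth=truth,
                            n_capped=n_capped)


def _prepend_line(path: str, line: str) -> None:
    with open(path, encoding="utf-8") as fh:
        body = fh.read()
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(line + "\n" + body)


def write_truth_table(truth: list, path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        [(t.factor_id, t.cancer_type_id, t.sex, repr(t.analytic_paf),
          repr(t.simulated_paf), repr(t.mc_standard_error)) for t in truth],
        columns=TRUTH_COLUMNS)
    df.to_csv(path, index=False, lineterminator="\n")


def read_truth_table(path: str | os.PathLike) -> list:
    df = pd.read_csv(path, comment="#")
    if list(df.columns) != TRUTH_COLUMNS:
        raise TableValidationError(
            f"header mismatch: expected {TRUTH_COLUMNS}", file=os.fspath(path))
    return [TruePafRecord(*rec) for rec in df.itertuples(index=False)]


# ---------------------------------------------------------------------------
# recovery experiment


def run_config_for(sim: SimulationResult,
                   min_incidence: int = 10) -> RunConfig:
    """Pipeline run configuration matching a simulation's outputs."""
    config = sim.config
    factors = {
        f.factor_id: {
            "evidence_mode": "rr_based",
            "framing": "harmful",
            "cancers": sorted({c.cancer_type_id for c in config.cancers
                               if any(lv.rr.get(c.cancer_type_id) is not None
                                      for lv in f.levels)}),
            "sexes": list(config.sexes),
            "exposure_year": config.exposure_year,
            "latency_years": config.latency_years,
        }
        for f in config.factors}
    return RunConfig(incidence_year=config.incidence_year,
                     tables={k: sim.paths[k] for k in
                             ("exposure", "rr", "incidence")},
                     factors=factors,
                     options=RunOptions(min_incidence=min_incidence,
                                        seed=config.seed))


def recovery_experiment(config: SimulationConfig,
                        workdir: str | os.PathLike) -> pd.DataFrame:
    """Simulate, run the full pipeline on the emitted tables, and compare.

    Returns one row per (factor or "combined", cancer, sex) with the
    pipeline PAF, the analytic and simulated truths, the Monte-Carlo SE,
    and whether the pipeline estimate falls within 3 SE of the simulated
    truth. Factors stamped ``significant=False`` are expected to recover a
    PAF of exactly 0, regardless of the simulated excess.
    """
    from .model import BurdenModel

    sim = simulate_population(config, workdir)
    results = BurdenModel.from_config(run_config_for(sim)).fit()

    pipeline_paf = {(r.factor_id, r.cancer_type_id, r.sex): r.paf
                    for r in results.attribution.rows}
    for r in results.attribution.combined:
        pipeline_paf[("combined", r.cancer_type_id, r.sex)] = r.paf

    rows = []
    for t in sim.truth:
        key = (t.factor_id, t.cancer_type_id, t.sex)
        pp = pipeline_paf.get(key)
        if pp is None:
            continue  # cell not modelled (e.g. factor without RRs there)
        expected = t.simulated_paf
        factor_sig = (t.factor_id == "combined"
                      or config.factor(t.factor_id).significant)
        if not factor_sig:
            expected = 0.0
        rows.append({
            "factor_id": t.factor_id, "cancer_type_id": t.cancer_type_id,
            "sex": t.sex, "pipeline_paf": pp,
            "analytic_paf": t.analytic_paf, "simulated_paf": t.simulated_paf,
            "mc_standard_error": t.mc_standard_error,
            "diff_simulated": pp - t.simulated_paf,
            "diff_analytic": pp - t.analytic_paf,
            "within_3se": abs(pp - expected) <= 3 * t.mc_standard_error,
        })
    return pd.DataFrame(rows)
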