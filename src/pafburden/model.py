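"""Model/Results objects for attributable-burden estimation.

:class:`BurdenModel` is built from the three (or four) input tables plus a
run configuration; :meth:`BurdenModel.fit` evaluates every (factor, cancer
type, sex) cell, combines factors multiplicatively per cell, rolls
subtypes up into their parents and returns a :class:`BurdenResults` whose
``summary()`` prints the per-factor burden table.

Usage::

    model = BurdenModel.from_config("run.yaml")
    res = model.fit()
    print(res.summary())
    res.save("out/")
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import pandas as pd

from . import tables as tbl
from .engine import PafValue, combine_pafs, paf_for_cell
from .exceptions import ConfigurationError, DataGapError
from .pipeline import (
    RunConfig,
    attributable_cases,
    check_factor_latency,
    filter_low_incidence,
    percentage,
)
from .types import (
    COMBINED_FACTOR,
    SEXES,
    AttributionRow,
    AttributionTable,
    DirectPafEntry,
    ExposureDistribution,
    IncidenceRecord,
    RelativeRiskEntry,
    RiskFactorSpec,
)


class BurdenModel:
    """Attributable cancer burden for a set of risk factors.

    Parameters
    ----------
    specs : list of RiskFactorSpec
        The risk factors and their evidence modes.
    distributions : list of ExposureDistribution
        Prevalence of exposure levels, per factor and sex.
    rr_entries : list of RelativeRiskEntry
        Relative risks per (factor, cancer type, sex, level).
    incidence : list of IncidenceRecord
        Registry-style case counts; only rows for ``incidence_year`` enter
        the fit.
    direct_pafs : list of DirectPafEntry, optional
        Published attributable fractions for direct-PAF factors.
    incidence_year : int
        The year whose burden is estimated.
    options : RunOptions-like, optional
        Engine options (minimum incidence, reduction transform, ...).
    """

    def __init__(self, specs, distributions, rr_entries, incidence,
                 direct_pafs=None, incidence_year=2018, options=None):
        from .pipeline import RunOptions

        self.specs: list[RiskFactorSpec] = list(specs)
        self.distributions: list[ExposureDistribution] = list(distributions)
        self.rr_entries: list[RelativeRiskEntry] = list(rr_entries)
        self.incidence: list[IncidenceRecord] = list(incidence)
        self.direct_pafs: list[DirectPafEntry] = list(direct_pafs or [])
        self.incidence_year = int(incidence_year)
        self.options = options or RunOptions()
        self._dist_by_key = {(d.factor_id, d.sex): d for d in self.distributions}
        self._direct_by_key = {(d.factor_id, d.cancer_type_id, d.sex): d
                               for d in self.direct_pafs}

    @classmethod
    def from_config(cls, config: RunConfig | str | os.PathLike) -> "BurdenModel":
        """Build a model from a run configuration (object or run.yaml path)."""
        if not isinstance(config, RunConfig):
            config = RunConfig.from_yaml(config)
        distributions = tbl.read_exposure_table(config.tables["exposure"])
        rr_entries = tbl.read_rr_table(config.tables["rr"])
        incidence = tbl.read_incidence_table(config.tables["incidence"])
        direct = (tbl.read_direct_paf_table(config.tables["direct_paf"])
                  if "direct_paf" in config.tables else [])
        specs = config.factor_specs()
        # exposure-table vintages must agree with the declared factor years
        years = tbl.read_exposure_years(config.tables["exposure"])
        for spec in specs:
            if spec.evidence_mode == "rr_based" and spec.factor_id in years \
                    and years[spec.factor_id] != spec.exposure_year:
                raise ConfigurationError(
                    f"factor {spec.factor_id!r}: exposure table vintage "
                    f"{years[spec.factor_id]} != configured exposure year "
                    f"{spec.exposure_year}")
        return cls(specs, distributions, rr_entries, incidence, direct,
                   incidence_year=config.incidence_year, options=config.options)

    # -- fitting -----------------------------------------------------------

    def fit(self) -> "BurdenResults":
        """Run the full attribution and return the results object."""
        for spec in self.specs:
            check_factor_latency(spec, self.incidence_year)

        year_records = [r for r in self.incidence if r.year == self.incidence_year]
        if not year_records:
            raise ConfigurationError(
                f"incidence table has no rows for year {self.incidence_year}")
        kept, excluded = filter_low_incidence(
            year_records, threshold=self.options.min_incidence,
            per_sex=self.options.per_sex_filter)
        cases_by_cell = {(r.cancer_type_id, r.sex): r.cases for r in kept}
        parent_of = {r.cancer_type_id: r.subtype_of for r in kept}

        log: list[str] = []
        for r in excluded:
            log.append(f"excluded {r.cancer_type_id}/{r.sex}: annual incidence "
                       f"{r.cases} below threshold {self.options.min_incidence}")
        for e in self.rr_entries:
            if not e.significant:
                log.append(f"forced RR=1 (not significant): "
                           f"{e.factor_id}/{e.cancer_type_id}/{e.sex}/{e.level_id}")

        rows: list[AttributionRow] = []
        pafs_by_cell: dict[tuple, list[PafValue]] = {}
        for spec in self.specs:
            for cancer in sorted(spec.linked_cancer_types):
                for sex in spec.sexes:
                    cases = cases_by_cell.get((cancer, sex))
                    if cases is None:
                        continue  # excluded or absent for this sex
                    paf = self._cell_paf(spec, cancer, sex)
                    attr = attributable_cases(paf, cases)
                    rows.append(AttributionRow(
                        factor_id=spec.factor_id, cancer_type_id=cancer,
                        sex=sex, paf=paf.value, attributable_cases=attr,
                        cases=cases))
                    pafs_by_cell.setdefault((cancer, sex), []).append(paf)

        combined: list[AttributionRow] = []
        for (cancer, sex), pafs in sorted(pafs_by_cell.items()):
            cpaf = combine_pafs(pafs)
            cases = cases_by_cell[(cancer, sex)]
            combined.append(AttributionRow(
                factor_id=COMBINED_FACTOR, cancer_type_id=cancer, sex=sex,
                paf=cpaf.value, attributable_cases=attributable_cases(cpaf, cases),
                cases=cases))

        table = AttributionTable(rows=rows, combined=combined)
        table.total_attributable = sum(r.attributable_cases for r in combined)
        # each case is counted once: subtype cases are contained in their
        # parent rows, so totals run over top-level diagnoses only
        table.total_cases = sum(r.cases for r in kept if r.subtype_of is None)
        return BurdenResults(model=self, attribution=table, kept=kept,
                             excluded=excluded, log=log, parent_of=parent_of)

    def _cell_paf(self, spec: RiskFactorSpec, cancer: str, sex: str) -> PafValue:
        if spec.evidence_mode == "direct_paf":
            entry = self._direct_by_key.get((spec.factor_id, cancer, sex))
            if entry is None:
                raise DataGapError(
                    f"no published PAF for ({spec.factor_id}, {cancer}, {sex})")
            return paf_for_cell(spec, direct=entry.paf, cancer_type_id=cancer)
        dist = self._dist_by_key.get((spec.factor_id, sex))
        if dist is None:
            raise DataGapError(
                f"no exposure distribution for ({spec.factor_id}, {sex})")
        return paf_for_cell(
            spec, dist=dist, rrs=self.rr_entries, cancer_type_id=cancer,
            reduction_transform=self.options.reduction_transform,
            allow_negative=self.options.allow_negative_paf)


@dataclass
class BurdenResults:
    """Fitted attributable-burden estimates.

    Attributes
    ----------
    attribution : AttributionTable
        Per-cell, combined and overall PAFs and attributable cases.
    kept, excluded : lists of IncidenceRecord
        The incidence rows that passed / failed the low-incidence filter.
    log : list of str
        Structured messages: exclusions, forced-null cells, warnings.
    """

    model: BurdenModel
    attribution: AttributionTable
    kept: list = field(default_factory=list)
    excluded: list = field(default_factory=list)
    log: list = field(default_factory=list)
    parent_of: dict = field(default_factory=dict)

    # -- views -------------------------------------------------------------

    @property
    def overall_paf(self) -> float:
        return self.attribution.overall_paf

    def factor_summary(self) -> pd.DataFrame:
        """Per-factor attributable cases and share of total burden
        (the headline per-factor view)."""
        recs: dict[str, float] = {}
        for r in self.attribution.rows:
            recs[r.factor_id] = recs.get(r.factor_id, 0.0) + r.attributable_cases
        total = self.attribution.total_cases
        df = pd.DataFrame(
            [(f, a, percentage(a / total)) for f, a in sorted(recs.items())],
            columns=["factor_id", "attributable_cases", "paf_pct"])
        return df.sort_values("attributable_cases", ascending=False,
                              kind="stable").reset_index(drop=True)

    def cancer_summary(self) -> pd.DataFrame:
        """Per cancer type (subtypes rolled into parents): cases, combined
        attributable cases, combined PAF %, by sex and both sexes."""
        attr: dict[tuple, float] = {}
        cases: dict[tuple, int] = {}
        for r in self.attribution.combined:
            target = self.parent_of.get(r.cancer_type_id) or r.cancer_type_id
            key = (target, r.sex)
            attr[key] = attr.get(key, 0.0) + r.attributable_cases
        for r in self.kept:
            if r.subtype_of is None:
                cases[(r.cancer_type_id, r.sex)] = r.cases
        recs = []
        for (cancer, sex), n in sorted(cases.items()):
            a = min(attr.get((cancer, sex), 0.0), float(n))
            recs.append((cancer, sex, n, a,
                         percentage(a / n) if n else 0.0))
        df = pd.DataFrame(recs, columns=["cancer_type_id", "sex", "cases",
                                         "attributable_cases", "paf_pct"])
        both = (df.groupby("cancer_type_id", as_index=False)
                  .agg(cases=("cases", "sum"),
                       attributable_cases=("attributable_cases", "sum")))
        both["sex"] = "all"
        both["paf_pct"] = [percentage(a / c) if c else 0.0
                           for a, c in zip(both.attributable_cases, both.cases)]
        return pd.concat([df, both[df.columns]], ignore_index=True)

    def summary(self) -> str:
        """Text report: overall burden, then the per-factor table."""
        t = self.attribution
        lines = [
            "Attributable burden summary",
            "===========================",
            f"Incidence year:          {self.model.incidence_year}",
            f"Total incident cases:    {t.total_cases:,}",
            f"Attributable cases:      {round(t.total_attributable):,}",
            f"Overall PAF:             {percentage(t.overall_paf):.1f}%",
            f"Diagnoses excluded (<{self.model.options.min_incidence}): "
            f"{len({r.cancer_type_id for r in self.excluded})}",
            "",
            "Per-factor burden",
            "-----------------",
        ]
        df = self.factor_summary()
        for rec in df.itertuples(index=False):
            lines.append(f"{rec.factor_id:<24s} {round(rec.attributable_cases):>8,}"
                         f" {rec.paf_pct:>6.1f}%")
        return "\n".join(lines)

    # -- output ------------------------------------------------------------

    def save(self, outdir: str | os.PathLike) -> dict:
        """Write attribution.csv, the factor/cancer summaries and run.log.

        Byte-identical across runs on identical inputs.
        """
        os.makedirs(outdir, exist_ok=True)
        paths = {
            "attribution": os.path.join(outdir, "attribution.csv"),
            "factor_summary": os.path.join(outdir, "factor_summary.csv"),
            "cancer_summary": os.path.join(outdir, "cancer_summary.csv"),
            "log": os.path.join(outdir, "run.log"),
        }
        tbl.write_attribution_table(self.attribution, paths["attribution"])
        self.factor_summary().to_csv(paths["factor_summary"], index=False,
                                     lineterminator="\n")
        self.cancer_summary().to_csv(paths["cancer_summary"], index=False,
                                     lineterminator="\n")
        with open(paths["log"], "w", encoding="utf-8") as fh:
            for line in self.log:
                fh.write(line + "\n")
        return paths

    def plot_factor_summary(self, ax=None):
        """Horizontal bar chart of attributable cases per factor."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        df = self.factor_summary().iloc[::-1]
        ax.barh(df.factor_id, df.attributable_cases)
        ax.set_xlabel("Attributable cases")
        ax.set_title(f"Attributable burden, {self.model.incidence_year} "
                     f"(overall PAF {percentage(self.overall_paf):.1f}%)")
        return ax
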