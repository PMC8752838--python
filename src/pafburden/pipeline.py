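"""Run-level operations: incidence filtering, latency linkage, case
attribution arithmetic, overall aggregation, and the run configuration.

The heavy lifting (PAF computation per cell, combination, rollups) lives
in :mod:`pafburden.model`; this module holds the free-standing operations
the model composes, so each is independently testable.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import yaml

from .exceptions import ConfigurationError, DomainError
from .types import AttributionTable, IncidenceRecord, RiskFactorSpec

DEFAULT_MIN_INCIDENCE = 10


def filter_low_incidence(records: list[IncidenceRecord],
                         threshold: int = DEFAULT_MIN_INCIDENCE,
                         per_sex: bool = False,
                         ) -> tuple[list[IncidenceRecord], list[IncidenceRecord]]:
    """Drop diagnoses with an annual population incidence below ``threshold``.

    By default a diagnosis is excluded iff its total annual cases summed
    over both sexes is below the threshold ("population incidence" reads
    on the whole population, not per-sex counts); ``per_sex=True`` applies
    the threshold to each (diagnosis, sex) count instead.

    Returns ``(kept, excluded)`` preserving input order.
    """
    if threshold < 1:
        raise DomainError(f"threshold must be a positive integer, got {threshold}")
    if per_sex:
        kept = [r for r in records if r.cases >= threshold]
        excluded = [r for r in records if r.cases < threshold]
        return kept, excluded
    totals: dict[tuple[str, int], int] = {}
    for r in records:
        key = (r.cancer_type_id, r.year)
        totals[key] = totals.get(key, 0) + r.cases
    kept = [r for r in records if totals[(r.cancer_type_id, r.year)] >= threshold]
    excluded = [r for r in records if totals[(r.cancer_type_id, r.year)] < threshold]
    return kept, excluded


def link_latency(exposure_year: int, incidence_year: int,
                 latency_years: int) -> bool:
    """True iff the exposure vintage matches the incidence year minus the
    assumed latency (e.g. 2008 exposure, 2018 incidence, 10-year latency).
    """
    for y in (exposure_year, incidence_year):
        if not (1900 <= y <= 2100):
            raise DomainError(f"implausible calendar year {y}")
    if latency_years < 0:
        raise DomainError(f"latency_years must be >= 0, got {latency_years}")
    return incidence_year - exposure_year == latency_years


def check_factor_latency(spec: RiskFactorSpec, incidence_year: int) -> None:
    """Raise a configuration error naming the factor on a latency mismatch."""
    if not link_latency(spec.exposure_year, incidence_year, spec.latency_years):
        raise ConfigurationError(
            f"factor {spec.factor_id!r}: exposure year {spec.exposure_year} + "
            f"latency {spec.latency_years} != incidence year {incidence_year}; "
            "bind the exposure table vintage to the incidence year")


def attributable_cases(paf, cases: int) -> float:
    """PAF x incident cases, unrounded (rounding is presentation-only)."""
    v = getattr(paf, "value", paf)
    if not (0.0 <= v <= 1.0):
        raise DomainError(f"paf {v} outside [0, 1]")
    if cases < 0:
        raise DomainError(f"cases must be >= 0, got {cases}")
    return v * cases


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (the convention of printed percentages),
    unlike banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    d = Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP)
    return float(d)


def percentage(fraction: float, ndigits: int = 1) -> float:
    """Report a fraction as a percentage rounded half-away-from-zero."""
    return round_half_away(100.0 * fraction, ndigits)


def aggregate_overall(table: AttributionTable, total_cases: int) -> dict:
    """Overall burden summary from the combined rows of an attribution table.

    Overall attributable cases are the exact sum of the combined rows;
    the overall PAF is that sum divided by ``total_cases``, reported as a
    percentage rounded to one decimal.
    """
    if total_cases <= 0:
        raise DomainError(f"total_cases must be positive, got {total_cases}")
    if not table.combined:
        raise DomainError("attribution table has no combined rows to aggregate")
    total_attr = sum(r.attributable_cases for r in table.combined)
    overall_paf = total_attr / total_cases
    return {
        "total_cases": total_cases,
        "total_attributable": total_attr,
        "overall_paf": overall_paf,
        "overall_paf_pct": percentage(overall_paf),
    }


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunOptions:
    min_incidence: int = DEFAULT_MIN_INCIDENCE
    per_sex_filter: bool = False
    reduction_transform: str = "log"  # "log" | "power"
    allow_negative_paf: bool = False
    seed: int | None = None


@dataclass
class RunConfig:
    """Everything a burden run needs: table paths, the incidence year,
    per-factor metadata, and engine options."""

    incidence_year: int
    tables: dict = field(default_factory=dict)  # exposure, rr, incidence, direct_paf
    factors: dict = field(default_factory=dict)  # factor_id -> spec kwargs
    options: RunOptions = field(default_factory=RunOptions)

    REQUIRED_TABLES = ("exposure", "rr", "incidence")

    def __post_init__(self):
        for name in self.REQUIRED_TABLES:
            if name not in self.tables:
                raise ConfigurationError(f"config omits the {name!r} table path")
        if not self.factors:
            raise ConfigurationError("config declares no risk factors")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigurationError(f"{path}: not a mapping")
        try:
            incidence_year = int(raw["incidence_year"])
        except KeyError:
            raise ConfigurationError(f"{path}: missing incidence_year") from None
        tables = dict(raw.get("tables") or {})
        base = os.path.dirname(os.fspath(path))
        tables = {k: v if os.path.isabs(v) else os.path.join(base, v)
                  for k, v in tables.items()}
        opts = RunOptions(**(raw.get("options") or {}))
        return cls(incidence_year=incidence_year, tables=tables,
                   factors=dict(raw.get("factors") or {}), options=opts)

    def factor_specs(self) -> list[RiskFactorSpec]:
        specs = []
        for factor_id, kw in self.factors.items():
            kw = dict(kw)
            specs.append(RiskFactorSpec(
                factor_id=factor_id,
                display_name=kw.get("display_name", factor_id),
                evidence_mode=kw.get("evidence_mode", "rr_based"),
                framing=kw.get("framing",
                               "harmful" if kw.get("evidence_mode", "rr_based")
                               == "rr_based" else None),
                n_units=kw.get("n_units"),
                linked_cancer_types=frozenset(kw.get("cancers", ())),
                sexes=tuple(kw.get("sexes", ("male", "female"))),
                exposure_year=int(kw.get("exposure_year",
                                         self.incidence_year - kw.get(
                                             "latency_years", 10))),
                latency_years=int(kw.get("latency_years", 10)),
            ))
        return specs


def run_pipeline(config: RunConfig | str | os.PathLike, outdir: str | os.PathLike):
    """Execute a full burden run and write its report files.

    Accepts a :class:`RunConfig` or a path to a ``run.yaml``. Writes
    ``attribution.csv``, ``factor_summary.csv``, ``cancer_summary.csv``
    and ``run.log`` into ``outdir``. Returns the fitted results object.
    Deterministic: identical inputs yield byte-identical outputs.
    """
    from .model import BurdenModel

    if not isinstance(config, RunConfig):
        config = RunConfig.from_yaml(config)
    results = BurdenModel.from_config(config).fit()
    results.save(outdir)
    return results
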