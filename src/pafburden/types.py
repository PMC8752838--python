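"""Domain types for attributable-burden calculations.

The vocabulary follows comparative risk assessment practice: a *risk
factor* exposes a share of the population (its :class:`ExposureDistribution`)
to elevated relative risks (:class:`RelativeRiskEntry`) for one or more
cancer types; incidence comes from a registry-style count table
(:class:`IncidenceRecord`); the result of a run is an
:class:`AttributionTable` of population attributable fractions (PAFs) and
attributable case counts.

All types validate their invariants on construction: no partially valid
object escapes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .exceptions import DomainError, TableValidationError

SEXES = ("male", "female")

#: Reserved level identifier for the unexposed / baseline stratum.
REFERENCE_LEVEL = "reference"

#: Reserved factor identifier for the combined (all factors jointly) rows
#: of an attribution table.
COMBINED_FACTOR = "__combined__"

#: Reserved factor identifier for the overall summary row.
OVERALL_FACTOR = "__overall__"
OVERALL_CANCER = "__all__"
OVERALL_SEX = "all"

_PROP_TOL = 1e-9


def _check_sex(sex: str) -> str:
    if sex not in SEXES:
        raise TableValidationError(f"unknown sex {sex!r}; expected one of {SEXES}")
    return sex


@dataclass(frozen=True)
class RiskFactorSpec:
    """A risk factor and how its evidence enters the calculation.

    Parameters
    ----------
    factor_id : str
        Short identifier, e.g. ``"smoking"``.
    display_name : str
        Human-readable name used in reports.
    evidence_mode : {"rr_based", "direct_paf"}
        ``rr_based`` factors are computed from prevalence and relative
        risks via the Levin formula; ``direct_paf`` factors adopt a
        published attributable fraction as-is (e.g. HPV, occupation, UV).
    framing : {"harmful", "reduction"}, optional
        Only for ``rr_based``. ``harmful``: the published RR describes the
        exposed-vs-unexposed contrast, so ERR = RR - 1. ``reduction``: the
        RR describes a lower-risk contrast (e.g. active vs inactive) and
        the harmful-direction ERR is ln(1/RR), scaled per exposure unit.
    n_units : int, optional
        Number of exposure units the published reduction-framed RR spans;
        the per-unit ERR divides by this. Only for ``framing="reduction"``.
    linked_cancer_types : frozenset of str
        Cancer types with a class-I-level causal link to this factor.
    sexes : tuple of str
        Subset of ("male", "female") the factor applies to.
    exposure_year : int
        Calendar year of the exposure-prevalence data.
    latency_years : int
        Assumed exposure-to-incidence latency (10 years in the base
        analysis; alternative latencies mean alternative exposure-table
        vintages, not lag modelling).
    """

    factor_id: str
    display_name: str
    evidence_mode: str
    linked_cancer_types: frozenset
    sexes: tuple = SEXES
    framing: str | None = None
    n_units: int | None = None
    exposure_year: int = 2008
    latency_years: int = 10

    def __post_init__(self):
        if self.evidence_mode not in ("rr_based", "direct_paf"):
            raise TableValidationError(
                f"factor {self.factor_id!r}: evidence_mode must be 'rr_based' or "
                f"'direct_paf', got {self.evidence_mode!r}")
        if self.evidence_mode == "rr_based":
            if self.framing not in ("harmful", "reduction"):
                raise TableValidationError(
                    f"factor {self.factor_id!r}: rr_based factors need framing "
                    f"'harmful' or 'reduction', got {self.framing!r}")
            if self.framing == "reduction":
                if self.n_units is None or self.n_units < 1:
                    raise TableValidationError(
                        f"factor {self.factor_id!r}: reduction framing requires "
                        f"n_units >= 1, got {self.n_units!r}")
        else:
            if self.framing is not None or self.n_units is not None:
                raise TableValidationError(
                    f"factor {self.factor_id!r}: direct_paf factors carry no "
                    "framing or n_units")
        if not self.linked_cancer_types:
            raise TableValidationError(
                f"factor {self.factor_id!r}: linked_cancer_types is empty")
        for s in self.sexes:
            _check_sex(s)
        if self.latency_years < 0:
            raise TableValidationError(
                f"factor {self.factor_id!r}: latency_years must be >= 0")


@dataclass(frozen=True)
class ExposureDistribution:
    """Prevalence proportions over exposure levels for one factor and sex.

    ``levels`` is an ordered tuple of ``(level_id, proportion)`` pairs and
    always contains the reference level explicitly; constructors accept an
    implicit reference and materialise it as 1 - sum(others).
    """

    factor_id: str
    sex: str
    levels: tuple  # ((level_id, proportion), ...)
    reference_level_id: str = REFERENCE_LEVEL

    def __post_init__(self):
        _check_sex(self.sex)
        ids = [lid for lid, _ in self.levels]
        if len(set(ids)) != len(ids):
            raise TableValidationError(
                f"factor {self.factor_id!r} ({self.sex}): duplicate level ids")
        total = 0.0
        for lid, p in self.levels:
            if not (0.0 <= p <= 1.0 + _PROP_TOL):
                raise TableValidationError(
                    f"factor {self.factor_id!r} ({self.sex}): proportion {p} for "
                    f"level {lid!r} outside [0, 1]")
            total += p
        if total > 1.0 + _PROP_TOL:
            raise TableValidationError(
                f"factor {self.factor_id!r} ({self.sex}): level proportions sum "
                f"to {total:.6g} > 1")
        if self.reference_level_id not in ids:
            raise TableValidationError(
                f"factor {self.factor_id!r} ({self.sex}): reference level "
                f"{self.reference_level_id!r} missing from levels")

    @classmethod
    def from_nonreference(cls, factor_id: str, sex: str,
                          levels: list[tuple[str, float]],
                          reference_level_id: str = REFERENCE_LEVEL,
                          ) -> "ExposureDistribution":
        """Build a distribution from non-reference levels only.

        The reference proportion is materialised as 1 - sum(p). An explicit
        reference row among ``levels`` is accepted and normalised.
        """
        explicit = [(lid, p) for lid, p in levels if lid == reference_level_id]
        others = [(lid, float(p)) for lid, p in levels if lid != reference_level_id]
        nonref_sum = sum(p for _, p in others)
        if nonref_sum > 1.0 + _PROP_TOL:
            raise TableValidationError(
                f"factor {factor_id!r} ({sex}): non-reference proportions sum to "
                f"{nonref_sum:.6g} > 1")
        if explicit:
            ref_p = float(explicit[0][1])
            if abs(ref_p + nonref_sum - 1.0) > 1e-6:
                raise TableValidationError(
                    f"factor {factor_id!r} ({sex}): explicit reference proportion "
                    f"{ref_p} inconsistent with 1 - sum(others) = {1 - nonref_sum:.6g}")
        else:
            ref_p = 1.0 - nonref_sum
        return cls(factor_id=factor_id, sex=sex,
                   levels=tuple(others) + ((reference_level_id, ref_p),),
                   reference_level_id=reference_level_id)

    @property
    def nonreference_levels(self) -> tuple:
        return tuple((lid, p) for lid, p in self.levels
                     if lid != self.reference_level_id)

    @property
    def reference_proportion(self) -> float:
        return dict(self.levels)[self.reference_level_id]


@dataclass(frozen=True)
class RelativeRiskEntry:
    """RR for one factor x cancer type x exposure level x sex.

    ``significant=False`` marks an association judged not statistically
    supported; downstream the effective RR is forced to 1 (zero excess),
    so the factor contributes nothing for that cell while remaining an
    explicit, auditable input.
    """

    factor_id: str
    cancer_type_id: str
    sex: str
    level_id: str
    rr: float
    significant: bool = True

    def __post_init__(self):
        _check_sex(self.sex)
        if not (self.rr > 0) or not math.isfinite(self.rr):
            raise TableValidationError(
                f"RR for ({self.factor_id}, {self.cancer_type_id}, {self.sex}, "
                f"{self.level_id}) must be a positive finite number, got {self.rr}")


@dataclass(frozen=True)
class IncidenceRecord:
    """Registry-style case count for one cancer type, sex and year."""

    cancer_type_id: str
    sex: str
    year: int
    cases: int
    subtype_of: str | None = None

    def __post_init__(self):
        _check_sex(self.sex)
        if self.cases < 0:
            raise TableValidationError(
                f"incidence for ({self.cancer_type_id}, {self.sex}, {self.year}) "
                f"has negative cases {self.cases}")


@dataclass(frozen=True)
class DirectPafEntry:
    """A published attributable fraction adopted as-is for one cell."""

    factor_id: str
    cancer_type_id: str
    sex: str
    paf: float

    def __post_init__(self):
        _check_sex(self.sex)
        if not (0.0 <= self.paf <= 1.0):
            raise TableValidationError(
                f"direct PAF for ({self.factor_id}, {self.cancer_type_id}, "
                f"{self.sex}) must lie in [0, 1], got {self.paf}")


@dataclass(frozen=True)
class AttributionRow:
    """One (factor, cancer type, sex) cell of an attribution table."""

    factor_id: str
    cancer_type_id: str
    sex: str
    paf: float
    attributable_cases: float
    cases: int

    def __post_init__(self):
        if not (-1e-12 <= self.paf <= 1.0 + 1e-12):
            raise DomainError(
                f"paf {self.paf} outside [0, 1] for ({self.factor_id}, "
                f"{self.cancer_type_id}, {self.sex})")
        if self.attributable_cases < -1e-9:
            raise DomainError("attributable_cases must be >= 0")
        if self.attributable_cases > self.cases + 1e-6:
            raise DomainError(
                f"attributable cases {self.attributable_cases} exceed incident "
                f"cases {self.cases} for ({self.factor_id}, "
                f"{self.cancer_type_id}, {self.sex})")


@dataclass
class AttributionTable:
    """Full output of a burden run.

    ``rows``: per-factor cells. ``combined``: one row per (cancer type, sex)
    with the multiplicatively combined PAF over all factors acting on that
    cell (factor_id == ``__combined__``). ``total_cases``,
    ``total_attributable`` and ``overall_paf`` summarise the whole run.
    """

    rows: list = field(default_factory=list)
    combined: list = field(default_factory=list)
    total_cases: int = 0
    total_attributable: float = 0.0

    @property
    def overall_paf(self) -> float:
        if self.total_cases == 0:
            return 0.0
        return self.total_attributable / self.total_cases
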