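"""The attributable-fraction engine.

Three operations make up the computational core:

* :func:`err_from_rr` turns a published relative risk into an excess
  relative risk (ERR), honouring the framing of the published contrast.
* :func:`paf_levin` evaluates the multi-level Levin formula

      PAF = S / (1 + S),   S = sum_i p_i * ERR_i

  over the non-reference exposure levels i, where p_i is the population
  proportion at level i.
* :func:`combine_pafs` combines single-factor PAFs into a joint PAF by
  applying each factor only to the cases not already attributed:
  1 - prod_i (1 - PAF_i). The product form is order-free.

No file I/O happens here; the layer consumes domain types and returns
:class:`PafValue` / :class:`ErrVector`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .exceptions import DataGapError, DomainError
from .types import ExposureDistribution, RelativeRiskEntry, RiskFactorSpec


@dataclass(frozen=True)
class ErrVector:
    """Per-level excess relative risks aligned with an exposure distribution.

    ``entries`` is an ordered tuple of ``(level_id, p, err)``; the
    reference level is present with err = 0.
    """

    factor_id: str
    cancer_type_id: str
    sex: str
    entries: tuple  # ((level_id, p, err), ...)
    reference_level_id: str

    def __post_init__(self):
        ref = [e for e in self.entries if e[0] == self.reference_level_id]
        if len(ref) != 1:
            raise DomainError("ErrVector must contain exactly one reference level")
        if ref[0][2] != 0.0:
            raise DomainError("reference level must carry err = 0")
        for _, _, err in self.entries:
            if err < -1.0:
                raise DomainError(f"ERR {err} below -1 is impossible (RR >= 0)")

    @property
    def nonreference(self) -> tuple:
        return tuple(e for e in self.entries if e[0] != self.reference_level_id)


@dataclass(frozen=True)
class PafValue:
    """A population attributable fraction with its provenance.

    Lies in [0, 1) whenever all ERRs are >= 0; a signed (net-protective)
    value is unbounded below and only arises when explicitly allowed.
    """

    value: float
    source: str = "computed"  # "computed" | "direct"

    def __post_init__(self):
        if self.source not in ("computed", "direct"):
            raise DomainError(f"unknown PAF source {self.source!r}")
        if not (self.value < 1.0 + 1e-12):
            raise DomainError(f"PAF {self.value} must be below 1")


def err_from_rr(rr: float, framing: str = "harmful", n_units: int = 1,
                significant: bool = True,
                reduction_transform: str = "log") -> float:
    """Excess relative risk for one exposure level.

    Parameters
    ----------
    rr : float
        Published relative risk, > 0.
    framing : {"harmful", "reduction"}
        ``harmful``: RR contrasts exposed vs unexposed; ERR = RR - 1.
        ``reduction``: RR contrasts a lower-risk state (e.g. physically
        active vs inactive); the harmful-direction ERR is ln(1/RR),
        divided by ``n_units`` when the published RR spans several
        exposure units.
    n_units : int
        Number of exposure units the reduction-framed RR spans (>= 1).
        Ignored (with a warning) for harmful framing.
    significant : bool
        False forces the effective RR to 1, i.e. a zero ERR: the
        association is a recognised carcinogen link whose risk estimate
        was not statistically supported, so it must not contribute.
    reduction_transform : {"log", "power"}
        ``log`` is the literal per-unit transform ln(1/RR)/n_units;
        ``power`` is the multiplicative alternative (1/RR)^(1/n_units) - 1,
        exposed for sensitivity analysis. The two agree to first order in
        (RR - 1).

    Returns
    -------
    float
        ERR >= -1 for the level; 0 for null or non-significant input.
    """
    if not (rr > 0) or not math.isfinite(rr):
        raise DomainError(f"rr must be positive and finite, got {rr}")
    if n_units < 1:
        raise DomainError(f"n_units must be >= 1, got {n_units}")
    if framing not in ("harmful", "reduction"):
        raise DomainError(f"unknown framing {framing!r}")
    if reduction_transform not in ("log", "power"):
        raise DomainError(f"unknown reduction_transform {reduction_transform!r}")
    if not significant:
        return 0.0
    if framing == "harmful":
        if n_units > 1:
            warnings.warn(
                f"n_units={n_units} ignored for harmful framing (ERR = RR - 1)",
                stacklevel=2)
        return rr - 1.0
    if reduction_transform == "log":
        return math.log(1.0 / rr) / n_units
    return (1.0 / rr) ** (1.0 / n_units) - 1.0


def paf_levin(errs: ErrVector, allow_negative: bool = False) -> PafValue:
    """Multi-level Levin attributable fraction S/(1+S), S = sum p_i ERR_i.

    Equivalent to the exact excess-case fraction of a stratified
    population where stratum i has proportion p_i and risk baseline *
    (1 + ERR_i). Negative S (a net-protective factor) raises unless
    ``allow_negative`` is set, in which case the signed value is
    returned.
    """
    s = math.fsum(p * err for _, p, err in errs.nonreference)
    if 1.0 + s <= 0.0:
        raise DomainError(
            f"1 + sum(p*ERR) = {1 + s:.6g} <= 0: inconsistent inputs")
    if s < 0.0 and not allow_negative:
        raise DomainError(
            f"net-protective input (sum p*ERR = {s:.6g} < 0); only the harmful "
            "direction of each factor is considered unless allow_negative=True")
    return PafValue(value=s / (1.0 + s), source="computed")


def combine_pafs(pafs: list) -> PafValue:
    """Joint PAF of several factors: 1 - prod(1 - PAF_i).

    Identical to attributing each factor sequentially to only the cases
    not yet attributed, and therefore independent of factor order. The
    result lies in [max PAF_i, min(1, sum PAF_i)].
    """
    residual = 1.0
    for paf in pafs:
        v = paf.value if isinstance(paf, PafValue) else float(paf)
        if not (0.0 <= v <= 1.0):
            raise DomainError(f"PAF {v} outside [0, 1]")
        residual *= 1.0 - v
    return PafValue(value=1.0 - residual, source="computed")


def build_err_vector(spec: RiskFactorSpec, dist: ExposureDistribution,
                     rrs: list[RelativeRiskEntry], cancer_type_id: str,
                     reduction_transform: str = "log") -> ErrVector:
    """Align an exposure distribution with its RR entries into an ErrVector.

    Every non-reference level of the distribution must have a matching RR
    row; a missing level is a data gap, never a silent RR = 1.
    """
    rr_by_level = {e.level_id: e for e in rrs
                   if e.factor_id == spec.factor_id
                   and e.cancer_type_id == cancer_type_id
                   and e.sex == dist.sex}
    entries = []
    for level_id, p in dist.levels:
        if level_id == dist.reference_level_id:
            entries.append((level_id, p, 0.0))
            continue
        entry = rr_by_level.get(level_id)
        if entry is None:
            raise DataGapError(
                f"no RR for cell (factor={spec.factor_id}, "
                f"cancer={cancer_type_id}, sex={dist.sex}, level={level_id}); "
                "state deliberate nulls with significant=false")
        err = err_from_rr(entry.rr, framing=spec.framing,
                          n_units=spec.n_units or 1,
                          significant=entry.significant,
                          reduction_transform=reduction_transform)
        entries.append((level_id, p, err))
    return ErrVector(factor_id=spec.factor_id, cancer_type_id=cancer_type_id,
                     sex=dist.sex, entries=tuple(entries),
                     reference_level_id=dist.reference_level_id)


def paf_for_cell(spec: RiskFactorSpec, dist: ExposureDistribution | None = None,
                 rrs: list[RelativeRiskEntry] | None = None,
                 cancer_type_id: str | None = None,
                 direct: PafValue | float | None = None,
                 reduction_transform: str = "log",
                 allow_negative: bool = False) -> PafValue:
    """PAF for one (factor, cancer type, sex) cell.

    Direct-PAF factors pass the published value through unchanged;
    RR-based factors evaluate the Levin formula on the ERR vector built
    from the aligned prevalence and RR inputs.
    """
    if spec.evidence_mode == "direct_paf":
        if direct is None:
            raise DataGapError(
                f"factor {spec.factor_id!r} is direct_paf but no published PAF "
                f"was supplied for cancer {cancer_type_id!r}")
        v = direct.value if isinstance(direct, PafValue) else float(direct)
        if not (0.0 <= v <= 1.0):
            raise DomainError(f"direct PAF {v} outside [0, 1]")
        return PafValue(value=v, source="direct")
    if dist is None or rrs is None or cancer_type_id is None:
        raise DataGapError(
            f"factor {spec.factor_id!r} is rr_based and needs an exposure "
            "distribution, RR entries and a cancer type")
    if cancer_type_id not in spec.linked_cancer_types:
        raise DataGapError(
            f"cancer {cancer_type_id!r} is not linked to factor "
            f"{spec.factor_id!r}")
    errs = build_err_vector(spec, dist, rrs, cancer_type_id,
                            reduction_transform=reduction_transform)
    return paf_levin(errs, allow_negative=allow_negative)
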