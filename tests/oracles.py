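"""Independent oracles used by the test suite.

These deliberately avoid the package's own formulas: the attributable
fraction is computed by fully enumerating a stratified population, and
joint effects by brute-force stratum products.
"""

from __future__ import annotations

import math


def exact_paf_enumeration(strata):
    """Exact excess-case fraction of a stratified population.

    ``strata`` is a list of (proportion, relative_risk) covering the whole
    population (proportions sum to 1, reference stratum has RR = 1). With
    baseline risk r, stratum i contributes p_i * r * RR_i cases; the
    excess over the all-reference population r is the attributable
    fraction. The baseline r cancels, so it is set to 1.
    """
    total = math.fsum(p * rr for p, rr in strata)
    baseline = math.fsum(p for p, _ in strata)  # = 1 when proportions sum to 1
    return (total - baseline) / total


def exact_joint_paf_enumeration(factor_strata):
    """Exact joint attributable fraction of independent multiplicative factors.

    ``factor_strata``: list over factors of [(p, RR), ...]. Enumerates the
    full cross-product of strata.
    """
    import itertools

    total = 0.0
    for combo in itertools.product(*factor_strata):
        p = math.prod(p for p, _ in combo)
        rr = math.prod(rr for _, rr in combo)
        total += p * rr
    return (total - 1.0) / total
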