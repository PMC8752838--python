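"""Unit and property tests for the ERR / Levin / combination core."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pafburden import (
    DataGapError,
    DomainError,
    ErrVector,
    ExposureDistribution,
    PafValue,
    RelativeRiskEntry,
    RiskFactorSpec,
    build_err_vector,
    combine_pafs,
    err_from_rr,
    paf_for_cell,
    paf_levin,
)

from oracles import exact_paf_enumeration


def make_err_vector(entries, factor="f", cancer="c", sex="male"):
    return ErrVector(factor_id=factor, cancer_type_id=cancer, sex=sex,
                     entries=tuple(entries) + (
                         ("reference", 1 - sum(p for _, p, _ in entries), 0.0),),
                     reference_level_id="reference")


class TestErrFromRr:
    @pytest.mark.parametrize("rr, framing, n_units, significant, expected", [
        (1.0, "harmful", 1, True, 0.0),
        (2.0, "harmful", 1, True, 1.0),
        (0.5, "reduction", 1, True, math.log(2.0)),
        (0.5, "reduction", 5, True, math.log(2.0) / 5),
        (3.7, "harmful", 1, False, 0.0),
        (0.71, "reduction", 1, False, 0.0),
    ])
    def test_published_rr_to_err(self, rr, framing, n_units, significant,
                                 expected):
        assert err_from_rr(rr, framing, n_units, significant) == pytest.approx(
            expected, abs=1e-12)

    @pytest.mark.parametrize("rr", [0.0, -1.0, float("inf"), float("nan")])
    def test_nonpositive_rr_rejected(self, rr):
        with pytest.raises(DomainError):
            err_from_rr(rr, "harmful", 1, True)

    def test_units_ignored_for_harmful_framing_with_warning(self):
        with pytest.warns(UserWarning, match="ignored"):
            assert err_from_rr(2.0, "harmful", 3, True) == 1.0

    def test_power_transform_alternative(self):
        # (1/RR)^(1/n) - 1: multiplicative per-unit reading
        got = err_from_rr(0.5, "reduction", 5, True,
                          reduction_transform="power")
        assert got == pytest.approx(2.0 ** 0.2 - 1.0, abs=1e-12)

    def test_reduction_and_harmful_framings_agree_to_first_order(self):
        # ln(1/RR) ~= 1/RR - 1 near RR = 1
        for rr in [0.9 + 0.01 * i for i in range(21)]:
            diff = err_from_rr(rr, "reduction", 1, True) - err_from_rr(
                1.0 / rr, "harmful", 1, True)
            assert abs(diff) <= (rr - 1.0) ** 2


class TestPafLevin:
    def test_single_level_matches_two_stratum_enumeration(self):
        # exposed half at RR 2, unexposed half at RR 1
        got = paf_levin(make_err_vector([("x", 0.5, 1.0)]))
        assert got.value == pytest.approx(1.0 / 3.0, abs=1e-12)
        assert got.value == pytest.approx(
            exact_paf_enumeration([(0.5, 2.0), (0.5, 1.0)]), abs=1e-12)

    def test_two_levels_match_three_stratum_enumeration(self):
        got = paf_levin(make_err_vector([("a", 0.3, 0.5), ("b", 0.1, 2.0)]))
        assert got.value == pytest.approx(0.35 / 1.35, abs=1e-12)
        assert got.value == pytest.approx(exact_paf_enumeration(
            [(0.3, 1.5), (0.1, 3.0), (0.6, 1.0)]), abs=1e-12)

    def test_no_excess_risk_gives_zero(self):
        got = paf_levin(make_err_vector([("a", 0.4, 0.0), ("b", 0.2, 0.0)]))
        assert got == PafValue(0.0, "computed")

    def test_net_protective_rejected_unless_allowed(self):
        ev = make_err_vector([("a", 0.5, -0.4)])
        with pytest.raises(DomainError):
            paf_levin(ev)
        assert paf_levin(ev, allow_negative=True).value == pytest.approx(
            -0.2 / 0.8, abs=1e-12)

    @given(st.lists(st.tuples(st.floats(0.001, 0.3),
                              st.floats(0.2, 10.0)),
                    min_size=1, max_size=3))
    @settings(max_examples=200, derandomize=True)
    def test_levin_equals_enumeration(self, levels):
        entries = [(f"l{i}", p, rr - 1.0)
                   for i, (p, rr) in enumerate(levels)]
        strata = [(p, rr) for p, rr in levels]
        strata.append((1 - sum(p for p, _ in levels), 1.0))
        got = paf_levin(make_err_vector(entries), allow_negative=True)
        assert got.value == pytest.approx(exact_paf_enumeration(strata),
                                          abs=1e-12)

    @given(st.floats(0.01, 0.3), st.floats(1.0, 5.0), st.floats(0.0, 0.2),
           st.floats(0.0, 2.0))
    @settings(max_examples=100, derandomize=True)
    def test_monotone_in_prevalence_and_err(self, p, rr, dp, derr):
        base = paf_levin(make_err_vector([("x", p, rr - 1.0)])).value
        more_p = paf_levin(make_err_vector([("x", p + dp, rr - 1.0)])).value
        more_e = paf_levin(make_err_vector([("x", p, rr - 1.0 + derr)])).value
        assert more_p >= base - 1e-15
        assert more_e >= base - 1e-15


class TestCombinePafs:
    def test_two_independent_halves_combine_to_three_quarters(self):
        assert combine_pafs([0.5, 0.5]).value == 0.75

    @pytest.mark.parametrize("pafs, expected", [
        ([0.3], 0.3),
        ([0.3, 0.0, 0.0], 0.3),
        ([0.0, 0.0], 0.0),
        ([1.0, 0.4], 1.0),
    ])
    def test_degenerate_lists(self, pafs, expected):
        assert combine_pafs(pafs).value == pytest.approx(expected, abs=1e-15)

    def test_out_of_range_paf_rejected(self):
        with pytest.raises(DomainError):
            combine_pafs([0.5, 1.2])
        with pytest.raises(DomainError):
            combine_pafs([-0.1])

    @given(st.lists(st.floats(0.0, 0.99), min_size=1, max_size=6),
           st.randoms(use_true_random=False))
    @settings(max_examples=200, derandomize=True)
    def test_permutation_invariance_and_bounds(self, pafs, rnd):
        combined = combine_pafs(pafs).value
        shuffled = list(pafs)
        rnd.shuffle(shuffled)
        assert combine_pafs(shuffled).value == pytest.approx(combined,
                                                             abs=1e-12)
        assert combined >= max(pafs) - 1e-12
        assert combined <= min(1.0, sum(pafs)) + 1e-12


class TestPafForCell:
    def test_direct_paf_passes_through_unchanged(self):
        uv = RiskFactorSpec("uv", "UV radiation", "direct_paf",
                            frozenset({"melanoma"}))
        got = paf_for_cell(uv, direct=0.932, cancer_type_id="melanoma")
        assert got == PafValue(0.932, "direct")

    def test_null_rr_gives_zero(self, smoking_spec):
        dist = ExposureDistribution.from_nonreference(
            "smoking", "male", [("current", 0.25)])
        rrs = [RelativeRiskEntry("smoking", "lung", "male", "current", 1.0)]
        got = paf_for_cell(smoking_spec, dist=dist, rrs=rrs,
                           cancer_type_id="lung")
        assert got.value == 0.0

    @pytest.mark.parametrize("p", [0.1, 0.3, 0.5, 0.7, 0.9])
    @pytest.mark.parametrize("rr", [1.1, 1.5, 2.0, 3.5, 5.0])
    def test_single_level_closed_form_on_grid(self, smoking_spec, p, rr):
        dist = ExposureDistribution.from_nonreference(
            "smoking", "male", [("current", p)])
        rrs = [RelativeRiskEntry("smoking", "lung", "male", "current", rr)]
        got = paf_for_cell(smoking_spec, dist=dist, rrs=rrs,
                           cancer_type_id="lung")
        assert got.value == pytest.approx(
            p * (rr - 1) / (1 + p * (rr - 1)), abs=1e-12)
        assert got.value == pytest.approx(
            exact_paf_enumeration([(p, rr), (1 - p, 1.0)]), abs=1e-12)

    def test_missing_rr_level_is_a_data_gap(self, smoking_spec, smoking_dist):
        rrs = [RelativeRiskEntry("smoking", "lung", "male", "current", 8.0)]
        with pytest.raises(DataGapError, match="former"):
            paf_for_cell(smoking_spec, dist=smoking_dist, rrs=rrs,
                         cancer_type_id="lung")

    def test_nonsignificant_level_contributes_nothing(self, smoking_spec,
                                                      smoking_dist):
        rrs = [
            RelativeRiskEntry("smoking", "lung", "male", "current", 8.0),
            RelativeRiskEntry("smoking", "lung", "male", "former", 2.0,
                              significant=False),
        ]
        got = paf_for_cell(smoking_spec, dist=smoking_dist, rrs=rrs,
                           cancer_type_id="lung")
        only_current = 0.25 * 7.0 / (1 + 0.25 * 7.0)
        assert got.value == pytest.approx(only_current, abs=1e-12)

    def test_err_vector_alignment(self, smoking_spec, smoking_dist,
                                  smoking_rrs):
        ev = build_err_vector(smoking_spec, smoking_dist, smoking_rrs, "lung")
        assert [e[0] for e in ev.entries] == ["current", "former", "reference"]
        assert ev.entries[-1][2] == 0.0
        assert ev.nonreference == (("current", 0.25, 7.0), ("former", 0.25, 1.0))
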