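"""Preventive fraction and attributable fraction algebra.

The closed-form cross-check for the attributable fraction is
pr(1-rr)/(rr + pr(1-rr)), derived by substituting RR_I = 1/rr into
Pr(RR_I-1)/[1+Pr(RR_I-1)] and clearing the fraction — an independent route
to the same quantity.
"""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dairyburden.risk_fractions import (
    PrevalenceScenario,
    default_grid,
    interval_fractions,
    invert_rr,
    parp,
    preventive_fraction,
    sweep_fractions,
)

prs = st.floats(min_value=0.001, max_value=1.0, allow_nan=False)
protective_rrs = st.floats(min_value=0.01, max_value=0.999, allow_nan=False)


def closed_form_paf(pr, rr):
    return pr * (1 - rr) / (rr + pr * (1 - rr))


class TestPointFormulas:
    @pytest.mark.parametrize(
        "pr, rr, expected",
        [(0.15, 0.85, 0.0225), (0.50, 0.68, 0.16), (0.35, 1.0, 0.0)],
    )
    def test_preventive_fraction_values(self, pr, rr, expected):
        assert preventive_fraction(pr, rr) == pytest.approx(expected, abs=1e-15)

    @pytest.mark.parametrize("rr, expected", [(1.0, 1.0), (0.5, 2.0), (0.85, 1 / 0.85)])
    def test_rr_inversion(self, rr, expected):
        assert invert_rr(rr) == pytest.approx(expected, rel=1e-15)

    @pytest.mark.parametrize(
        "pr, rr_i, expected",
        [
            (0.15, 1 / 0.85, 0.15 * (1 / 0.85 - 1) / (1 + 0.15 * (1 / 0.85 - 1))),
            (0.50, 1 / 0.68, 0.50 * (1 / 0.68 - 1) / (1 + 0.50 * (1 / 0.68 - 1))),
            (0.25, 1.0, 0.0),
        ],
    )
    def test_attributable_fraction_values(self, pr, rr_i, expected):
        assert parp(pr, rr_i) == pytest.approx(expected, rel=1e-15)

    def test_breast_cancer_and_high_fat_colorectal_magnitudes(self):
        # the two canonical spot values, to published display precision
        assert round(parp(0.15, invert_rr(0.85)) * 100, 2) == 2.58
        assert round(parp(0.50, invert_rr(0.68)) * 100, 2) == 19.05

    @pytest.mark.parametrize(
        "fn, args",
        [
            (preventive_fraction, (0.15, 1.2)),  # harmful rr
            (preventive_fraction, (0.0, 0.9)),
            (preventive_fraction, (1.5, 0.9)),
            (invert_rr, (0.0,)),
            (invert_rr, (-1.0,)),
            (parp, (0.15, 0.9)),  # rr_inverse < 1
            (parp, (0.0, 1.2)),
        ],
    )
    def test_domain_errors(self, fn, args):
        with pytest.raises(ValueError):
            fn(*args)


class TestAlgebraicProperties:
    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(pr=prs, rr=protective_rrs)
    def test_closed_form_equivalence(self, pr, rr):
        via_inversion = parp(pr, invert_rr(rr))
        direct = closed_form_paf(pr, rr)
        assert math.isclose(via_inversion, direct, rel_tol=1e-12)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(pr=st.floats(min_value=0.001, max_value=0.999), rr=protective_rrs)
    def test_attributable_dominates_preventive(self, pr, rr):
        assert parp(pr, invert_rr(rr)) > preventive_fraction(pr, rr)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(pr=prs, rr=protective_rrs, delta=st.floats(min_value=1e-6, max_value=0.5))
    def test_both_fractions_increase_as_rr_falls(self, pr, rr, delta):
        lower_rr = max(rr - delta, 1e-6)
        if lower_rr >= rr:
            return
        assert preventive_fraction(pr, lower_rr) > preventive_fraction(pr, rr)
        assert parp(pr, invert_rr(lower_rr)) > parp(pr, invert_rr(rr))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(pr=st.floats(min_value=0.001, max_value=0.5), rr=protective_rrs,
           factor=st.floats(min_value=1.01, max_value=2.0))
    def test_both_fractions_increase_with_prevalence(self, pr, rr, factor):
        higher = min(pr * factor, 1.0)
        if higher <= pr:
            return
        assert preventive_fraction(higher, rr) > preventive_fraction(pr, rr)
        assert parp(higher, invert_rr(rr)) > parp(pr, invert_rr(rr))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(pr=prs)
    def test_null_effect_gives_zero(self, pr):
        assert preventive_fraction(pr, 1.0) == 0.0
        assert parp(pr, 1.0) == 0.0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(rr=protective_rrs)
    def test_preventive_fraction_linear_in_prevalence(self, rr):
        assert math.isclose(
            preventive_fraction(0.50, rr),
            (10 / 3) * preventive_fraction(0.15, rr),
            rel_tol=1e-12,
        )


class TestSweep:
    def test_default_grid_values(self):
        assert tuple(s.pr for s in default_grid()) == (0.15, 0.25, 0.35, 0.50)

    def test_breast_cancer_row(self, estimate_by_cell):
        e = estimate_by_cell[("breast_cancer", "total_dairy")]
        cells = sweep_fractions(e, default_grid())
        pf = [round(c.preventive_fraction * 100, 2) for c in cells]
        pa = [round(c.parp * 100, 2) for c in cells]
        assert pf == [2.25, 3.75, 5.25, 7.50]
        assert pa == [2.58, 4.23, 5.82, 8.11]

    def test_t2d_single_scenario(self, estimate_by_cell):
        e = estimate_by_cell[("t2d", "total_dairy")]
        (cell,) = sweep_fractions(e, [PrevalenceScenario(0.15)])
        assert round(cell.preventive_fraction * 100, 2) == 1.35
        assert round(cell.parp * 100, 2) == 1.46

    def test_empty_grid_rejected(self, estimate_by_cell):
        with pytest.raises(ValueError):
            sweep_fractions(estimate_by_cell[("cvd", "total_dairy")], [])


class TestIntervalBounds:
    def test_breast_cancer_ci_substitution(self, estimate_by_cell):
        e = estimate_by_cell[("breast_cancer", "total_dairy")]
        pair = interval_fractions(e, PrevalenceScenario(0.15))
        assert pair.conservative.preventive_fraction == pytest.approx(0.0075, abs=1e-12)
        assert pair.optimistic.preventive_fraction == pytest.approx(0.0360, abs=1e-12)
        assert not pair.clamped

    def test_degenerate_ci_collapses_to_point(self):
        from dairyburden.evidence_registry import EffectEstimate

        e = EffectEstimate(
            outcome_id="cvd", exposure_category="milk", comparison="high vs. low",
            srre=0.9, ci_lower=0.9, ci_upper=0.9, n_studies=3,
            first_author="X", pub_year=2020,
        )
        pair = interval_fractions(e, PrevalenceScenario(0.25))
        assert pair.conservative == pair.optimistic
        assert pair.conservative.preventive_fraction == pair.point.preventive_fraction

    def test_ci_reaching_null_clamps_conservative_bound_to_zero(self):
        from dairyburden.evidence_registry import EffectEstimate

        e = EffectEstimate(
            outcome_id="cvd", exposure_category="milk", comparison="high vs. low",
            srre=0.95, ci_lower=0.90, ci_upper=1.0, n_studies=3,
            first_author="X", pub_year=2020,
        )
        pair = interval_fractions(e, PrevalenceScenario(0.35))
        assert pair.clamped
        assert pair.conservative.preventive_fraction == 0.0
        assert pair.conservative.parp == 0.0
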