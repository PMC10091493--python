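"""Fixation probability U(p) and substitution rates from the diffusion."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import slowerx as sx
from slowerx.diffusion import (
    KIMURA_SIGMA_THRESHOLD,
    fixation_probability,
    kimura_rate,
)
from slowerx.model import DriftCoefficients, LocusClass


def coeffs_from_scaled(ne_sbar: float, ne_sigma: float, ne: float = 1e6, p0: float = 1e-6):
    return DriftCoefficients(s_bar=ne_sbar / ne, sigma=ne_sigma / ne, Ne=ne, p0=p0)


# ---------------------------------------------------------------------------
# sojourn weight G


def test_G_at_zero_and_neutral_is_one():
    coeffs = coeffs_from_scaled(1.5, 0.3)
    assert sx.G(0.0, coeffs) == 1.0
    neutral = coeffs_from_scaled(0.0, 0.0)
    y = np.linspace(0, 1, 7)
    assert np.allclose(sx.G(y, neutral), 1.0)


def test_G_closed_value():
    # Ne = 1000, s_bar = 1e-3, sigma = 0, y = 1 -> exp(-4)
    coeffs = DriftCoefficients(s_bar=1e-3, sigma=0.0, Ne=1000.0, p0=1e-3)
    assert sx.G(1.0, coeffs) == pytest.approx(0.01831563888873418, rel=1e-12)


def test_G_rejects_out_of_range_frequency():
    coeffs = coeffs_from_scaled(1.0, 0.0)
    with pytest.raises(sx.ParameterError):
        sx.G(1.5, coeffs)
    with pytest.raises(sx.ParameterError):
        sx.G(-0.1, coeffs)


# ---------------------------------------------------------------------------
# U(p)


@pytest.mark.parametrize("method", ["closed_form", "quadrature"])
def test_neutral_fixation_probability_equals_initial_frequency(method):
    coeffs = coeffs_from_scaled(0.0, 0.0, p0=0.01)
    res = fixation_probability(0.01, coeffs, method=method)
    assert res.u == pytest.approx(0.01, rel=1e-12)
    assert res.relative_rate == pytest.approx(1.0, rel=1e-12)


def test_additive_limit_matches_kimura_value():
    # Ne*s_bar = 1, sigma = 0: rate -> 4/(1 - e^-4) as p0 -> 0
    coeffs = coeffs_from_scaled(1.0, 0.0, p0=1e-9)
    res = fixation_probability(1e-9, coeffs)
    assert res.method == "kimura_limit"
    assert res.relative_rate == pytest.approx(4.074629441455096, rel=1e-6)
    assert kimura_rate(4.0) == pytest.approx(4.074629441455096, rel=1e-14)


def test_strongly_deleterious_fixation_is_tiny_but_finite():
    coeffs = DriftCoefficients(s_bar=-1e-4, sigma=0.0, Ne=1e6, p0=1e-6)
    res = fixation_probability(1e-6, coeffs)
    assert 0.0 < res.u < 1e-15
    assert math.isfinite(res.u)


def test_u_is_increasing_in_initial_frequency():
    coeffs = coeffs_from_scaled(2.0, -0.7)
    p_grid = np.linspace(1e-4, 1 - 1e-4, 40)
    u = [fixation_probability(p, coeffs).u for p in p_grid]
    assert np.all(np.diff(u) > 0)
    assert u[0] < 1e-2 and u[-1] > 1 - 1e-2


def test_u_boundary_limits():
    coeffs = coeffs_from_scaled(1.0, 0.4)
    assert fixation_probability(1e-12, coeffs).u < 1e-10
    assert fixation_probability(1 - 1e-12, coeffs).u > 1 - 1e-10


@given(
    ne_sbar=st.floats(min_value=-3.0, max_value=5.0),
    ne_sigma=st.floats(min_value=-2.0, max_value=2.0),
    p0=st.floats(min_value=1e-7, max_value=0.5),
)
def test_evaluation_paths_agree_and_stay_in_unit_interval(ne_sbar, ne_sigma, p0):
    coeffs = coeffs_from_scaled(ne_sbar, ne_sigma, p0=p0)
    closed = fixation_probability(p0, coeffs, method="closed_form")
    quad = fixation_probability(p0, coeffs, method="quadrature")
    assert 0.0 <= closed.u <= 1.0
    assert closed.u == pytest.approx(quad.u, rel=1e-8, abs=1e-300)


def test_continuity_across_sigma_switch():
    """The Kimura branch joins the general closed form at the threshold."""
    ne = 1e6
    for ne_sbar in (-2.0, 0.7, 3.0):
        eps = KIMURA_SIGMA_THRESHOLD / 4.0
        below = coeffs_from_scaled(ne_sbar, (KIMURA_SIGMA_THRESHOLD - eps) / 4.0, ne)
        above = coeffs_from_scaled(ne_sbar, (KIMURA_SIGMA_THRESHOLD + eps) / 4.0, ne)
        u_below = fixation_probability(1e-6, below)
        u_above = fixation_probability(1e-6, above)
        assert u_below.method == "kimura_limit" and u_above.method == "closed_form"
        assert u_below.u == pytest.approx(u_above.u, rel=1e-7)


def test_rate_nondecreasing_in_mean_selection():
    for ne_sigma in (-1.0, 0.0, 1.0):
        rates = [
            fixation_probability(1e-6, coeffs_from_scaled(s, ne_sigma)).relative_rate
            for s in np.linspace(-3, 5, 17)
        ]
        assert np.all(np.diff(rates) > 0)


# ---------------------------------------------------------------------------
# relative substitution rates


def test_neutral_rate_is_one_for_every_class(big_pop):
    reg = sx.SelectionRegime(0.0, 0.0, 0.3)
    for lc in LocusClass:
        for method in ("closed_form", "quadrature"):
            assert sx.relative_substitution_rate(
                reg, lc, big_pop, method=method
            ) == pytest.approx(1.0, rel=1e-12)


def test_autosomal_additive_rate_is_kimura(big_pop):
    # s_f = s_m = 3e-6, h = 1/2: Ne_A * s_bar = 1.5 -> 6/(1 - e^-6)
    reg = sx.SelectionRegime(3e-6, 3e-6, 0.5)
    rate = sx.relative_substitution_rate(reg, "autosomal", big_pop, first_order=True)
    assert rate == pytest.approx(6.014909469941068, rel=1e-12)


def test_exact_rate_approaches_first_order_rate():
    reg = sx.SelectionRegime(3e-6, 3e-6, 0.2)
    for n in (10**5, 10**6, 10**7):
        pop = sx.PopulationModel(N=n, Ne_A=1e6)
        exact = sx.relative_substitution_rate(reg, "diploid_X", pop)
        limit = sx.relative_substitution_rate(reg, "diploid_X", pop, first_order=True)
        assert exact == pytest.approx(limit, rel=10.0 / n)


def test_slower_x_for_beneficial_equal_effects(big_pop):
    # Ne_A*s = 3, h = 0.2: diploid X substitutes more slowly than an autosome
    reg = sx.SelectionRegime(3e-6, 3e-6, 0.2)
    rate_x = sx.relative_substitution_rate(reg, "diploid_X", big_pop)
    rate_a = sx.relative_substitution_rate(reg, "autosomal", big_pop)
    assert rate_x < rate_a


def test_rejects_bad_method_and_p0(big_pop):
    reg = sx.SelectionRegime(1e-6, 1e-6, 0.5)
    with pytest.raises(sx.ParameterError):
        sx.relative_substitution_rate(reg, "autosomal", big_pop, method="magic")
    coeffs = coeffs_from_scaled(1.0, 0.0)
    with pytest.raises(sx.ParameterError):
        fixation_probability(0.0, coeffs)
    with pytest.raises(sx.ParameterError):
        fixation_probability(1.0, coeffs)
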