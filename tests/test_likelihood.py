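"""Core model functions: category probabilities, log-likelihoods, analytic
derivatives against finite differences, and the closed-form profile root."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar

from bilat_or.likelihood import (
    Group,
    category_probs,
    constrained_stratum_loglik,
    d2l_dpi2,
    dl_dpi,
    dl_drho,
    group_information,
    group_loglik,
    pi2_from,
    pi_closed_form,
    rho_information,
    stratum_groups,
    stratum_information,
    stratum_loglik,
)
from conftest import random_group

counts_st = st.integers(min_value=0, max_value=25)
groups_st = st.tuples(counts_st, counts_st, counts_st, counts_st, counts_st).map(
    lambda t: Group(*t)
).filter(lambda g: g.n_tot + g.m_tot > 0)
interior = st.floats(min_value=0.05, max_value=0.95)


@pytest.mark.parametrize(
    "pi, rho, expected",
    [
        (0.5, 0.0, (0.25, 0.50, 0.25)),   # independence: Binomial(2, 1/2)
        (0.3, 1.0, (0.7, 0.0, 0.3)),       # perfect correlation: one Bernoulli
        (0.0, 0.6, (1.0, 0.0, 0.0)),       # zero event rate
        (1.0, 0.2, (0.0, 0.0, 1.0)),
    ],
)
def test_category_probs_examples(pi, rho, expected):
    assert category_probs(pi, rho) == pytest.approx(expected, abs=1e-15)


def test_category_probs_simplex_grid():
    pi, rho = np.meshgrid(np.linspace(0, 1, 21), np.linspace(0, 1, 21))
    p0, p1, p2 = category_probs(pi, rho)
    assert np.all(p0 >= 0) and np.all(p1 >= 0) and np.all(p2 >= 0)
    assert np.allclose(p0 + p1 + p2, 1.0, atol=1e-12)


def test_category_probs_rejects_out_of_range():
    with pytest.raises(ValueError):
        category_probs(-0.1, 0.5)
    with pytest.raises(ValueError):
        category_probs(0.5, 1.2)


def test_stratum_loglik_empty_counts_is_zero():
    z = Group(0, 0, 0, 0, 0)
    assert stratum_loglik((z, z), 0.3, 0.7, 0.4) == 0.0


@given(g1=groups_st, g2=groups_st, pi1=interior, pi2=interior, rho=interior)
@settings(max_examples=150, deadline=None)
def test_stratum_loglik_is_termwise_sum(g1, g2, pi1, pi2, rho):
    """l_j equals the brute-force sum of count-weighted log probabilities."""
    expected = 0.0
    for g, pi in ((g1, pi1), (g2, pi2)):
        p = category_probs(pi, rho)
        expected += (
            g.n0 * math.log(1 - pi) + g.n1 * math.log(pi)
            + sum(c * math.log(pc) for c, pc in zip((g.m0, g.m1, g.m2), p) if c)
        )
    assert stratum_loglik((g1, g2), pi1, pi2, rho) == pytest.approx(
        expected, rel=1e-12
    )


@given(g1=groups_st, g2=groups_st, pi1=interior, rho=interior,
       theta=st.floats(min_value=0.1, max_value=8.0))
@settings(max_examples=150, deadline=None)
def test_constrained_loglik_substitution_identity(g1, g2, pi1, rho, theta):
    direct = stratum_loglik((g1, g2), pi1, pi2_from(pi1, theta), rho)
    assert constrained_stratum_loglik((g1, g2), pi1, rho, theta) == direct


def test_constrained_loglik_null_or_reduces_to_equal_probs(rng):
    g1, g2 = random_group(rng), random_group(rng)
    assert constrained_stratum_loglik((g1, g2), 0.4, 0.3, 1.0) == pytest.approx(
        stratum_loglik((g1, g2), 0.4, 0.4, 0.3)
    )


@given(g=groups_st, pi=interior, rho=interior)
@settings(max_examples=200, deadline=None)
def test_dl_dpi_matches_finite_differences(g, pi, rho):
    h = 1e-6
    fd = (group_loglik(g, pi + h, rho) - group_loglik(g, pi - h, rho)) / (2 * h)
    an = dl_dpi(g, pi, rho)
    assert an == pytest.approx(fd, rel=1e-5, abs=1e-5)


@given(g=groups_st, pi=interior, rho=interior)
@settings(max_examples=200, deadline=None)
def test_d2l_dpi2_matches_finite_differences(g, pi, rho):
    h = 1e-6
    fd = (dl_dpi(g, pi + h, rho) - dl_dpi(g, pi - h, rho)) / (2 * h)
    assert d2l_dpi2(g, pi, rho) == pytest.approx(fd, rel=1e-4, abs=1e-4)


@given(g1=groups_st, g2=groups_st, pi1=interior, pi2=interior, rho=interior)
@settings(max_examples=200, deadline=None)
def test_dl_drho_matches_finite_differences(g1, g2, pi1, pi2, rho):
    h = 1e-7
    fd = (
        stratum_loglik((g1, g2), pi1, pi2, rho + h)
        - stratum_loglik((g1, g2), pi1, pi2, rho - h)
    ) / (2 * h)
    assert dl_drho((g1, g2), pi1, pi2, rho) == pytest.approx(
        fd, rel=1e-4, abs=1e-4
    )


def test_dl_drho_zero_without_bilateral_data():
    g = Group(4, 7, 0, 0, 0)
    assert dl_drho((g, g), 0.3, 0.6, 0.2) == 0.0


def test_dl_dpi_zero_at_closed_form_root(rng):
    for _ in range(50):
        g = random_group(rng)
        rho = float(rng.uniform(0.05, 0.9))
        root = pi_closed_form(g, rho)
        if 1e-8 < root < 1 - 1e-8:
            assert abs(dl_dpi(g, root, rho)) < 1e-8 * max(
                1.0, abs(d2l_dpi2(g, root, rho))
            )


@pytest.mark.parametrize("rho", [0.0, 0.2, 0.8])
def test_pi_closed_form_unilateral_reduces_to_binomial(rho):
    g = Group(6, 9, 0, 0, 0)
    assert pi_closed_form(g, rho) == pytest.approx(9 / 15, abs=1e-12)


def test_pi_closed_form_symmetric_bilateral():
    assert pi_closed_form(Group(0, 0, 5, 10, 5), 0.0) == pytest.approx(0.5)


def test_pi_closed_form_errors():
    with pytest.raises(ValueError, match="no observations"):
        pi_closed_form(Group(0, 0, 0, 0, 0), 0.3)
    with pytest.raises(ValueError, match="rho"):
        pi_closed_form(Group(1, 1, 1, 1, 1), 1.0)


def test_pi_closed_form_matches_brute_force_maximiser(rng):
    """Closed-form root vs bounded 1-D numerical maximisation, 1000 cases."""
    worst = 0.0
    for _ in range(1000):
        g = random_group(rng, max_count=15)
        rho = float(rng.uniform(0.0, 0.97))
        root = pi_closed_form(g, rho)
        res = minimize_scalar(
            lambda x: -group_loglik(g, x, rho),
            bounds=(1e-9, 1 - 1e-9), method="bounded",
            options={"xatol": 1e-12},
        )
        # compare in likelihood value (flat optima can differ in argument)
        gap = group_loglik(g, root, rho) - (-res.fun)
        assert gap > -1e-7, (g, rho, root, res.x)
        if 1e-6 < res.x < 1 - 1e-6:
            worst = max(worst, abs(root - res.x))
    assert worst < 1e-6


def test_rho_information_degenerate_and_linear():
    g_uni = Group(3, 4, 0, 0, 0)
    assert rho_information((g_uni, g_uni), 0.3, 0.4, 0.5) == 0.0
    g = Group(2, 3, 10, 20, 10)
    g2 = Group(1, 1, 20, 40, 20)  # doubled bilateral sizes
    one = rho_information((g, g), 0.3, 0.4, 0.5)
    two = rho_information(
        (g._replace(m0=20, m1=40, m2=20), g._replace(m0=20, m1=40, m2=20)),
        0.3, 0.4, 0.5,
    )
    assert two == pytest.approx(2 * one, rel=1e-12)
    assert one > 0
    assert g2.m_tot == 2 * g.m_tot


def _expected_neg_hessian_rho(pi, rho, m, h=1e-5):
    """Oracle: average -d2 log p_t / drho2 over exact category probabilities."""
    p = category_probs(pi, rho)
    tot = 0.0
    for t, pt in enumerate(p):
        lp = lambda r: math.log(category_probs(pi, r)[t])  # noqa: E731
        tot += m * pt * (-(lp(rho + h) - 2 * lp(rho) + lp(rho - h)) / h**2)
    return tot


def test_rho_information_matches_expectation_oracle():
    pi1, pi2, rho, m = 0.3, 0.4, 0.5, 50
    oracle = _expected_neg_hessian_rho(pi1, rho, m) + _expected_neg_hessian_rho(
        pi2, rho, m
    )
    g1 = Group(0, 0, 17, 17, 16)
    g2 = Group(0, 0, 16, 17, 17)
    got = rho_information((g1, g2), pi1, pi2, rho)
    assert got == pytest.approx(oracle, rel=1e-5)


def test_group_information_matches_numeric_expectation(rng):
    """The analytic 2x2 expected information equals the numerically averaged
    negative Hessian of one subject's log-likelihood, scaled by group size."""
    pi, rho, m, n = 0.35, 0.45, 40, 25
    g = Group(n // 2, n - n // 2, m // 3, m // 3, m - 2 * (m // 3))
    got = group_information(g, pi, rho)
    h = 1e-5
    p = category_probs(pi, rho)
    I = np.zeros((2, 2))
    # multinomial part
    for t, pt in enumerate(p):
        def lp(x, r, t=t):
            return math.log(category_probs(x, r)[t])
        dxx = (lp(pi + h, rho) - 2 * lp(pi, rho) + lp(pi - h, rho)) / h**2
        drr = (lp(pi, rho + h) - 2 * lp(pi, rho) + lp(pi, rho - h)) / h**2
        dxr = (
            lp(pi + h, rho + h) - lp(pi + h, rho - h)
            - lp(pi - h, rho + h) + lp(pi - h, rho - h)
        ) / (4 * h * h)
        I += -m * pt * np.array([[dxx, dxr], [dxr, drr]])
    I[0, 0] += n / (pi * (1 - pi))
    assert got == pytest.approx(I, rel=1e-4)


def test_stratum_information_block_structure(aom):
    groups = stratum_groups(aom)[0]
    I = stratum_information(groups, 0.5, 0.45, 0.7)
    assert I[0, 1] == 0 == I[1, 0]  # groups are independent given rho
    assert np.allclose(I, I.T)
    assert np.all(np.linalg.eigvalsh(I) > 0)
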