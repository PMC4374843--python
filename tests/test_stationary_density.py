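"""Stationary density: closed form, quadrature oracle, transforms."""

import math

import numpy as np
import pytest
from scipy.stats import gamma as gamma_dist

from decoyburst import (
    GeneCircuitParams,
    Variable,
    degradation_rate,
    density_free,
    density_log10,
    normalize,
    origin_exponent,
    q_exponents,
    stationary_ode_residual,
    unnormalized_density_closed,
    unnormalized_density_quadrature,
)
from .conftest import random_params


class TestQExponents:
    def test_q1_equals_a0_for_equal_decay(self, fig1_y100):
        # gamma_b = 1 makes (kb+y)/(kb+gamma_b*y) = 1
        assert q_exponents(fig1_y100).q1 == pytest.approx(0.75, abs=0)

    def test_fig1_values(self, fig1_y100):
        q = q_exponents(fig1_y100)
        assert q.valid
        assert q.q3 == pytest.approx(25.0 / 499.0 - 0.75, rel=1e-12)
        assert q.q4 == pytest.approx(101.0 * (0.75 / 101.0 + 25.0 / (1 - 500 + 100)),
                                     rel=1e-12)
        assert q.q3 == pytest.approx(-0.700, abs=5e-4)
        assert q.q4 == pytest.approx(-5.58, abs=5e-3)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"kp": 1.0, "kb": 1.0},                     # kp == kb
            {"kp": 101.0, "kb": 1.0, "y": 100.0},       # kp == kb + gb*y
            {"y": 0.0},                                 # gb*y == 0
            {"gamma_b": 0.0},                           # gb*y == 0
        ],
    )
    def test_degenerate_cases_flagged(self, kwargs):
        base = dict(a0=0.75, a1=25.0, kp=500.0, b=50.0, y=100.0, kb=1.0,
                    gamma_b=1.0)
        base.update(kwargs)
        q = q_exponents(GeneCircuitParams(**base))
        assert not q.valid
        with pytest.raises(ValueError):
            unnormalized_density_closed(10.0, GeneCircuitParams(**base))


class TestClosedVsQuadrature:
    def test_fig1_ratio_constant(self, fig1_y100):
        xs = np.geomspace(0.1, 5000.0, 20)
        r = np.array(
            [
                unnormalized_density_closed(x, fig1_y100)
                / unnormalized_density_quadrature(x, fig1_y100)
                for x in xs
            ]
        )
        assert (r.max() - r.min()) / r.mean() < 1e-6

    def test_randomized_ratio_constant(self):
        """Closed form and the integral form agree up to one global
        constant over randomized valid parameter sets."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            p = random_params(rng, require_valid_closed_form=True)
            xs = np.geomspace(0.5, 50.0 * p.b, 8)
            r = np.array(
                [
                    unnormalized_density_closed(x, p)
                    / unnormalized_density_quadrature(x, p)
                    for x in xs
                ]
            )
            assert (r.max() - r.min()) / r.mean() < 1e-6

    def test_y_zero_limit_reduces_to_no_decoy_law(self):
        # as y -> 0 the density approaches x^(a0-1) (kp+x)^a1-ish form;
        # compare the quadrature density against the explicit y=0 reduction
        p = GeneCircuitParams(a0=0.75, a1=25.0, kp=500.0, b=50.0, y=1e-8,
                              kb=1.0, gamma_b=1.0)
        xs = np.geomspace(1.0, 2000.0, 10)
        ref = xs ** (p.a0 - 1) * (p.kp + xs) ** p.a1 * np.exp(-xs / p.b)
        vals = np.array([unnormalized_density_quadrature(x, p) for x in xs])
        r = vals / ref
        assert (r.max() - r.min()) / r.mean() < 1e-5

    def test_protected_decay_finite_positive(self):
        p = GeneCircuitParams(a0=0.75, a1=25.0, kp=500.0, b=50.0, y=100.0,
                              kb=1.0, gamma_b=0.0)
        for x in (0.5, 50.0, 500.0, 5000.0):
            v = unnormalized_density_quadrature(x, p)
            assert math.isfinite(v) and v > 0


class TestNormalize:
    def test_gamma_law(self, gamma_case):
        """No feedback, no decoys: the stationary law is Gamma(a0, b)."""
        g = normalize(gamma_case)
        ref = gamma_dist.pdf(g.abscissae, gamma_case.a0, scale=gamma_case.b)
        mask = ref > ref.max() * 1e-8
        assert np.abs(g.values[mask] / ref[mask] - 1).max() < 1e-6

    def test_mass_one(self, fig1_y100):
        g = normalize(fig1_y100)
        assert g.normalized
        assert g.integral() == pytest.approx(1.0, abs=1e-6)

    def test_singular_density_still_normalizes(self):
        p = GeneCircuitParams(a0=0.5, a1=0.0, kp=500.0, b=50.0, y=0.0)
        g = normalize(p)
        assert g.integral() == pytest.approx(1.0, abs=1e-6)
        # singular at the origin: density grows without bound as x -> 0
        assert g.values[0] > g.values[100] > g.values[200]

    def test_a0_zero_rejected(self):
        p = GeneCircuitParams(a0=0.0, a1=25.0, kp=500.0, b=50.0)
        with pytest.raises(ValueError):
            normalize(p)


class TestOriginBehavior:
    def test_threshold_at_a0_one_for_equal_decay(self):
        for a0, sign in [(0.5, -1), (1.0, 0), (1.5, 1)]:
            p = GeneCircuitParams(a0=a0, a1=25.0, kp=500.0, b=50.0, y=100.0,
                                  kb=1.0, gamma_b=1.0)
            e = origin_exponent(p)
            assert np.sign(e) == sign

    def test_generalized_threshold(self):
        # divergence iff a0*(kb+y)/(kb+gb*y) < 1
        p = GeneCircuitParams(a0=0.4, a1=5.0, kp=300.0, b=20.0, y=100.0,
                              kb=1.0, gamma_b=0.5)
        expect = 0.4 * 101.0 / 51.0 - 1.0
        assert origin_exponent(p) == pytest.approx(expect, rel=1e-12)


class TestTransforms:
    def test_free_density_jacobian_at_half_occupancy(self, fig1_y100):
        """p_free(xf=1) = p(x=51) * (1 + y*kb/(xf+kb)^2) = 26 * p(51)."""
        g = normalize(fig1_y100)
        gf = density_free(g, fig1_y100)
        p51 = np.interp(51.0, g.abscissae, g.values)
        pf1 = np.interp(1.0, gf.abscissae, gf.values)
        assert pf1 == pytest.approx(26.0 * p51, rel=1e-4)

    def test_free_equals_total_without_decoys(self, fig1_y0):
        g = normalize(fig1_y0)
        gf = density_free(g, fig1_y0)
        np.testing.assert_allclose(gf.values, g.values, rtol=1e-12)

    def test_mass_conserved(self, fig1_y100):
        g = normalize(fig1_y100)
        assert density_free(g, fig1_y100).integral() == pytest.approx(1.0, abs=1e-6)
        assert density_log10(g, fig1_y100).integral() == pytest.approx(1.0, abs=1e-6)

    def test_log_density_vanishes_at_minus_infinity(self):
        # p(x) diverges at 0 for a0 = 0.5 but x*p(x) -> 0, so the log-scale
        # density decays toward z -> -inf
        p = GeneCircuitParams(a0=0.5, a1=0.0, kp=500.0, b=50.0, y=0.0)
        gl = density_log10(normalize(p), p)
        assert gl.values[0] < gl.values[len(gl.values) // 2]
        assert gl.values[0] < 1e-2 * gl.values.max()

    def test_wrong_variable_rejected(self, fig1_y100):
        g = normalize(fig1_y100)
        gl = density_log10(g, fig1_y100)
        with pytest.raises(ValueError):
            density_log10(gl, fig1_y100)
        with pytest.raises(ValueError):
            density_free(gl, fig1_y100)


class TestStationaryBalance:
    @pytest.mark.parametrize("case", ["fig1", "gamma"])
    def test_residual_small(self, case, fig1_y100, gamma_case):
        params = fig1_y100 if case == "fig1" else gamma_case
        g = normalize(params)
        r = stationary_ode_residual(g, params)
        flux = np.array([degradation_rate(x, params) for x in g.abscissae])
        scale = (flux * g.values / params.b).max()
        interior = slice(5, -5)
        assert np.abs(r[interior]).max() / scale < 1e-4

    def test_residual_scales_linearly(self, fig1_y100):
        # the balance is linear in p: doubling the density doubles r
        g = normalize(fig1_y100)
        r1 = stationary_ode_residual(g, fig1_y100)
        g2 = type(g)(g.variable, g.abscissae, 2.0 * g.values, normalized=False,
                     kappa=g.kappa, origin_exp=g.origin_exp)
        r2 = stationary_ode_residual(g2, fig1_y100)
        np.testing.assert_allclose(r2, 2.0 * r1, rtol=1e-10, atol=1e-300)
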