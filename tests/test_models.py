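"""Closed-form model identities: 4PL, AND gate, EC quantiles, DRLR."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from gatefit import (
    ANDGateParams,
    FourPLParams,
    ParameterError,
    drlr_analytic,
    ec_quantile,
    eval_and_gate,
    eval_four_pl,
)


class TestFourPL:
    def test_midpoint_and_zero(self, fourpl_ref):
        assert eval_four_pl(fourpl_ref.ec50, fourpl_ref) == pytest.approx(
            (fourpl_ref.y0 + fourpl_ref.ymax) / 2
        )
        assert eval_four_pl(0.0, fourpl_ref) == fourpl_ref.y0

    def test_hand_evaluated_point(self):
        # y0 + 10000 * (450/500) at n=1: occupancy 450/(50+450) = 0.9
        p = FourPLParams(y0=100, ymax=10100, ec50=50, n=1)
        assert eval_four_pl(450.0, p) == pytest.approx(9100.0, rel=1e-12)

    def test_strictly_increasing(self, fourpl_ref):
        x = np.geomspace(1e-3, 1e5, 200)
        y = eval_four_pl(x, fourpl_ref)
        assert np.all(np.diff(y) > 0)

    @pytest.mark.parametrize(
        "kw", [dict(n=-1.0), dict(n=0.0), dict(ec50=0.0), dict(ec50=-5.0), dict(y0=-1.0)]
    )
    def test_invalid_params_rejected(self, kw):
        base = dict(y0=0.0, ymax=1.0, ec50=1.0, n=1.0)
        with pytest.raises(ParameterError):
            FourPLParams(**{**base, **kw})


class TestANDGate:
    def test_p_independent_when_f1_is_one(self):
        p = ANDGateParams(y0=5.0, dy=100.0, n=1.3, k1=10.0, k2=50.0, f1=1.0)
        i = np.array([0.0, 1.0, 10.0, 1e4])[:, None]
        pp = np.array([0.0, 5.0, 50.0, 1e5])[None, :]
        y = eval_and_gate(i, pp, p)
        assert np.allclose(y, y[:, :1])  # identical across the P axis

    def test_strict_and_when_f1_is_zero(self):
        p = ANDGateParams(y0=2.0, dy=10.0, n=2.0, k1=5.0, k2=7.0, f1=0.0)
        sat = 1e8
        assert eval_and_gate(sat, sat, p) == pytest.approx(p.y0 + p.dy, rel=1e-12)
        assert eval_and_gate(sat, 0.0, p) == pytest.approx(p.y0, abs=1e-12)

    def test_half_occupancy_product(self):
        p = ANDGateParams(y0=0.0, dy=1.0, n=1.0, k1=3.0, k2=9.0, f1=0.0)
        assert eval_and_gate(3.0, 9.0, p) == pytest.approx(0.25, rel=1e-12)

    @pytest.mark.parametrize("f1", [-0.1, 1.1])
    def test_leak_fraction_domain(self, f1):
        with pytest.raises(ParameterError):
            ANDGateParams(y0=0, dy=1, n=1, k1=1, k2=1, f1=f1)

    @given(
        n=st.floats(0.5, 4.0),
        k1=st.floats(0.1, 100.0),
        k2=st.floats(0.1, 100.0),
        f1=st.floats(0.0, 1.0),
    )
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_monotone_nondecreasing_both_axes(self, n, k1, k2, f1):
        p = ANDGateParams(y0=1.0, dy=50.0, n=n, k1=k1, k2=k2, f1=f1)
        grid = np.geomspace(1e-3, 1e4, 25)
        surface = eval_and_gate(grid[:, None], grid[None, :], p)
        assert np.all(np.diff(surface, axis=0) >= -1e-12)
        assert np.all(np.diff(surface, axis=1) >= -1e-12)

    @given(
        n=st.floats(0.5, 4.0),
        f1=st.floats(0.0, 1.0),
        dy=st.floats(0.1, 1e4),
    )
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_anchor_identities_at_saturation(self, n, f1, dy):
        """Basal, dual-saturated, and I-only-saturated outputs hit their
        closed-form anchors exactly in the saturating limit."""
        p = ANDGateParams(y0=3.0, dy=dy, n=n, k1=7.0, k2=11.0, f1=f1)
        assert eval_and_gate(0.0, 0.0, p) == p.y0
        assert eval_and_gate(np.inf, np.inf, p) == pytest.approx(p.y0 + p.dy, rel=1e-12)
        assert eval_and_gate(np.inf, 0.0, p) == pytest.approx(
            p.y0 + f1 * p.dy, rel=1e-12, abs=1e-12
        )

    def test_anchor_identities_at_finite_saturation(self):
        """With concentrations at 1e6x each K and a steep-enough Hill
        coefficient, the anchors hold to absolute 1e-9 on a unit-scale gate."""
        p = ANDGateParams(y0=0.2, dy=1.0, n=2.0, k1=4.0, k2=9.0, f1=0.3)
        sat1, sat2 = 1e6 * p.k1, 1e6 * p.k2
        assert abs(eval_and_gate(0.0, 0.0, p) - p.y0) < 1e-9
        assert abs(eval_and_gate(sat1, sat2, p) - (p.y0 + p.dy)) < 1e-9
        assert abs(eval_and_gate(sat1, 0.0, p) - (p.y0 + p.f1 * p.dy)) < 1e-9

    def test_slice_at_saturating_i_is_exact_4pl_in_p(self):
        gate = ANDGateParams(y0=10.0, dy=500.0, n=1.7, k1=20.0, k2=80.0, f1=0.2)
        p_grid = np.geomspace(1e-2, 1e5, 60)
        slice_vals = eval_and_gate(np.inf, p_grid, gate)
        equiv = FourPLParams(
            y0=gate.y0 + gate.f1 * gate.dy, ymax=gate.y0 + gate.dy,
            ec50=gate.k2, n=gate.n,
        )
        assert np.max(np.abs(slice_vals - eval_four_pl(p_grid, equiv))) < 1e-10


class TestDerivedQuantities:
    def test_ec_quantile_closed_forms(self, fourpl_ref):
        assert ec_quantile(fourpl_ref, 0.5) == pytest.approx(fourpl_ref.ec50)
        assert ec_quantile(fourpl_ref, 0.9) == pytest.approx(9 * fourpl_ref.ec50)
        p2 = FourPLParams(y0=0, ymax=1, ec50=12.0, n=2.0)
        assert ec_quantile(p2, 0.1) == pytest.approx(12.0 / 3.0)

    @pytest.mark.parametrize("q", [0.0, 1.0, -0.2, 1.5])
    def test_ec_quantile_domain(self, fourpl_ref, q):
        with pytest.raises(ValueError):
            ec_quantile(fourpl_ref, q)

    def test_ec_quantile_matches_numeric_root(self, fourpl_ref):
        for q in (0.1, 0.25, 0.9):
            target = fourpl_ref.y0 + q * (fourpl_ref.ymax - fourpl_ref.y0)
            root = brentq(
                lambda x: eval_four_pl(x, fourpl_ref) - target, 1e-9, 1e9,
                xtol=1e-12, rtol=1e-14,
            )
            assert ec_quantile(fourpl_ref, q) == pytest.approx(root, rel=1e-9)

    def test_drlr_special_values(self):
        assert drlr_analytic(FourPLParams(0, 1, 1, 1.0)) == pytest.approx(81.0)
        assert drlr_analytic(FourPLParams(0, 1, 1, 40.0)) == pytest.approx(1.0, abs=0.2)
        assert drlr_analytic(FourPLParams(0, 1, 1, 1.90848)) == pytest.approx(
            10.0, rel=1e-4
        )

    @given(n=st.floats(0.3, 10.0))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_drlr_agrees_with_bisection(self, n):
        """81**(1/n) equals the EC90/EC10 ratio found by root-finding on
        the curve itself, to 1e-8 relative, across n in [0.3, 10]."""
        p = FourPLParams(y0=7.0, ymax=120.0, ec50=3.0, n=n)

        def conc_at(q):
            target = p.y0 + q * (p.ymax - p.y0)
            return brentq(
                lambda x: eval_four_pl(x, p) - target, 1e-12, 1e12,
                xtol=1e-300, rtol=1e-15,
            )

        numeric = conc_at(0.9) / conc_at(0.1)
        assert drlr_analytic(p) == pytest.approx(numeric, rel=1e-8)

    def test_drlr_independent_of_scale_params(self):
        a = FourPLParams(y0=0, ymax=1, ec50=1.0, n=1.4)
        b = FourPLParams(y0=500, ymax=9e4, ec50=777.0, n=1.4)
        assert drlr_analytic(a) == drlr_analytic(b)
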