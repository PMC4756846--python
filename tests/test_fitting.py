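"""Parameter estimation: 4PL slice fits, global AND-gate fits, contours."""

import itertools

import numpy as np
import pytest

from gatefit import (
    ANDGateParams,
    FourPLParams,
    InsufficientDataError,
    NoiseModel,
    default_levels,
    drlr_numeric,
    eval_four_pl,
    extract_contours,
    fit_and_gate_global,
    fit_four_pl,
    simulate_matrix,
    slice_matrix,
)
from gatefit.models import eval_and_gate

from conftest import log_points


class TestSliceMatrix:
    def test_selects_requested_axis(self, noiseless_matrix):
        i_sat = noiseless_matrix.i_levels[-1]
        s = slice_matrix(noiseless_matrix, "P", i_sat)
        assert s.conc.size == noiseless_matrix.p_levels.size
        np.testing.assert_array_equal(s.conc, noiseless_matrix.p_levels)

    def test_missing_level_lists_available(self, noiseless_matrix):
        with pytest.raises(LookupError, match="available"):
            slice_matrix(noiseless_matrix, "P", 123.456)

    def test_saturating_slice_matches_4pl(self, gate_ref, noiseless_matrix):
        """A P slice at near-saturating I is (nearly) a 4PL with midpoint k2."""
        i_sat = noiseless_matrix.i_levels[-1]  # 100x k1
        s = slice_matrix(noiseless_matrix, "P", i_sat)
        hi_sat = i_sat**gate_ref.n / (gate_ref.k1**gate_ref.n + i_sat**gate_ref.n)
        equiv = FourPLParams(
            y0=gate_ref.y0 + gate_ref.f1 * gate_ref.dy * hi_sat,
            ymax=gate_ref.y0 + gate_ref.dy * hi_sat,
            ec50=gate_ref.k2,
            n=gate_ref.n,
        )
        np.testing.assert_allclose(
            s.responses[:, 0], eval_four_pl(s.conc, equiv), rtol=1e-12
        )


class TestFourPLFit:
    def test_noiseless_recovery(self, fourpl_ref):
        x = log_points(fourpl_ref.ec50)
        fit = fit_four_pl((x, eval_four_pl(x, fourpl_ref)))
        assert fit.converged
        assert fit.params.y0 == pytest.approx(fourpl_ref.y0, rel=1e-3)
        assert fit.params.ymax == pytest.approx(fourpl_ref.ymax, rel=1e-3)
        assert fit.params.ec50 == pytest.approx(fourpl_ref.ec50, rel=1e-3)
        assert fit.params.n == pytest.approx(fourpl_ref.n, rel=1e-3)
        assert fit.drlr == pytest.approx(fit.ec90 / fit.ec10, rel=1e-9)
        assert fit.ec10 < fit.params.ec50 < fit.ec90

    def test_flat_series_not_converged(self):
        x = log_points(10.0, 8)
        fit = fit_four_pl((x, np.full_like(x, 42.0)))
        assert not fit.converged
        assert fit.warnings

    def test_too_few_levels_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_four_pl((np.array([0, 1, 2, 3.0]), np.array([0, 1, 2, 3.0])))

    def test_digital_curve_drlr(self):
        """A Hill coefficient of 1.90848 yields the 10-fold (digital) DRLR."""
        p = FourPLParams(y0=100, ymax=10100, ec50=50, n=1.90848)
        x = log_points(p.ec50)
        fit = fit_four_pl((x, eval_four_pl(x, p)))
        assert fit.drlr == pytest.approx(10.0, rel=0.01)

    @pytest.mark.parametrize("scale", [0.001, 1.0, 1000.0])
    def test_drlr_invariant_to_concentration_rescaling(self, fourpl_ref, scale):
        x = log_points(fourpl_ref.ec50)
        y = eval_four_pl(x, fourpl_ref)
        fit = fit_four_pl((x * scale, y))
        assert fit.params.ec50 == pytest.approx(fourpl_ref.ec50 * scale, rel=1e-4)
        assert fit.drlr == pytest.approx(81.0 ** (1 / fourpl_ref.n), rel=1e-4)

    @pytest.mark.parametrize(
        "truth",
        [
            FourPLParams(y0=100, ymax=10100, ec50=50, n=1.0),
            FourPLParams(y0=5, ymax=500, ec50=8, n=2.2),
            FourPLParams(y0=0.5, ymax=90, ec50=300, n=0.7),
        ],
    )
    def test_matches_brute_force_lattice_search(self, truth):
        """The optimizer's solution is at least as good as, and adjacent to,
        an exhaustive grid search on a 4-D lattice around the truth."""
        x = log_points(truth.ec50, 12)
        y = eval_four_pl(x, truth)
        fit = fit_four_pl((x, y))

        factors = np.linspace(0.9, 1.1, 7)
        best_rss, best_combo = np.inf, None
        for fy0, fym, fec, fn in itertools.product(factors, repeat=4):
            cand = FourPLParams(
                y0=truth.y0 * fy0, ymax=truth.ymax * fym,
                ec50=truth.ec50 * fec, n=truth.n * fn,
            )
            rss = float(np.sum((eval_four_pl(x, cand) - y) ** 2))
            if rss < best_rss:
                best_rss, best_combo = rss, cand
        assert fit.rss <= best_rss + 1e-12
        # within one lattice step (~3.3%) of the lattice optimum
        for attr in ("y0", "ymax", "ec50", "n"):
            assert getattr(fit.params, attr) == pytest.approx(
                getattr(best_combo, attr), rel=0.04
            )


class TestGlobalGateFit:
    def test_noiseless_recovery_all_parameters(self, gate_ref, noiseless_matrix):
        fit = fit_and_gate_global(noiseless_matrix)
        assert fit.converged
        for attr in ("y0", "dy", "n", "k1", "k2", "f1"):
            assert getattr(fit.params, attr) == pytest.approx(
                getattr(gate_ref, attr), rel=1e-3
            ), attr
        assert fit.enhancement == pytest.approx(12.0, rel=1e-3)
        assert fit.start_points_tried >= 13

    def test_p_independent_gate_flags_unidentifiable_axis(self):
        truth = ANDGateParams(y0=10, dy=1000, n=1.2, k1=30, k2=50, f1=1.0)
        m = simulate_matrix(truth, replicates=1, noise=NoiseModel(kind="none"))
        fit = fit_and_gate_global(m)
        assert fit.params.f1 >= 0.999
        assert any("unidentifiable" in w for w in fit.warnings)

    def test_three_fold_enhancement_recovery(self, gate_ref):
        truth = ANDGateParams(
            y0=gate_ref.y0, dy=gate_ref.dy, n=gate_ref.n,
            k1=gate_ref.k1, k2=gate_ref.k2, f1=1.0 / 3.0,
        )
        m = simulate_matrix(
            truth,
            i_levels=default_levels(truth.k1, 11),
            p_levels=default_levels(truth.k2, 11),
            replicates=1,
            noise=NoiseModel(kind="none"),
        )
        fit = fit_and_gate_global(m)
        assert fit.enhancement == pytest.approx(3.0, rel=1e-3)

    def test_grid_too_small_rejected(self, gate_ref):
        m = simulate_matrix(
            gate_ref,
            i_levels=[0.0, 10.0, 1000.0],
            p_levels=default_levels(gate_ref.k2, 7),
            replicates=1,
            noise=NoiseModel(kind="none"),
        )
        with pytest.raises(InsufficientDataError, match="I levels"):
            fit_and_gate_global(m)

    def test_recovery_under_noise(self):
        """Median relative error of every gate parameter stays below 10%
        with 5% multiplicative noise and 3 replicates (12 random draws)."""
        rng = np.random.default_rng(2024)
        errs = {k: [] for k in ("y0", "dy", "n", "k1", "k2", "f1")}
        for rep in range(12):
            truth = ANDGateParams(
                y0=50.0,
                dy=8000.0,
                n=float(rng.uniform(0.7, 3.0)),
                k1=float(10 ** rng.uniform(0.5, 2.5)),
                k2=float(10 ** rng.uniform(0.5, 2.5)),
                f1=float(rng.uniform(0.02, 0.9)),
            )
            m = simulate_matrix(
                truth, replicates=3, noise=NoiseModel(cv=0.05, seed=1000 + rep)
            )
            fit = fit_and_gate_global(m)
            for k in errs:
                errs[k].append(
                    abs(getattr(fit.params, k) / getattr(truth, k) - 1.0)
                )
        for k, v in errs.items():
            assert np.median(v) < 0.10, (k, np.median(v))

    def test_noiseless_recovery_random_draws(self):
        rng = np.random.default_rng(7)
        for rep in range(6):
            truth = ANDGateParams(
                y0=20.0,
                dy=5000.0,
                n=float(rng.uniform(0.7, 3.0)),
                k1=float(10 ** rng.uniform(0.5, 2.5)),
                k2=float(10 ** rng.uniform(0.5, 2.5)),
                f1=float(rng.uniform(0.02, 0.9)),
            )
            m = simulate_matrix(truth, replicates=1, noise=NoiseModel(kind="none"))
            fit = fit_and_gate_global(m)
            for k in ("y0", "dy", "n", "k1", "k2", "f1"):
                assert getattr(fit.params, k) == pytest.approx(
                    getattr(truth, k), rel=1e-3
                ), (rep, k)


class TestContours:
    def _normalized(self, params, i, p):
        return (eval_and_gate(i, p, params) - params.y0) / params.dy

    def test_points_reevaluate_to_level(self, gate_ref, noiseless_matrix):
        fit = fit_and_gate_global(noiseless_matrix)
        cs = extract_contours(fit)
        assert cs.levels == (0.10, 0.50, 0.90)
        for level, curve in cs.curves.items():
            assert curve.size > 0
            vals = self._normalized(fit.params, curve[:, 0], curve[:, 1])
            assert np.max(np.abs(vals - level)) < 1e-6

    def test_strict_and_contour_asymptotes(self):
        p = ANDGateParams(y0=0.0, dy=1.0, n=1.0, k1=10.0, k2=40.0, f1=0.0)
        cs = extract_contours(p, i_range=(0.1, 1e5), p_range=(0.4, 4e5), levels=[0.5])
        curve = cs.curves[0.5]
        # at saturating I the contour approaches P = k2 (H(P) -> 0.5)
        far = curve[curve[:, 0] > 1e3 * p.k1]
        assert far.size > 0
        assert np.allclose(far[:, 1], p.k2, rtol=0.01)
        # every point satisfies H(I)H(P) = 0.5 exactly
        vals = self._normalized(p, curve[:, 0], curve[:, 1])
        assert np.max(np.abs(vals - 0.5)) < 1e-9

    def test_p_independent_gate_gives_vertical_contours(self):
        p = ANDGateParams(y0=0.0, dy=1.0, n=1.5, k1=25.0, k2=60.0, f1=1.0)
        cs = extract_contours(p, levels=[0.1, 0.9])
        for level, curve in cs.curves.items():
            assert curve.size > 0
            assert np.ptp(curve[:, 0]) < 1e-9 * np.max(curve[:, 0])  # one I value

    def test_unreachable_level_warns_and_is_empty(self):
        p = ANDGateParams(y0=0.0, dy=1.0, n=1.0, k1=10.0, k2=10.0, f1=0.0)
        with pytest.warns(UserWarning, match="unreachable"):
            cs = extract_contours(
                p, i_range=(1e-4, 1e-3), p_range=(1e-4, 1e-3), levels=[0.9]
            )
        assert cs.curves[0.9].size == 0


class TestDRLRNumeric:
    def test_exact_4pl_matches_closed_form(self):
        p = FourPLParams(y0=10, ymax=110, ec50=5.0, n=1.0)
        ratio = drlr_numeric(lambda x: eval_four_pl(x, p), p.y0, p.ymax)
        assert ratio == pytest.approx(81.0, rel=1e-6)

    def test_analogue_curve_245(self):
        p = FourPLParams(y0=100, ymax=10100, ec50=50, n=0.79881)
        ratio = drlr_numeric(lambda x: eval_four_pl(x, p), p.y0, p.ymax)
        assert ratio == pytest.approx(245.0, rel=0.01)

    def test_decreasing_curve_rejected(self):
        with pytest.raises(ValueError, match="monotone"):
            drlr_numeric(lambda x: 1.0 / (1.0 + x), 0.0, 1.0)
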