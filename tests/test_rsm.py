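import numpy as np
import pytest
from itertools import combinations

from scipy import optimize

from nanodoe.designs import FactorSpec, make_bbd
from nanodoe.rsm import (
    SingularDesignError,
    anova_decompose,
    find_optimum,
    fit_quadratic,
    predict,
    quadratic_terms,
    stationary_point,
)
from nanodoe.synthetic import SurfaceTruth, gen_bbd_responses

TRUTH_COEF = (0.7, -0.14, 0.08, -0.15, 0.11, -0.15, 0.04, -0.26, -0.09, -0.12)


def poly_eval(coef, x):
    """Independent quadratic evaluation used as the oracle for predict()."""
    x = np.asarray(x, dtype=float)
    val = coef[0] + np.dot(coef[1:4], x)
    k = 4
    for i, j in combinations(range(3), 2):
        val += coef[k] * x[i] * x[j]
        k += 1
    val += np.dot(coef[7:10], x ** 2)
    return val


class TestFit:
    def test_noiseless_self_consistency(self):
        """An exact quadratic response is recovered to machine precision."""
        design, y = gen_bbd_responses(SurfaceTruth(m=3, coef=TRUTH_COEF, noise_sd=0.0))
        fit = fit_quadratic(design, y)
        assert np.max(np.abs(fit.coef.to_numpy() - TRUTH_COEF)) < 1e-10
        assert fit.ss_residual < 1e-18
        # fitted surface reproduces the generating values at every design point
        for row, yi in zip(design.coded.to_numpy(dtype=float), y):
            assert predict(fit, row) == pytest.approx(yi, abs=1e-10)

    def test_constant_response(self):
        design = make_bbd(5)
        fit = fit_quadratic(design, np.full(17, 3.5))
        assert fit.intercept == pytest.approx(3.5, abs=1e-10)
        assert np.max(np.abs(fit.coef.to_numpy()[1:])) < 1e-10

    def test_contrast_identity_on_bbd(self, bbd_design, published_od):
        """On the orthogonal BBD, OLS linear coefficients equal sum(xi*y)/8 and
        interactions equal sum(xi*xj*y)/4 — two independent computations."""
        fit = fit_quadratic(bbd_design, published_od)
        x = bbd_design.coded.to_numpy(dtype=float)
        for i, name in enumerate(bbd_design.factor_names):
            contrast = float(x[:, i] @ published_od) / 8.0
            assert fit.coef[name] == pytest.approx(contrast, abs=1e-10)
        for i, j in combinations(range(3), 2):
            contrast = float((x[:, i] * x[:, j]) @ published_od) / 4.0
            key = f"{bbd_design.factor_names[i]}:{bbd_design.factor_names[j]}"
            assert fit.coef[key] == pytest.approx(contrast, abs=1e-10)

    def test_fit_invariant_to_run_order(self, bbd_design, published_od):
        rng = np.random.default_rng(5)
        perm = rng.permutation(17)
        shuffled = bbd_design.coded.iloc[perm]
        fit_a = fit_quadratic(bbd_design, published_od)
        fit_b = fit_quadratic(shuffled, published_od[perm])
        assert np.allclose(fit_a.coef.to_numpy(), fit_b.coef.to_numpy(), atol=1e-12)

    def test_singular_design_rejected(self):
        # two-level design: squared columns collapse onto the intercept
        x = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]] * 4, dtype=float)
        with pytest.raises(SingularDesignError):
            fit_quadratic(x, np.arange(16.0))

    def test_insufficient_runs_rejected(self):
        design = make_bbd(5)
        with pytest.raises(ValueError, match="insufficient|runs"):
            fit_quadratic(design.coded.iloc[:9], np.arange(9.0))

    def test_estimation_error_shrinks_with_noise(self):
        """Mean absolute coefficient error grows with the noise sd (O(sigma))."""
        errs = {}
        for sd in (0.05, 0.2):
            e = []
            for rep in range(40):
                design, y = gen_bbd_responses(
                    SurfaceTruth(m=3, coef=TRUTH_COEF, noise_sd=sd, seed=1000 + rep))
                fit = fit_quadratic(design, y)
                e.append(np.abs(fit.coef.to_numpy() - TRUTH_COEF).mean())
            errs[sd] = np.mean(e)
        assert errs[0.2] > 2.0 * errs[0.05]


class TestAnova:
    def test_sum_of_squares_additivity(self, bbd_design, published_od):
        fit = fit_quadratic(bbd_design, published_od)
        rows = {r.source: r for r in anova_decompose(fit, bbd_design, published_od)}
        assert rows["model"].ss + rows["residual"].ss == pytest.approx(
            rows["total"].ss, rel=1e-9)
        assert rows["lack of fit"].ss + rows["pure error"].ss == pytest.approx(
            rows["residual"].ss, rel=1e-9)
        assert rows["model"].df + rows["residual"].df == rows["total"].df
        assert rows["lack of fit"].df + rows["pure error"].df == rows["residual"].df

    def test_noiseless_quadratic_has_no_residual(self):
        design, y = gen_bbd_responses(SurfaceTruth(m=3, coef=TRUTH_COEF, noise_sd=0.0))
        fit = fit_quadratic(design, y)
        rows = {r.source: r for r in anova_decompose(fit, design, y)}
        assert rows["residual"].ss < 1e-18
        assert rows["lack of fit"].ss == pytest.approx(0.0, abs=1e-18)

    def test_partial_ss_match_orthogonal_contrast_ss(self, bbd_design, published_od):
        """For linear terms on the BBD, drop-one-column SS equals 8*b^2."""
        fit = fit_quadratic(bbd_design, published_od)
        rows = {r.source: r for r in anova_decompose(fit, bbd_design, published_od)}
        for name in bbd_design.factor_names:
            assert rows[name].ss == pytest.approx(8.0 * fit.coef[name] ** 2, rel=1e-9)

    def test_unreplicated_design_warns_and_omits_lof(self):
        design, y = gen_bbd_responses(SurfaceTruth(m=3, coef=TRUTH_COEF,
                                                   noise_sd=0.1, seed=3), n_center=1)
        fit = fit_quadratic(design, y)
        with pytest.warns(UserWarning, match="replicated"):
            rows = anova_decompose(fit, design, y)
        sources = {r.source for r in rows}
        assert "lack of fit" not in sources and "residual" in sources


class TestOptimum:
    SPECS = [FactorSpec("X1", low=1.5, center=2.0, high=2.5, units="mg/mL"),
             FactorSpec("X2", low=1.0, center=2.0, high=3.0, units="mg/mL"),
             FactorSpec("X3", low=1.0, center=2.0, high=3.0, units="ratio")]

    def test_pure_concave_bowl_peaks_at_origin(self):
        coef = (2.0, 0, 0, 0, 0, 0, 0, -1.0, -1.0, -1.0)
        design, y = gen_bbd_responses(SurfaceTruth(m=3, coef=coef, noise_sd=0.0))
        fit = fit_quadratic(design, y)
        opt = find_optimum(fit, self.SPECS, goal="maximize")
        assert opt.classification == "interior maximum"
        assert np.allclose(opt.coded, 0.0, atol=1e-10)
        assert opt.predicted == pytest.approx(2.0, abs=1e-10)

    def test_stationary_point_matches_numeric_optimizer(self, bbd_design, published_od):
        """The closed-form stationary point agrees with an independent
        numerical maximization of the fitted surface."""
        fit = fit_quadratic(bbd_design, published_od)
        xs = stationary_point(fit)
        res = optimize.minimize(lambda p: -predict(fit, p), np.zeros(3),
                                bounds=[(-1, 1)] * 3, method="L-BFGS-B",
                                options={"ftol": 1e-15, "gtol": 1e-12})
        assert np.allclose(xs, res.x, atol=1e-6)

    def test_optimum_dominates_design_points(self, bbd_design, published_od):
        fit = fit_quadratic(bbd_design, published_od)
        opt = find_optimum(fit, self.SPECS, goal="maximize")
        for row in bbd_design.coded.to_numpy(dtype=float):
            assert opt.predicted >= predict(fit, row) - 1e-12

    def test_boundary_optimum_when_stationary_point_outside_cube(self):
        # strongly tilted surface: maximum sits on the cube boundary
        coef = (0.0, 1.0, 0, 0, 0, 0, 0, -0.1, -0.1, -0.1)
        design, y = gen_bbd_responses(SurfaceTruth(m=3, coef=coef, noise_sd=0.0))
        fit = fit_quadratic(design, y)
        opt = find_optimum(fit, self.SPECS, goal="maximize")
        assert "boundary" in opt.classification
        assert opt.coded[0] == pytest.approx(1.0, abs=1e-6)

    def test_rounding_of_natural_optimum(self, bbd_design, published_od):
        fit = fit_quadratic(bbd_design, published_od)
        opt = find_optimum(fit, self.SPECS, goal="maximize", rounding_step=0.1)
        assert opt.natural_rounded == pytest.approx([2.0, 2.3, 1.5])


class TestPredict:
    def test_at_center_returns_intercept(self, bbd_design, published_od):
        fit = fit_quadratic(bbd_design, published_od)
        assert predict(fit, [0, 0, 0]) == pytest.approx(fit.intercept)

    def test_matches_independent_polynomial_evaluation(self, published_coef, bbd_design,
                                                       published_od):
        fit = fit_quadratic(bbd_design, published_od)
        coef = fit.coef.to_numpy()
        for pt in ([0.0, 0.3, -0.5], [1.0, -1.0, 0.25], [-0.052, 0.258, -0.545]):
            assert predict(fit, pt) == pytest.approx(poly_eval(coef, pt), abs=1e-12)

    def test_dimension_check(self, bbd_design, published_od):
        fit = fit_quadratic(bbd_design, published_od)
        with pytest.raises(ValueError):
            predict(fit, [0.0, 0.0])


def test_quadratic_terms_layout():
    mm = quadratic_terms(np.array([[1.0, 2.0, 3.0]]), ["X1", "X2", "X3"])
    assert list(mm.columns) == ["const", "X1", "X2", "X3", "X1:X2", "X1:X3",
                                "X2:X3", "X1^2", "X2^2", "X3^2"]
    assert mm.iloc[0].tolist() == [1, 1, 2, 3, 2, 3, 6, 1, 4, 9]
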