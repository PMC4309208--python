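"""Inverse-identification machinery: DOE, RMS metric, quadratic
surrogate, box minimization and the identification loop.

The identification loop is exercised here against a fast analytic
forward model with strong, smooth sensitivity to both factors; the
end-to-end loop over the finite-element forward model is covered by the
acceptance suite.
"""

import numpy as np
import pytest
from sklearn.base import clone

from porodisc.metamodel import (
    DiskParameterIdentifier,
    QuadraticResponseSurface,
    SearchWindow,
    backward_identify,
    default_window,
    full_factorial,
    minimize_qrs,
    rms_error,
)

WINDOW = SearchWindow((1.2, 1.8), (1.56e-16, 2.34e-16))


def analytic_forward(e_np: float, k: float) -> np.ndarray:
    """Surrogate sweep with smooth sensitivity to both factors."""
    j = np.arange(6)
    return (4.2 / e_np) * (1.0 + 0.25 * (j / 5.0) * (k / 2.0e-16))


class TestSearchWindow:
    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError):
            SearchWindow((1.5, 1.5), (1e-16, 2e-16))
        with pytest.raises(ValueError):
            SearchWindow((1.2, 1.8), (2e-16, 1e-16))

    def test_scale_unscale_roundtrip(self):
        pts = full_factorial(WINDOW)
        back = WINDOW.unscale(WINDOW.scale(pts))
        assert np.allclose(back, pts, rtol=1e-12)

    def test_expansion_recentres_and_widens(self):
        w2 = WINDOW.expanded_around(1.8, 2.0e-16)
        assert w2.e_np_range == pytest.approx((1.8 - 0.45, 1.8 + 0.45))
        assert w2.k_range[1] - w2.k_range[0] == pytest.approx(1.5 * 0.78e-16)
        assert w2.e_np_range[0] > 0 and w2.k_range[0] > 0

    def test_expansion_clips_at_positivity(self):
        w = SearchWindow((0.1, 2.0), (1e-16, 2e-16)).expanded_around(0.1, 1e-16)
        assert w.e_np_range[0] > 0
        assert w.k_range[0] > 0


class TestFullFactorial:
    def test_levels_and_values(self):
        pts = full_factorial(WINDOW)
        assert pts.shape == (25, 2)
        assert np.allclose(np.unique(pts[:, 0]), [1.2, 1.35, 1.5, 1.65, 1.8])
        # modulus is the outer loop: first 5 points share the lowest E
        assert np.allclose(pts[:5, 0], 1.2)
        assert np.allclose(pts[:5, 1], np.linspace(1.56e-16, 2.34e-16, 5))

    def test_three_levels(self):
        pts = full_factorial(SearchWindow((1.0, 2.0), (1e-16, 2e-16), levels=3))
        assert pts.shape == (9, 2)


class TestRmsError:
    def test_identity_is_zero(self):
        assert rms_error([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_uniform_offset(self):
        assert rms_error([1.05] * 4, [1.0] * 4) == pytest.approx(5.0)

    def test_hand_computed_value(self):
        # 100 * sqrt((0.2^2 + 0.1^2)/2) / 1.5
        assert rms_error([2.2, 0.9], [2.0, 1.0]) == pytest.approx(10.540925, rel=1e-6)

    def test_symmetric_under_frequency_permutation(self):
        a, b = np.array([1.0, 1.3, 0.9]), np.array([1.1, 1.2, 1.0])
        perm = [2, 0, 1]
        assert rms_error(a, b) == pytest.approx(rms_error(a[perm], b[perm]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            rms_error([1.0, 2.0], [1.0])
        with pytest.raises(ValueError):
            rms_error([1.0, -1.0], [1.0, -1.0])


class TestQuadraticResponseSurface:
    def test_exact_polynomial_recovered(self):
        coef = np.array([3.0, 1.0, -2.0, 0.5, 0.7, -0.3])
        pts = full_factorial(WINDOW)
        y = QuadraticResponseSurface._design(WINDOW.scale(pts)) @ coef
        qrs = QuadraticResponseSurface(window=WINDOW).fit(pts, y)
        assert np.allclose(qrs.coef_, coef, rtol=1e-8)
        assert qrs.r2_ == pytest.approx(1.0)
        assert np.allclose(qrs.predict(pts), y, rtol=1e-8)

    def test_constant_response(self):
        pts = full_factorial(WINDOW)
        qrs = QuadraticResponseSurface(window=WINDOW).fit(pts, np.full(25, 7.5))
        assert qrs.coef_[0] == pytest.approx(7.5)
        assert np.allclose(qrs.coef_[1:], 0.0, atol=1e-10)

    def test_collinear_design_rejected(self):
        e = np.linspace(1.2, 1.8, 10)
        pts = np.column_stack([e, np.full(10, 2.0e-16)])
        with pytest.raises(ValueError, match="rank"):
            QuadraticResponseSurface(window=WINDOW).fit(pts, np.ones(10))


class TestMinimizeQrs:
    def _model(self, coef):
        qrs = QuadraticResponseSurface(window=WINDOW)
        qrs.window_ = WINDOW
        qrs.coef_ = np.asarray(coef, dtype=float)
        return qrs

    def test_centred_paraboloid(self):
        e, k = minimize_qrs(self._model([1.0, 0.0, 0.0, 2.0, 3.0, 0.0]))
        assert e == pytest.approx(1.5)
        assert k == pytest.approx(1.95e-16)

    def test_monotone_plane_returns_corner(self):
        e, k = minimize_qrs(self._model([1.0, -2.0, 1.0, 0.0, 0.0, 0.0]))
        assert e == pytest.approx(1.8)
        assert k == pytest.approx(1.56e-16)

    @pytest.mark.parametrize(
        "coef",
        [
            [1.0, 0.5, -0.3, 0.2, -0.4, 0.6],   # indefinite
            [0.0, 0.1, 0.2, -1.0, -1.0, 0.0],   # concave: corner minimum
            [2.0, -0.8, 0.1, 0.9, 0.05, -0.7],  # edge minimum
        ],
    )
    def test_matches_dense_grid_oracle(self, coef):
        model = self._model(coef)
        n = 201
        s = np.linspace(-1, 1, n)
        xx, yy = np.meshgrid(s, s, indexing="ij")
        grid = np.column_stack([xx.ravel(), yy.ravel()])
        vals = model.predict_scaled(grid)
        best = grid[np.argmin(vals)]
        e, k = minimize_qrs(model)
        found = WINDOW.scale(np.array([[e, k]]))[0]
        cell = 2.0 / (n - 1)
        assert np.all(np.abs(found - best) <= cell + 1e-12)


class TestBackwardIdentify:
    def test_noise_free_convergence_and_recovery(self):
        truth = (1.41, 2.17e-16)
        obs = analytic_forward(*truth)
        res = backward_identify(obs, analytic_forward, WINDOW)
        assert res.converged
        assert res.rms_pct_final < 5.0
        assert res.e_np_opt == pytest.approx(truth[0], rel=0.10)
        assert res.e_af_opt / res.e_np_opt == pytest.approx(1.67, rel=1e-12)
        assert len(res.doe_records) == 25 * res.rounds

    def test_monotone_improvement_over_doe(self):
        rng = np.random.default_rng(3)
        obs = analytic_forward(1.41, 2.17e-16) * (1 + rng.normal(0, 0.02, 6))
        res = backward_identify(obs, analytic_forward, WINDOW)
        last = [r.rms_pct for r in res.doe_records if r.round == res.rounds]
        assert res.rms_pct_final <= min(last) + 1e-12

    def test_deterministic(self):
        rng = np.random.default_rng(11)
        obs = analytic_forward(1.5, 1.9e-16) * (1 + rng.normal(0, 0.02, 6))
        r1 = backward_identify(obs, analytic_forward, WINDOW)
        r2 = backward_identify(obs, analytic_forward, WINDOW)
        assert r1.e_np_opt == r2.e_np_opt
        assert r1.k_opt == r2.k_opt
        assert r1.rms_pct_final == r2.rms_pct_final

    def test_window_expansion_reaches_outside_truth(self):
        truth = (2.5, 2.0e-16)  # modulus outside the initial window
        obs = analytic_forward(*truth)
        res = backward_identify(obs, analytic_forward, WINDOW, max_rounds=6)
        assert len(res.windows_visited) > 1
        final = res.windows_visited[-1]
        assert final.e_np_range[0] <= truth[0] <= final.e_np_range[1]
        assert res.rms_pct_final < 5.0

    def test_doe_table_layout(self):
        obs = analytic_forward(1.41, 2.17e-16)
        res = backward_identify(obs, analytic_forward, WINDOW)
        table = res.doe_table()
        assert list(table.columns) == ["round", "e_np", "k", "rms_pct"]
        assert len(table) == 25 * res.rounds
        assert (table.rms_pct >= 0).all()


class TestDiskParameterIdentifier:
    def test_sklearn_estimator_contract(self):
        est = DiskParameterIdentifier(window=WINDOW, forward=analytic_forward)
        cloned = clone(est)
        assert cloned.get_params()["window"] == WINDOW
        est2 = est.set_params(max_rounds=3)
        assert est2.max_rounds == 3

    def test_fit_attributes_and_predict(self):
        freqs = np.array([0.01, 0.063, 0.1, 0.63, 1.0, 6.3])
        obs = analytic_forward(1.41, 2.17e-16)
        est = DiskParameterIdentifier(window=WINDOW, forward=analytic_forward)
        est.fit(freqs, obs)
        assert est.converged_
        assert est.rms_pct_final_ < 5.0
        assert est.e_af_ == pytest.approx(1.67 * est.e_np_)
        pred = est.predict(freqs)
        assert pred.shape == (6,)
        assert np.allclose(pred, analytic_forward(est.e_np_, est.k_))

    def test_unfitted_predict_raises(self):
        from sklearn.exceptions import NotFittedError

        est = DiskParameterIdentifier(window=WINDOW, forward=analytic_forward)
        with pytest.raises(NotFittedError):
            est.predict(np.array([0.1, 1.0]))

    def test_default_windows_match_group_ranges(self):
        w = default_window("intact")
        assert w.e_np_range == (1.2, 1.8)
        assert w.k_range == (1.56e-16, 2.34e-16)
        wd = default_window("degenerated")
        assert wd.k_range == (1.18e-16, 1.76e-16)
        with pytest.raises(ValueError):
            default_window("unknown")
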