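"""MaxEnt features, penalised fitting (oracle-checked), prediction, importance."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from parasdm import maxent as mx
from parasdm.geodata import GridSpec, OccurrenceSet
from tests.conftest import stack_from


def grid_search_objective(F_pres, F_bg, betas, half_width=8.0, rounds=9, points=25):
    """Independent nested grid-search maximiser for <=2-feature problems."""
    k = F_pres.shape[1]
    centre = np.zeros(k)
    width = half_width

    def objective(lam):
        return mx.penalized_objective(np.asarray(lam), F_pres, F_bg, betas)

    best_val, best_lam = objective(centre), centre
    for _ in range(rounds):
        axes = [np.linspace(c - width, c + width, points) for c in centre]
        grids = np.meshgrid(*axes, indexing="ij")
        pts = np.column_stack([g.ravel() for g in grids])
        vals = np.array([objective(p) for p in pts])
        i = int(np.argmax(vals))
        if vals[i] > best_val:
            best_val, best_lam = vals[i], pts[i]
        centre = pts[i]
        width *= 2.5 / points
    return best_val, best_lam


class TestFeatures:
    def test_boundary_values(self):
        X = np.array([[0.0], [1.0], [0.5]])
        fs = mx.FeatureSet.build(X, ["x"], classes="LQH", k_h=3)
        F = fs.transform(X)
        names = fs.feature_names()
        at_min, at_max = F[0], F[1]
        assert at_min[names.index("L:x")] == 0 and at_min[names.index("Q:x")] == 0
        assert at_max[names.index("L:x")] == 1 and at_max[names.index("Q:x")] == 1
        fwd = [i for i, n in enumerate(names) if n.startswith("HF")]
        rev = [i for i, n in enumerate(names) if n.startswith("HR")]
        assert np.all(at_min[fwd] == 0) and np.all(at_min[rev] > 0)
        assert np.all(F >= 0) and np.all(F <= 1)

    def test_hinge_hand_example(self):
        # single knot at 0.5 on [0, 1]: x=0.75 -> forward 0.5, reverse 0
        X = np.array([[0.0], [1.0], [0.75]])
        fs = mx.FeatureSet.build(X, ["x"], classes="H", k_h=1)
        np.testing.assert_allclose(fs.hinge_knots["x"], [0.5])
        F = fs.transform(X)
        np.testing.assert_allclose(F[2], [0.5, 0.0])

    def test_constant_covariate_dropped(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        fs = mx.FeatureSet.build(X, ["flat", "x"], classes="L")
        assert fs.covariate_names == ["x"]

    def test_penalty_tables_interpolate_with_sample_size(self):
        F = np.random.default_rng(0).uniform(size=(65, 2))
        b65 = mx.default_penalties(F, ["L", "L"], "L", rm=1.0)
        b_small = mx.default_penalties(F[:12], ["L", "L"], "L", rm=1.0)
        # base beta shrinks with m (1.0 at m=10 down to 0.05 at m=100)
        assert np.all(b_small > b65)


class TestFit:
    def test_infinite_penalty_gives_uniform_model(self):
        F_pres = np.ones((5, 1))
        F_bg = np.vstack([np.zeros((50, 1)), np.ones((50, 1))])
        lam, lz, H = mx.fit_maxent(F_pres, F_bg, np.array([1e9]))
        assert lam[0] == 0.0
        assert H == pytest.approx(np.log(100), abs=1e-12)
        assert lz == pytest.approx(np.log(100), abs=1e-12)

    def test_binary_feature_matches_golden_section_oracle(self):
        F_pres = np.ones((6, 1))
        F_bg = np.vstack([np.zeros((50, 1)), np.ones((50, 1))])
        beta = 0.1
        lam, _, _ = mx.fit_maxent(F_pres, F_bg, np.array([beta]), tol=1e-8)

        def neg(l):
            return -(np.mean(F_pres * l) - logsumexp(F_bg * l) - beta * abs(l))

        oracle = minimize_scalar(neg, bounds=(-20, 20), method="bounded",
                                 options={"xatol": 1e-12})
        assert lam[0] == pytest.approx(oracle.x, abs=1e-5)

    @pytest.mark.parametrize("n_features", [1, 2])
    def test_objective_matches_nested_grid_search(self, n_features):
        rng = np.random.default_rng(100 + n_features)
        F_pres = rng.uniform(0.4, 1.0, size=(8, n_features))
        F_bg = rng.uniform(0.0, 1.0, size=(60, n_features))
        betas = np.full(n_features, 0.05)
        lam, _, _ = mx.fit_maxent(F_pres, F_bg, betas, tol=1e-9)
        fitted = mx.penalized_objective(lam, F_pres, F_bg, betas)
        oracle_val, _ = grid_search_objective(F_pres, F_bg, betas)
        assert fitted == pytest.approx(oracle_val, abs=1e-6)
        assert fitted >= oracle_val - 1e-6  # optimiser at least as good

    def test_kkt_moment_match_within_penalties(self):
        # stationarity of the penalised likelihood: model feature expectations
        # stay within beta_j of presence means
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            classes = ("L", "LQ", "LQH")[seed % 3]
            X_pres = rng.normal(0.4, 0.25, size=(25, 2))
            X_bg = rng.uniform(-0.5, 1.5, size=(300, 2))
            model = mx.train_maxent(X_pres, X_bg, ["a", "b"], classes=classes,
                                    rm=1.0, k_h=4, tol=1e-7)
            F_p = model.features.transform(X_pres)
            F_b = model.features.transform(X_bg)
            q = np.exp(F_b @ model.coefficients - model.log_partition)
            gap = np.abs(F_b.T @ q - F_p.mean(axis=0))
            assert np.all(gap <= model.penalties + 1e-5)

    def test_raw_predictions_sum_to_one_over_background(self):
        rng = np.random.default_rng(8)
        X_pres = rng.normal(0.6, 0.2, size=(30, 3))
        X_bg = rng.uniform(0, 1, size=(400, 3))
        model = mx.train_maxent(X_pres, X_bg, list("abc"), classes="LQ")
        raw = model.raw_from_features(model.features.transform(X_bg))
        assert raw.sum() == pytest.approx(1.0, abs=1e-6)
        assert 0 <= model.entropy <= np.log(400) + 1e-9

    def test_nonconvergence_raises_with_grad_norm(self):
        rng = np.random.default_rng(1)
        F_pres = rng.uniform(size=(20, 4))
        F_bg = rng.uniform(size=(200, 4))
        with pytest.raises(mx.ConvergenceError) as exc:
            mx.fit_maxent(F_pres, F_bg, np.full(4, 1e-4), tol=1e-16, max_iter=3)
        assert exc.value.grad_norm > 0


class TestPredict:
    def test_uniform_model_closed_form(self):
        F_pres = np.ones((5, 1))
        X_bg = np.linspace(0, 1, 80).reshape(-1, 1)
        model = mx.train_maxent(np.full((5, 1), 0.8), X_bg, ["x"], classes="L", rm=1e9)
        raw = model.predict_matrix(X_bg, output="raw")
        np.testing.assert_allclose(raw, 1 / 80, atol=1e-12)
        cll = model.predict_matrix(X_bg, output="cloglog")
        np.testing.assert_allclose(cll, 1 - np.exp(-1.0), atol=1e-12)
        logi = model.predict_matrix(X_bg, output="logistic")
        np.testing.assert_allclose(logi, 0.5, atol=1e-12)

    def test_clamping_beyond_training_max(self):
        rng = np.random.default_rng(2)
        model = mx.train_maxent(rng.uniform(0.5, 1, (20, 1)), rng.uniform(0, 1, (100, 1)),
                                ["x"], classes="LQ")
        inside = model.predict_matrix(np.array([[1.0]]))
        beyond = model.predict_matrix(np.array([[7.0]]))
        assert beyond[0] == pytest.approx(inside[0], abs=1e-14)

    def test_nested_classes_do_not_lose_training_gain(self):
        # richer nested feature spaces fit training data at least as well
        rng = np.random.default_rng(6)
        X_pres = rng.normal(0.7, 0.15, size=(40, 2))
        X_bg = rng.uniform(0, 1, size=(500, 2))
        gains = []
        for classes in ("L", "LQ", "LQH"):
            model = mx.train_maxent(X_pres, X_bg, ["a", "b"], classes=classes, k_h=6)
            F_p = model.features.transform(X_pres)
            # unpenalised training gain: mean presence log raw + log n_bg
            gain = float(np.mean(F_p @ model.coefficients) - model.log_partition) + np.log(500)
            gains.append(gain)
        assert gains[0] <= gains[1] + 1e-3 and gains[1] <= gains[2] + 1e-3

    def test_model_json_roundtrip(self, tmp_path):
        rng = np.random.default_rng(3)
        model = mx.train_maxent(rng.normal(0.5, 0.2, (25, 2)), rng.uniform(0, 1, (200, 2)),
                                ["a", "b"], classes="LQH", k_h=3)
        model.to_json(tmp_path / "m.json")
        back = mx.MaxentModel.from_json(tmp_path / "m.json")
        X = rng.uniform(0, 1, (50, 2))
        np.testing.assert_allclose(back.predict_matrix(X), model.predict_matrix(X))


@pytest.fixture(scope="module")
def one_signal_world():
    spec = GridSpec(0.0, 30.0, 0.1, 50, 40)
    rng = np.random.default_rng(21)
    signal = np.linspace(-2, 2, 50)[:, None] + 0.3 * rng.normal(size=spec.shape)
    noise = rng.normal(size=spec.shape)
    stack = stack_from(spec, {"signal": signal, "noise": noise})
    # presences where signal is high
    rows, cols = np.unravel_index(np.argsort(signal.ravel())[-60:], spec.shape)
    lon, lat = spec.cell_center(rows, cols)
    occ = OccurrenceSet("sp", np.column_stack([lon, lat]))
    return stack, occ


class TestPermutationImportance:
    def test_single_covariate_model_gets_everything(self, one_signal_world):
        stack, occ = one_signal_world
        sub = stack.subset(["signal"])
        X = sub.to_matrix()
        X_pres = mx.covariates_at(occ, sub)
        model = mx.train_maxent(X_pres, X, ["signal"], classes="LQ")
        imp = mx.permutation_importance(model, sub, occ, n_perm=3, seed=0)
        assert imp["signal"] == pytest.approx(100.0)

    def test_covariate_with_zero_coefficients_scores_zero(self, one_signal_world):
        stack, occ = one_signal_world
        X_pres = mx.covariates_at(occ, stack)
        X_bg = stack.to_matrix()
        model = mx.train_maxent(X_pres, X_bg, ["signal", "noise"], classes="L", rm=1.0)
        # force the noise covariate out of the model: its features carry no weight
        names = model.features.feature_names()
        model.coefficients[names.index("L:noise")] = 0.0
        imp = mx.permutation_importance(model, stack, occ, n_perm=3, seed=1)
        assert imp["noise"] == pytest.approx(0.0, abs=1e-12)
        assert imp["signal"] == pytest.approx(100.0)

    def test_zero_coefficient_model_reports_zeros(self, one_signal_world):
        stack, occ = one_signal_world
        X_pres = mx.covariates_at(occ, stack)
        model = mx.train_maxent(X_pres, stack.to_matrix(), ["signal", "noise"],
                                classes="L", rm=1e9)
        imp = mx.permutation_importance(model, stack, occ, n_perm=2, seed=2)
        assert imp == {"signal": 0.0, "noise": 0.0}
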