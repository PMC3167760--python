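"""Cascade-forward nets, SCG training, bagged ensembles, cross-validation."""

import numpy as np
import pytest

import glaufuse as gf
from glaufuse.ann import (
    BaggedCascadeEnsemble,
    CascadeForwardNet,
    TrainConfig,
    member_bootstrap_indices,
    scg_train,
    stratified_subsets,
)


def _finite_difference_grad(net, X, y, eps=1e-6):
    w0 = net.get_flat()
    grad = np.empty_like(w0)
    for i in range(w0.size):
        wp, wm = w0.copy(), w0.copy()
        wp[i] += eps
        wm[i] -= eps
        net.set_flat(wp)
        lp = net.loss(X, y)
        net.set_flat(wm)
        lm = net.loss(X, y)
        grad[i] = (lp - lm) / (2 * eps)
    net.set_flat(w0)
    return grad


class TestForwardAndGradient:
    def test_same_seed_same_weights_different_seed_different(self):
        a = gf.init_mlp(5, 4, 3, seed=7)
        b = gf.init_mlp(5, 4, 3, seed=7)
        c = gf.init_mlp(5, 4, 3, seed=8)
        assert np.array_equal(a.get_flat(), b.get_flat())
        assert not np.array_equal(a.get_flat(), c.get_flat())

    def test_zero_weights_output_half(self, rng):
        net = CascadeForwardNet(6, 4, 3)
        for x in rng.normal(size=(5, 6)):
            assert net.forward(x)[0] == pytest.approx(0.5)

    def test_output_strictly_in_unit_interval(self, rng):
        net = gf.init_mlp(8, 5, 3, seed=1)
        net.set_flat(net.get_flat() * 20.0)  # extreme weights
        out = net.forward(rng.normal(size=(1000, 8)) * 10.0)
        assert np.all(out > 0.0) and np.all(out < 1.0)

    def test_dimension_mismatch_raises(self):
        net = gf.init_mlp(4, 3, 2, seed=0)
        with pytest.raises(ValueError, match="features"):
            net.forward(np.zeros((2, 5)))

    def test_backprop_matches_central_finite_differences(self, rng):
        """Analytic gradient on a 3-4-3-1 cascade net vs central differences,
        1e-6 relative."""
        net = gf.init_mlp(3, 4, 3, seed=3)
        X = rng.normal(size=(12, 3))
        y = rng.integers(0, 2, size=12).astype(float)
        _, grad = net.loss_and_grad(X, y)
        fd = _finite_difference_grad(net, X, y)
        denom = np.maximum(np.abs(fd), 1e-8)
        assert np.max(np.abs(grad - fd) / denom) < 1e-6


class TestSCG:
    def test_zero_epochs_is_noop(self, rng):
        net = gf.init_mlp(4, 3, 2, seed=5)
        before = net.get_flat()
        scg_train(net, rng.normal(size=(10, 4)), rng.integers(0, 2, 10), max_epochs=0)
        assert np.array_equal(net.get_flat(), before)

    def test_accepted_step_errors_never_increase(self, rng):
        net = gf.init_mlp(6, 5, 3, seed=2)
        X = rng.normal(size=(40, 6))
        y = (X[:, 0] + X[:, 1] > 0).astype(float)
        hist = scg_train(net, X, y, max_epochs=200)
        errs = hist["train_error"]
        assert len(errs) > 5
        assert all(b <= a + 1e-15 for a, b in zip(errs, errs[1:]))

    def test_reaches_least_squares_optimum_on_convex_surrogate(self, rng):
        """On a linear-model MSE surface (convex quadratic), SCG reaches the
        closed-form least-squares optimum error to within 1e-6."""
        X = rng.normal(size=(60, 5))
        y = X @ np.array([1.0, -2.0, 0.5, 0.0, 3.0]) + 0.3 + rng.normal(0, 0.2, 60)
        surrogate = QuadraticSurrogate(X, y)
        scg_train(surrogate, X, y, max_epochs=500)
        Xb = np.column_stack([X, np.ones(len(y))])
        w_star, *_ = np.linalg.lstsq(Xb, y, rcond=None)
        best = float(np.mean((Xb @ w_star - y) ** 2))
        assert surrogate.loss(X, y) - best < 1e-6

    def test_logistic_representable_targets_driven_to_zero_error(self, rng):
        X = rng.normal(size=(60, 4))
        w_true = np.array([1.0, -2.0, 0.5, 0.0])
        y = 1.0 / (1.0 + np.exp(-(X @ w_true - 0.3)))
        net = gf.init_mlp(4, 3, 2, seed=9)
        scg_train(net, X, y, max_epochs=3000)
        assert net.loss(X, y) < 1e-6  # representable exactly: optimum MSE is 0

    def test_xor_is_learned(self):
        X = np.array([[0.0, 0], [0, 1], [1, 0], [1, 1]])
        y = np.array([0.0, 1, 1, 0])
        net = gf.init_mlp(2, 4, 4, seed=11)
        scg_train(net, X, y, max_epochs=2000)
        assert net.loss(X, y) < 0.05

    def test_early_stopping_restores_best_weights(self, rng):
        X = rng.normal(size=(60, 5))
        y = rng.integers(0, 2, 60).astype(float)  # pure noise: stop error rises
        sx = rng.normal(size=(30, 5))
        sy = rng.integers(0, 2, 30).astype(float)
        net = gf.init_mlp(5, 6, 4, seed=4)
        hist = scg_train(net, X, y, sx, sy, max_epochs=300, patience=5)
        final_stop = net.loss(sx, sy)
        assert final_stop == pytest.approx(hist["best_stop_error"])
        assert final_stop <= hist["stop_error"][-1] + 1e-12

    def test_nan_inputs_abort_with_diagnostic(self, rng):
        net = gf.init_mlp(3, 3, 2, seed=0)
        X = rng.normal(size=(10, 3))
        X[0, 0] = np.nan
        with pytest.raises(FloatingPointError, match="non-finite"):
            scg_train(net, X, np.zeros(10), max_epochs=10)


class QuadraticSurrogate:
    """Linear least-squares problem wearing the net's training interface.

    Lets the SCG routine be exercised on an exactly convex surface whose
    optimum has a closed form (the normal equations).
    """

    def __init__(self, X, y):
        self._X = np.column_stack([X, np.ones(len(y))])
        self._y = np.asarray(y, float)
        self._w = np.zeros(self._X.shape[1])

    def get_flat(self):
        return self._w.copy()

    def set_flat(self, w):
        self._w = np.asarray(w, float).copy()

    def loss(self, X, y):
        return float(np.mean((self._X @ self._w - self._y) ** 2))

    def loss_and_grad(self, X, y):
        r = self._X @ self._w - self._y
        return float(np.mean(r ** 2)), (2.0 / len(r)) * (self._X.T @ r)


def _gaussian_blobs(n=200, sep=4.0, dim=6, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, dim))
    y = np.repeat([0, 1], n // 2)
    X[y == 1, 0] += sep
    return X, y


@pytest.fixture(scope="module")
def fitted():
    X, y = _gaussian_blobs()
    ens = BaggedCascadeEnsemble(
        n_members=10, hidden1=4, hidden2=3, max_epochs=60, random_state=3
    ).fit(X, y)
    return ens, X, y


class TestEnsemble:
    def test_member_count_and_round_robin_stop_subsets(self, fitted):
        ens, _, _ = fitted
        assert len(ens.members_) == 10
        assert ens.stop_subset_of_member_ == [m % 9 for m in range(10)]

    def test_every_subset_used_at_least_floor_times_at_full_size(self):
        stops = [m % 9 for m in range(35)]
        assert all(stops.count(j) >= 35 // 9 for j in range(9))

    def test_prediction_is_mean_of_member_outputs(self, fitted):
        ens, X, _ = fitted
        agg = ens.decision_scores(X[:7])
        members = ens.member_scores(X[:7])
        assert np.allclose(agg, members.mean(axis=0))
        assert np.all((agg > 0) & (agg < 1))

    def test_bootstrap_reproducible_from_seed_and_member(self, fitted):
        ens, X, y = fitted
        y_arr = np.asarray(y)
        subsets = stratified_subsets(y_arr, 9, 3)
        for m in (0, 4, 9):
            pool = np.concatenate([s for j, s in enumerate(subsets) if j != m % 9])
            again = member_bootstrap_indices(3, m, pool)
            assert np.array_equal(again, ens.bootstrap_indices_[m])

    def test_subset_lacking_a_class_rejected(self):
        X, y = _gaussian_blobs(n=40)
        bad = [np.flatnonzero(y == 0)[:2]] + [np.arange(4 * j, 4 * j + 4) + 10 for j in range(8)]
        with pytest.raises(ValueError, match="lacks"):
            BaggedCascadeEnsemble(n_members=2, max_epochs=5).fit(X, y, subsets=bad)


@pytest.fixture(scope="module")
def cv_result():
    X, y = _gaussian_blobs(n=200, sep=6.0)
    fs = gf.FeatureSet(input_type=gf.InputType.SAP, matrix=X, labels=np.asarray(y))
    cfg = TrainConfig(n_members=5, hidden1=4, hidden2=3, max_epochs=60)
    return gf.crossvalidate(fs, k=10, config=cfg, seed=42), X, y


class TestCrossValidation:
    def test_folds_partition_and_stratify(self, cv_result):
        cv, _, y = cv_result
        assert np.all(cv.fold_of_record >= 0)
        for fold in range(10):
            mask = cv.fold_of_record == fold
            assert abs(mask.sum() - 20) <= 1
            per_class = [np.sum(mask & (np.asarray(y) == c)) for c in (0, 1)]
            assert abs(per_class[0] - per_class[1]) <= 1
        assert not np.any(np.isnan(cv.scores))

    def test_separable_problem_reaches_high_out_of_fold_auroc(self, cv_result):
        cv, _, _ = cv_result
        assert gf.roc(cv.scores, cv.labels).auroc > 0.99

    def test_same_seed_reproduces_partition_and_bootstraps(self, cv_result):
        cv, X, y = cv_result
        fs = gf.FeatureSet(input_type=gf.InputType.SAP, matrix=X, labels=np.asarray(y))
        cfg = TrainConfig(n_members=5, hidden1=4, hidden2=3, max_epochs=60)
        cv2 = gf.crossvalidate(fs, k=10, config=cfg, seed=42)
        assert np.array_equal(cv.fold_of_record, cv2.fold_of_record)
        assert np.array_equal(cv.scores, cv2.scores)
        for f in range(10):
            for m in range(5):
                assert np.array_equal(cv.bootstrap_indices[f][m], cv2.bootstrap_indices[f][m])

    def test_k_below_three_rejected(self, cv_result):
        _, X, y = cv_result
        fs = gf.FeatureSet(input_type=gf.InputType.SAP, matrix=X, labels=np.asarray(y))
        with pytest.raises(ValueError, match="k must be"):
            gf.crossvalidate(fs, k=2)
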