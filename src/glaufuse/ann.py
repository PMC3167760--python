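"""Cascade-forward multilayer perceptrons trained by scaled conjugate
gradient, bagged into an early-stopping ensemble, and evaluated under
stratified k-fold cross-validation.

Architecture
------------
Each network has two hidden tanh layers and one logistic output neuron,
with *cascade* connectivity: every layer receives direct connections from
the input and from all preceding layers, so the forward pass is

    h1  = tanh(W_ih1 x + b1)
    h2  = tanh(W_ih2 x + W_h1h2 h1 + b2)
    out = sigma(W_io x + W_h1o h1 + W_h2o h2 + b3)

The loss is mean squared error on {0, 1} class targets.

Training
--------
Møller's scaled conjugate gradient: a conjugate-gradient method whose step
size comes from a second-order estimate (finite-difference Hessian-vector
product along the search direction) stabilised by Levenberg-Marquardt
style scaling of a damping parameter lambda; no user learning rate.  One
SCG iteration is one epoch.  Training stops at ``max_epochs`` or when the
early-stopping set error has not improved for ``patience`` accepted steps;
the weights with the best stopping-set error are returned.

Ensemble
--------
35 members by default.  Member ``m`` reserves stratified training subset
``m mod 9`` for early stopping and trains on an independent bootstrap
resample of the union of the other 8 subsets (bagging).  The ensemble
output is the unweighted mean of the member outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .features import FeatureSet, VarianceRetainedPCA

__all__ = [
    "CascadeForwardNet",
    "init_mlp",
    "forward",
    "scg_train",
    "CascadeForwardClassifier",
    "BaggedCascadeEnsemble",
    "TrainConfig",
    "CVResult",
    "train_ensemble",
    "crossvalidate",
]


_UNIT_LO = np.nextafter(0.0, 1.0)
_UNIT_HI = np.nextafter(1.0, 0.0)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    # keep the output strictly inside (0, 1) even when saturated
    return np.clip(out, _UNIT_LO, _UNIT_HI)


class CascadeForwardNet:
    """Weights and differentiable forward pass of one cascade-forward MLP."""

    _BLOCKS = ("W_ih1", "b1", "W_ih2", "W_h1h2", "b2", "W_io", "W_h1o", "W_h2o", "b3")

    def __init__(self, n_in: int, h1: int, h2: int):
        if min(n_in, h1, h2) < 1:
            raise ValueError("layer sizes must be >= 1")
        self.n_in, self.h1, self.h2 = n_in, h1, h2
        self.shapes = {
            "W_ih1": (h1, n_in), "b1": (h1,),
            "W_ih2": (h2, n_in), "W_h1h2": (h2, h1), "b2": (h2,),
            "W_io": (1, n_in), "W_h1o": (1, h1), "W_h2o": (1, h2), "b3": (1,),
        }
        self.weights = {k: np.zeros(s) for k, s in self.shapes.items()}

    @property
    def n_weights(self) -> int:
        return sum(int(np.prod(s)) for s in self.shapes.values())

    def get_flat(self) -> np.ndarray:
        return np.concatenate([self.weights[k].ravel() for k in self._BLOCKS])

    def set_flat(self, w: np.ndarray) -> None:
        i = 0
        for k in self._BLOCKS:
            size = int(np.prod(self.shapes[k]))
            self.weights[k] = w[i : i + size].reshape(self.shapes[k]).copy()
            i += size
        if i != w.size:
            raise ValueError("flat weight vector has wrong length")

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Network output in (0, 1) for each row of X."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_in:
            raise ValueError(f"expected {self.n_in} input features, got {X.shape[1]}")
        w = self.weights
        h1 = np.tanh(X @ w["W_ih1"].T + w["b1"])
        h2 = np.tanh(X @ w["W_ih2"].T + h1 @ w["W_h1h2"].T + w["b2"])
        z3 = X @ w["W_io"].T + h1 @ w["W_h1o"].T + h2 @ w["W_h2o"].T + w["b3"]
        return _sigmoid(z3).ravel()

    def loss(self, X: np.ndarray, y: np.ndarray) -> float:
        out = self.forward(X)
        return float(np.mean((out - y) ** 2))

    def loss_and_grad(self, X: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
        """Mean-squared-error loss and its gradient w.r.t. the flat weights."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        n = X.shape[0]
        w = self.weights
        h1 = np.tanh(X @ w["W_ih1"].T + w["b1"])
        h2 = np.tanh(X @ w["W_ih2"].T + h1 @ w["W_h1h2"].T + w["b2"])
        z3 = (X @ w["W_io"].T + h1 @ w["W_h1o"].T + h2 @ w["W_h2o"].T + w["b3"]).ravel()
        out = _sigmoid(z3)
        loss = float(np.mean((out - y) ** 2))

        dz3 = (2.0 / n) * (out - y) * out * (1.0 - out)  # (n,)
        dz3c = dz3[:, None]
        g = {
            "W_io": dz3c.T @ X, "W_h1o": dz3c.T @ h1, "W_h2o": dz3c.T @ h2,
            "b3": np.array([dz3.sum()]),
        }
        dh2 = dz3c @ w["W_h2o"]            # (n, h2)
        dz2 = dh2 * (1.0 - h2 ** 2)
        g["W_ih2"] = dz2.T @ X
        g["W_h1h2"] = dz2.T @ h1
        g["b2"] = dz2.sum(axis=0)
        dh1 = dz3c @ w["W_h1o"] + dz2 @ w["W_h1h2"]
        dz1 = dh1 * (1.0 - h1 ** 2)
        g["W_ih1"] = dz1.T @ X
        g["b1"] = dz1.sum(axis=0)
        grad = np.concatenate([g[k].ravel() for k in self._BLOCKS])
        return loss, grad

    def copy(self) -> "CascadeForwardNet":
        net = CascadeForwardNet(self.n_in, self.h1, self.h2)
        net.set_flat(self.get_flat())
        return net


def init_mlp(n_in: int, h1: int, h2: int, seed: int | np.random.SeedSequence) -> CascadeForwardNet:
    """Seeded symmetric uniform initialization scaled by fan-in.

    Each weight block is drawn U(-1/sqrt(fan_in), +1/sqrt(fan_in)) where
    fan_in is the total number of incoming connections of the receiving
    layer (inputs plus all cascaded layers); biases start at 0.
    """
    net = CascadeForwardNet(n_in, h1, h2)
    rng = np.random.default_rng(seed)
    fan_in = {"h1": n_in, "h2": n_in + h1, "out": n_in + h1 + h2}
    layer_of = {
        "W_ih1": "h1", "W_ih2": "h2", "W_h1h2": "h2",
        "W_io": "out", "W_h1o": "out", "W_h2o": "out",
    }
    for name, layer in layer_of.items():
        lim = 1.0 / np.sqrt(fan_in[layer])
        net.weights[name] = rng.uniform(-lim, lim, size=net.shapes[name])
    return net


def forward(net: CascadeForwardNet, x: Sequence[float]) -> np.ndarray:
    """Functional alias for :meth:`CascadeForwardNet.forward`."""
    return net.forward(np.asarray(x, dtype=float))


def scg_train(
    net: CascadeForwardNet,
    train_x: np.ndarray,
    train_y: np.ndarray,
    stop_x: np.ndarray | None = None,
    stop_y: np.ndarray | None = None,
    max_epochs: int = 500,
    patience: int = 10,
    grad_tol: float = 1e-8,
) -> dict:
    """Train ``net`` in place by Møller's scaled conjugate gradient.

    When a stopping set is given, training halts once its error has not
    improved for ``patience`` consecutive accepted steps and the weights
    with the best stopping-set error are restored.  Returns a history dict
    with the accepted-step training errors (non-increasing by construction)
    and the stopping-set error trace.
    """
    X = np.atleast_2d(np.asarray(train_x, dtype=float))
    y = np.asarray(train_y, dtype=float).ravel()
    if X.shape[0] == 0:
        raise ValueError("empty training set")
    use_stop = stop_x is not None and stop_y is not None
    if use_stop:
        stop_x = np.atleast_2d(np.asarray(stop_x, dtype=float))
        stop_y = np.asarray(stop_y, dtype=float).ravel()
        if stop_x.shape[0] == 0:
            raise ValueError("empty stopping set")

    history: dict = {"train_error": [], "stop_error": [], "epochs": 0}
    if max_epochs == 0:
        return history

    sigma0 = 1.0e-5
    lamb, lamb_bar = 1.0e-6, 0.0
    w = net.get_flat()
    E_w, grad = net.loss_and_grad(X, y)
    r = -grad
    p = r.copy()
    success = True
    N = w.size
    k = 0

    best_stop = np.inf
    best_w = w.copy()
    wait = 0
    delta = p2 = 1.0  # defined on first pass (success=True)

    def _check(value: float) -> float:
        if not np.isfinite(value):
            raise FloatingPointError("SCG: training error became non-finite")
        return value

    for epoch in range(max_epochs):
        if success:
            p2 = float(p @ p)
            if p2 <= grad_tol ** 2:
                break
            sigma = sigma0 / np.sqrt(p2)
            net.set_flat(w + sigma * p)
            _, grad_sigma = net.loss_and_grad(X, y)
            s = (grad_sigma - grad) / sigma
            delta = float(p @ s)
        delta += (lamb - lamb_bar) * p2
        if delta <= 0:  # make the Hessian estimate positive definite
            lamb_bar = 2.0 * (lamb - delta / p2)
            delta = -delta + lamb * p2
            lamb = lamb_bar
        mu = float(p @ r)
        if mu == 0.0:  # search direction orthogonal to the gradient: converged
            break
        alpha = mu / delta
        net.set_flat(w + alpha * p)
        E_new = _check(net.loss(X, y))
        Delta = 2.0 * delta * (E_w - E_new) / mu ** 2  # comparison parameter

        if Delta >= 0:  # accept the step
            w = w + alpha * p
            E_w = E_new
            net.set_flat(w)
            _, grad = net.loss_and_grad(X, y)
            r_new = -grad
            lamb_bar = 0.0
            success = True
            k += 1
            if k % N == 0:  # restart with steepest descent
                p = r_new.copy()
            else:
                beta = float(r_new @ r_new - r_new @ r) / mu
                p = r_new + beta * p
            r = r_new
            if Delta >= 0.75:
                lamb *= 0.25
            history["train_error"].append(E_w)
            if use_stop:
                stop_err = _check(net.loss(stop_x, stop_y))
                history["stop_error"].append(stop_err)
                if stop_err < best_stop:
                    best_stop, best_w, wait = stop_err, w.copy(), 0
                else:
                    wait += 1
                    if wait >= patience:
                        history["epochs"] = epoch + 1
                        break
        else:
            lamb_bar = lamb
            success = False
        if Delta < 0.25:
            lamb += delta * (1.0 - Delta) / p2
        lamb = min(lamb, 1.0e20)
        history["epochs"] = epoch + 1

    if use_stop and np.isfinite(best_stop):
        net.set_flat(best_w)
        history["best_stop_error"] = best_stop
    else:
        net.set_flat(w)
    return history


class CascadeForwardClassifier(ClassifierMixin, BaseEstimator):
    """Binary classifier backed by one SCG-trained cascade-forward MLP.

    Parameters follow the scikit-learn convention; ``fit`` accepts an
    optional early-stopping set via ``stop_X`` / ``stop_y``.
    """

    def __init__(
        self,
        hidden1: int = 10,
        hidden2: int = 5,
        max_epochs: int = 500,
        patience: int = 10,
        normalize: bool = True,
        random_state: int | None = None,
    ):
        self.hidden1 = hidden1
        self.hidden2 = hidden2
        self.max_epochs = max_epochs
        self.patience = patience
        self.normalize = normalize
        self.random_state = random_state

    def _scale(self, X: np.ndarray) -> np.ndarray:
        return (X - self.input_mean_) / self.input_scale_

    def fit(self, X, y, stop_X=None, stop_y=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("CascadeForwardClassifier is strictly binary")
        # per-feature standardization from the training data keeps the tanh
        # layers out of saturation whatever the input units (scores vs µm)
        if self.normalize:
            self.input_mean_ = X.mean(axis=0)
            sd = X.std(axis=0)
            self.input_scale_ = np.where(sd > 0, sd, 1.0)
        else:
            self.input_mean_ = np.zeros(X.shape[1])
            self.input_scale_ = np.ones(X.shape[1])
        Xs = self._scale(X)
        yb = (y == self.classes_[1]).astype(float)
        stop_Xs = stop_yb = None
        if stop_X is not None and stop_y is not None:
            stop_Xs = self._scale(np.asarray(stop_X, dtype=float))
            stop_yb = (np.asarray(stop_y) == self.classes_[1]).astype(float)
        seed = self.random_state if self.random_state is not None else 0
        self.net_ = init_mlp(X.shape[1], self.hidden1, self.hidden2, seed)
        self.history_ = scg_train(
            self.net_, Xs, yb, stop_Xs, stop_yb,
            max_epochs=self.max_epochs, patience=self.patience,
        )
        self.n_features_in_ = X.shape[1]
        return self

    def decision_scores(self, X) -> np.ndarray:
        check_is_fitted(self, "net_")
        return self.net_.forward(self._scale(np.asarray(X, dtype=float)))

    def predict_proba(self, X):
        p = self.decision_scores(X)
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        return self.classes_[(self.decision_scores(X) >= 0.5).astype(int)]


@dataclass(frozen=True)
class TrainConfig:
    """Ensemble and training hyper-parameters.

    ``hidden1``/``hidden2`` of None selects the size rule used throughout:
    10/5 hidden units for score-vector inputs (52+ dims) and 8/4 for
    compact PCA-only inputs (< 52 dims).
    """

    n_members: int = 35
    n_stop_subsets: int = 9
    hidden1: int | None = None
    hidden2: int | None = None
    max_epochs: int = 500
    patience: int = 10

    def hidden_sizes(self, n_features: int) -> tuple[int, int]:
        if self.hidden1 is not None and self.hidden2 is not None:
            return self.hidden1, self.hidden2
        return (8, 4) if n_features < 52 else (10, 5)


class BaggedCascadeEnsemble(ClassifierMixin, BaseEstimator):
    """Bagged ensemble of cascade-forward MLPs with rotating early stopping.

    ``fit`` partitions the training data into ``n_stop_subsets`` stratified
    subsets (or accepts a precomputed partition); member ``m`` reserves
    subset ``m mod n_stop_subsets`` for early stopping and trains on a
    bootstrap resample (with replacement, same size) of the union of the
    remaining subsets.  Prediction is the mean of the member outputs, which
    stays strictly inside (0, 1).
    """

    def __init__(
        self,
        n_members: int = 35,
        n_stop_subsets: int = 9,
        hidden1: int | None = None,
        hidden2: int | None = None,
        max_epochs: int = 500,
        patience: int = 10,
        random_state: int | None = None,
    ):
        self.n_members = n_members
        self.n_stop_subsets = n_stop_subsets
        self.hidden1 = hidden1
        self.hidden2 = hidden2
        self.max_epochs = max_epochs
        self.patience = patience
        self.random_state = random_state

    def _config(self) -> TrainConfig:
        return TrainConfig(
            n_members=self.n_members,
            n_stop_subsets=self.n_stop_subsets,
            hidden1=self.hidden1,
            hidden2=self.hidden2,
            max_epochs=self.max_epochs,
            patience=self.patience,
        )

    def fit(self, X, y, subsets: list[np.ndarray] | None = None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("ensemble is strictly binary")
        seed = self.random_state if self.random_state is not None else 0
        if subsets is None:
            subsets = stratified_subsets(y, self.n_stop_subsets, seed)
        if len(subsets) != self.n_stop_subsets:
            raise ValueError(f"expected {self.n_stop_subsets} training subsets")
        for i, idx in enumerate(subsets):
            if len(np.unique(y[idx])) != 2:
                raise ValueError(f"training subset {i} lacks one class")

        cfg = self._config()
        h1, h2 = cfg.hidden_sizes(X.shape[1])
        self.members_: list[CascadeForwardClassifier] = []
        self.stop_subset_of_member_: list[int] = []
        self.bootstrap_indices_: list[np.ndarray] = []
        for m in range(self.n_members):
            stop_id = m % self.n_stop_subsets
            pool = np.concatenate([s for j, s in enumerate(subsets) if j != stop_id])
            boot = member_bootstrap_indices(seed, m, pool)
            member = CascadeForwardClassifier(
                hidden1=h1, hidden2=h2,
                max_epochs=self.max_epochs, patience=self.patience,
                random_state=_member_seed(seed, m),
            )
            member.fit(X[boot], y[boot], stop_X=X[subsets[stop_id]], stop_y=y[subsets[stop_id]])
            self.members_.append(member)
            self.stop_subset_of_member_.append(stop_id)
            self.bootstrap_indices_.append(boot)
        self.n_features_in_ = X.shape[1]
        return self

    def decision_scores(self, X) -> np.ndarray:
        check_is_fitted(self, "members_")
        return np.mean([m.decision_scores(X) for m in self.members_], axis=0)

    def member_scores(self, X) -> np.ndarray:
        check_is_fitted(self, "members_")
        return np.array([m.decision_scores(X) for m in self.members_])

    def predict_proba(self, X):
        p = self.decision_scores(X)
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        return self.classes_[(self.decision_scores(X) >= 0.5).astype(int)]


def _member_seed(seed: int, member: int) -> int:
    """Deterministic per-member seed below 2**31."""
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, member, 0x5CA1AB1E])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def member_bootstrap_indices(seed: int, member: int, pool: np.ndarray) -> np.ndarray:
    """Bootstrap resample of ``pool`` for one member, reproducible from (seed, member)."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, member, 0xB007]))
    return pool[rng.integers(0, len(pool), size=len(pool))]


def stratified_subsets(y: np.ndarray, n_subsets: int, seed: int) -> list[np.ndarray]:
    """Partition indices into class-stratified subsets (sizes differ by <= 1 per class)."""
    skf = StratifiedKFold(n_splits=n_subsets, shuffle=True, random_state=int(seed) & 0x7FFFFFFF)
    return [test for _, test in skf.split(np.zeros((len(y), 1)), y)]


def train_ensemble(
    X: np.ndarray,
    y: np.ndarray,
    subsets: list[np.ndarray],
    config: TrainConfig = TrainConfig(),
    seed: int = 0,
) -> BaggedCascadeEnsemble:
    """Train one ensemble from explicit stratified training subsets."""
    ens = BaggedCascadeEnsemble(
        n_members=config.n_members,
        n_stop_subsets=config.n_stop_subsets,
        hidden1=config.hidden1,
        hidden2=config.hidden2,
        max_epochs=config.max_epochs,
        patience=config.patience,
        random_state=seed,
    )
    return ens.fit(X, y, subsets=subsets)


@dataclass
class CVResult:
    """Out-of-fold ensemble outputs from stratified k-fold cross-validation."""

    fold_of_record: np.ndarray     # (n,) test-fold id per record
    scores: np.ndarray             # (n,) out-of-fold ensemble output in (0, 1)
    labels: np.ndarray             # (n,)
    input_type: str
    bootstrap_indices: list[list[np.ndarray]]  # per fold, per member
    fold_logs: list[dict] = field(default_factory=list)


def crossvalidate(
    featureset: FeatureSet,
    k: int = 10,
    config: TrainConfig = TrainConfig(),
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold cross-validation of the bagged ensemble.

    For every fold the remaining records are split into the ensemble's
    stratified training subsets; when the feature set defers PCA
    (train-fold policy), the projection is fitted on the training records
    of that fold only and applied to the held-out fold.
    """
    if k < 3:
        raise ValueError("k must be >= 3")
    X_full = featureset.matrix
    y = featureset.labels
    if len(np.unique(y)) != 2:
        raise ValueError("both classes must be present")
    seed = int(seed) & 0x7FFFFFFF

    fold_of = np.full(len(y), -1, dtype=int)
    scores = np.full(len(y), np.nan)
    boot_all: list[list[np.ndarray]] = []
    logs: list[dict] = []

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for fold, (train_idx, test_idx) in enumerate(skf.split(np.zeros((len(y), 1)), y)):
        fold_of[test_idx] = fold
        if featureset.pca_block is not None:
            lo, hi, thr = featureset.pca_block
            pca = VarianceRetainedPCA(thr).fit(X_full[train_idx, lo:hi])
            X = np.hstack([X_full[:, :lo], pca.transform(X_full[:, lo:hi])])
            n_comp = pca.n_components_
        else:
            X, n_comp = X_full, None

        subset_seed = _member_seed(seed, 10_000 + fold)
        local = stratified_subsets(y[train_idx], config.n_stop_subsets, subset_seed)
        subsets = [train_idx[s] for s in local]
        ens = train_ensemble(X, y, subsets, config=config, seed=_member_seed(seed, fold))
        scores[test_idx] = ens.decision_scores(X[test_idx])
        boot_all.append(list(ens.bootstrap_indices_))
        logs.append(
            {
                "fold": fold,
                "n_train": len(train_idx),
                "n_test": len(test_idx),
                "n_pca_components": n_comp,
                "member_epochs": [m.history_["epochs"] for m in ens.members_],
            }
        )

    return CVResult(
        fold_of_record=fold_of,
        scores=scores,
        labels=y.copy(),
        input_type=featureset.input_type.value,
        bootstrap_indices=boot_all,
        fold_logs=logs,
    )
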