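"""The MSM classifier and its cross-validation harness.

The classifier is a four-layer fully connected network: an input layer and
two hidden layers with output dimensions 100 and 50, all using CReLU
(concatenated rectified linear units) activation, and a 2-way softmax
output. CReLU(x) = concat(max(x, 0), max(-x, 0)) doubles the width of
whatever it is applied to, so the effective widths are
d -> 2d -> (100 -> 200) -> (50 -> 100) -> 2. Overfitting control on small
cohorts: L2 weight decay, a dropout layer (rate 0.4) between the two hidden
layers, and early stopping on a held-out slice of the training data.

Trained by mini-batch Adam on the cross-entropy loss. The implementation
is plain numpy with manual gradients — the network is small enough that a
deep-learning framework would add nothing but a dependency.

``cross_validate`` runs stratified 10-fold CV with, per fold: feature
standardisation fitted on the training portion, SMOTE oversampling of the
training portion only, then training and evaluation on the untouched test
fold. ``comparators`` runs the identical harness with L2 logistic
regression and an RBF SVM.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, f1_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .resampling import SMOTE

__all__ = ["MSMClassifier", "CVResult", "cross_validate", "comparators"]


def _crelu(z: np.ndarray) -> np.ndarray:
    return np.concatenate([np.maximum(z, 0.0), np.maximum(-z, 0.0)], axis=1)


def _crelu_backward(z: np.ndarray, grad: np.ndarray) -> np.ndarray:
    d = z.shape[1]
    return grad[:, :d] * (z > 0) - grad[:, d:] * (z < 0)


class MSMClassifier(BaseEstimator, ClassifierMixin):
    """Feedforward CReLU network for binary mental-health prediction.

    Parameters
    ----------
    hidden_dims : tuple of int, default (100, 50)
        Output dimensions of the two hidden linear layers (before the
        CReLU doubling).
    dropout_rate : float, default 0.4
        Dropout between the two hidden layers (training only).
    l2_lambda : float, default 1e-4
        L2 penalty on all weight matrices.
    learning_rate, batch_size, max_epochs : Adam optimisation settings.
    early_stop_patience : int, default 20
        Epochs without validation-loss improvement before stopping; the
        best weights seen are restored.
    validation_fraction : float, default 0.1
        Slice of the training data held out for early stopping.
    seed : int, default 0
        Controls initialisation, batching, dropout masks and the
        validation split.
    """

    def __init__(
        self,
        hidden_dims: tuple[int, int] = (100, 50),
        dropout_rate: float = 0.4,
        l2_lambda: float = 1e-4,
        learning_rate: float = 1e-3,
        batch_size: int = 16,
        max_epochs: int = 500,
        early_stop_patience: int = 20,
        validation_fraction: float = 0.1,
        seed: int = 0,
    ):
        self.hidden_dims = hidden_dims
        self.dropout_rate = dropout_rate
        self.l2_lambda = l2_lambda
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.early_stop_patience = early_stop_patience
        self.validation_fraction = validation_fraction
        self.seed = seed

    # -- network plumbing ---------------------------------------------------

    def _init_weights(self, rng: np.random.Generator, d_in: int) -> list:
        h1, h2 = self.hidden_dims
        dims = [(2 * d_in, h1), (2 * h1, h2), (2 * h2, 2)]
        params = []
        for fan_in, fan_out in dims:
            scale = np.sqrt(2.0 / fan_in)
            params.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            params.append(np.zeros(fan_out))
        return params

    def _forward(
        self,
        X: np.ndarray,
        params: list,
        rng: np.random.Generator | None = None,
    ):
        """Forward pass; with *rng* dropout is active (training mode)."""
        W1, b1, W2, b2, W3, b3 = params
        a0 = _crelu(X)
        z1 = a0 @ W1 + b1
        a1 = _crelu(z1)
        if rng is not None and self.dropout_rate > 0:
            keep = 1.0 - self.dropout_rate
            mask = (rng.random(a1.shape) < keep) / keep
            a1d = a1 * mask
        else:
            mask = None
            a1d = a1
        z2 = a1d @ W2 + b2
        a2 = _crelu(z2)
        logits = a2 @ W3 + b3
        return a0, z1, a1d, mask, z2, a2, logits

    @staticmethod
    def _softmax(logits: np.ndarray) -> np.ndarray:
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def _loss(self, probs: np.ndarray, y: np.ndarray, params: list) -> float:
        eps = 1e-12
        nll = -np.mean(np.log(probs[np.arange(len(y)), y] + eps))
        l2 = sum(float(np.sum(W * W)) for W in params[::2])
        return nll + self.l2_lambda * l2

    # -- estimator interface ------------------------------------------------

    def fit(self, X, y) -> "MSMClassifier":
        X, y = check_X_y(X, y)
        X = X.astype(np.float64)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("training data contains a single class")
        if len(self.classes_) > 2:
            raise ValueError("binary classification only")
        self.n_features_in_ = X.shape[1]

        rng = np.random.default_rng(self.seed)
        # held-out slice for early stopping (stratified when possible)
        n_val = int(np.ceil(self.validation_fraction * len(X)))
        strat = (
            y_idx
            if n_val >= 2 and np.min(np.bincount(y_idx)) >= 2
            else None
        )
        if self.validation_fraction > 0 and len(X) >= 10:
            X_tr, X_val, y_tr, y_val = train_test_split(
                X,
                y_idx,
                test_size=self.validation_fraction,
                random_state=int(rng.integers(2**31)),
                stratify=strat,
            )
        else:
            X_tr, y_tr = X, y_idx
            X_val, y_val = X, y_idx

        params = self._init_weights(rng, X.shape[1])
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0

        best_loss = np.inf
        best_params = [p.copy() for p in params]
        patience_left = self.early_stop_patience

        n = len(X_tr)
        for _epoch in range(self.max_epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                Xb, yb = X_tr[idx], y_tr[idx]
                grads = self._gradients(Xb, yb, params, rng)
                step += 1
                for i, g in enumerate(grads):
                    m[i] = beta1 * m[i] + (1 - beta1) * g
                    v[i] = beta2 * v[i] + (1 - beta2) * g * g
                    m_hat = m[i] / (1 - beta1**step)
                    v_hat = v[i] / (1 - beta2**step)
                    params[i] -= self.learning_rate * m_hat / (np.sqrt(v_hat) + eps)

            *_, logits = self._forward(X_val, params)
            val_loss = self._loss(self._softmax(logits), y_val, params)
            if val_loss < best_loss - 1e-6:
                best_loss = val_loss
                best_params = [p.copy() for p in params]
                patience_left = self.early_stop_patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    break

        self.params_ = best_params
        self.n_epochs_ = _epoch + 1
        self.validation_loss_ = float(best_loss)
        return self

    def _gradients(
        self,
        Xb: np.ndarray,
        yb: np.ndarray,
        params: list,
        rng: np.random.Generator,
    ) -> list:
        W1, b1, W2, b2, W3, b3 = params
        a0, z1, a1d, mask, z2, a2, logits = self._forward(Xb, params, rng)
        probs = self._softmax(logits)
        nb = len(Xb)
        delta = probs
        delta[np.arange(nb), yb] -= 1.0
        delta /= nb

        gW3 = a2.T @ delta + 2 * self.l2_lambda * W3
        gb3 = delta.sum(axis=0)
        d_a2 = delta @ W3.T
        d_z2 = _crelu_backward(z2, d_a2)
        gW2 = a1d.T @ d_z2 + 2 * self.l2_lambda * W2
        gb2 = d_z2.sum(axis=0)
        d_a1 = d_z2 @ W2.T
        if mask is not None:
            d_a1 = d_a1 * mask
        d_z1 = _crelu_backward(z1, d_a1)
        gW1 = a0.T @ d_z1 + 2 * self.l2_lambda * W1
        gb1 = d_z1.sum(axis=0)
        return [gW1, gb1, gW2, gb2, gW3, gb3]

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "params_")
        X = check_array(X).astype(np.float64)
        *_, logits = self._forward(X, self.params_)
        return self._softmax(logits)

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


# --------------------------------------------------------------------------
# Cross-validation harness
# --------------------------------------------------------------------------

@dataclass
class CVResult:
    """Per-fold and aggregate metrics of one cross-validated run."""

    accuracies: list[float]
    f1_scores: list[float]
    fold_test_indices: list[np.ndarray]
    fold_fingerprints: list[str]
    seed: int
    classifier: str

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def mean_f1(self) -> float:
        return float(np.mean(self.f1_scores))


def _fingerprint(indices: np.ndarray) -> str:
    return hashlib.sha256(np.sort(indices).astype(np.int64).tobytes()).hexdigest()


def cross_validate(
    X,
    y,
    estimator: BaseEstimator | None = None,
    *,
    smote: SMOTE | None = None,
    n_folds: int = 10,
    seed: int = 0,
    standardize: bool = True,
    positive_label=True,
) -> CVResult:
    """Stratified k-fold CV with per-fold standardisation and SMOTE.

    The scaler and the oversampler only ever see the training portion of a
    fold; the test fold is evaluated untouched. F1 is reported for the
    *sick* (positive) class. Fold assignments are deterministic for a
    fixed seed and are fingerprinted so leakage checks can assert that
    resampling never alters test-fold membership.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if estimator is None:
        estimator = MSMClassifier(seed=seed)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    accs, f1s, test_sets, prints = [], [], [], []
    for fold, (train_idx, test_idx) in enumerate(skf.split(X, y)):
        X_tr, y_tr = X[train_idx], y[train_idx]
        X_te, y_te = X[test_idx], y[test_idx]
        if standardize:
            scaler = StandardScaler().fit(X_tr)
            X_tr, X_te = scaler.transform(X_tr), scaler.transform(X_te)
        if smote is not None:
            fold_smote = SMOTE(**{**smote.get_params(),
                                  "seed": smote.seed + fold})
            X_tr, y_tr = fold_smote.fit_resample(X_tr, y_tr)
        est = clone(estimator)
        if "seed" in est.get_params():
            est.set_params(seed=seed + fold)
        elif "random_state" in est.get_params():
            est.set_params(random_state=seed + fold)
        est.fit(X_tr, y_tr)
        pred = est.predict(X_te)
        accs.append(float(accuracy_score(y_te, pred)))
        f1s.append(float(f1_score(y_te, pred, pos_label=positive_label,
                                  zero_division=0)))
        test_sets.append(test_idx)
        prints.append(_fingerprint(test_idx))
    return CVResult(
        accuracies=accs,
        f1_scores=f1s,
        fold_test_indices=test_sets,
        fold_fingerprints=prints,
        seed=seed,
        classifier=type(estimator).__name__,
    )


def comparators(
    X,
    y,
    *,
    smote: SMOTE | None = None,
    n_folds: int = 10,
    seed: int = 0,
) -> dict[str, CVResult]:
    """Run the identical CV harness with the three classifiers compared:
    L2 logistic regression, RBF SVM, and the CReLU network."""
    estimators = {
        "logistic_regression": LogisticRegression(max_iter=2000),
        "svm_rbf": SVC(kernel="rbf"),
        "neural_network": MSMClassifier(seed=seed),
    }
    return {
        name: cross_validate(
            X, y, est, smote=smote, n_folds=n_folds, seed=seed
        )
        for name, est in estimators.items()
    }
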