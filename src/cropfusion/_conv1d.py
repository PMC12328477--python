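"""A small 1-D convolutional network classifier in pure NumPy.

Treats each feature vector as a length-L, single-channel sequence: two
valid-mode Conv1D layers (ReLU) followed by a dense softmax layer, trained
with Adam on the cross-entropy loss.  Written against the scikit-learn
estimator protocol (fit / predict / predict_proba) so it can sit inside a
Pipeline next to the other backends.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .errors import ValidationError

__all__ = ["Conv1DClassifier"]


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _conv_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Valid-mode 1-D convolution.

    x: (n, C_in, L); W: (C_out, C_in, k); returns (n, C_out, L - k + 1).
    """
    k = W.shape[2]
    xw = np.lib.stride_tricks.sliding_window_view(x, k, axis=2)  # (n,Cin,P,k)
    return np.einsum("fck,ncpk->nfp", W, xw, optimize=True) + b[None, :, None]


def _conv_backward(
    x: np.ndarray, W: np.ndarray, dz: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of a valid-mode conv: returns (dx, dW, db)."""
    k = W.shape[2]
    xw = np.lib.stride_tricks.sliding_window_view(x, k, axis=2)
    dW = np.einsum("nfp,ncpk->fck", dz, xw, optimize=True)
    db = dz.sum(axis=(0, 2))
    dx = np.zeros_like(x)
    for t in range(k):
        # dz position p consumed x[..., p + t]
        dx[:, :, t:t + dz.shape[2]] += np.einsum(
            "nfp,fc->ncp", dz, W[:, :, t], optimize=True
        )
    return dx, dW, db


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + eps)


class Conv1DClassifier(ClassifierMixin, BaseEstimator):
    """Two Conv1D layers (64 and 128 filters, kernel 3, ReLU) + softmax.

    Inherits the scikit-learn estimator protocol so it can sit inside a
    Pipeline next to the other backends.
    """

    def __init__(
        self,
        filters: tuple[int, int] = (64, 128),
        kernel_size: int = 3,
        learning_rate: float = 0.0005,
        epochs: int = 120,
        batch_size: int = 64,
        random_state: int = 0,
    ):
        self.filters = filters
        self.kernel_size = kernel_size
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.random_state = random_state

    # -- core ----------------------------------------------------------------

    def _forward(self, x: np.ndarray) -> tuple[np.ndarray, tuple]:
        z1 = _conv_forward(x, self.W1_, self.b1_)
        a1 = _relu(z1)
        z2 = _conv_forward(a1, self.W2_, self.b2_)
        a2 = _relu(z2)
        flat = a2.reshape(a2.shape[0], -1)
        logits = flat @ self.W3_ + self.b3_
        return logits, (x, z1, a1, z2, a2, flat)

    def _loss_grads(
        self, x: np.ndarray, onehot: np.ndarray
    ) -> tuple[float, list[np.ndarray]]:
        logits, (x0, z1, a1, z2, a2, flat) = self._forward(x)
        probs = _softmax(logits)
        n = x.shape[0]
        eps = 1e-12
        loss = float(-(onehot * np.log(probs + eps)).sum() / n)
        dlogits = (probs - onehot) / n
        dW3 = flat.T @ dlogits
        db3 = dlogits.sum(axis=0)
        dflat = dlogits @ self.W3_.T
        da2 = dflat.reshape(a2.shape)
        dz2 = da2 * (z2 > 0)
        da1, dW2, db2 = _conv_backward(a1, self.W2_, dz2)
        dz1 = da1 * (z1 > 0)
        _, dW1, db1 = _conv_backward(x0, self.W1_, dz1)
        return loss, [dW1, db1, dW2, db2, dW3, db3]

    def fit(self, X: np.ndarray, y: np.ndarray) -> "Conv1DClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValidationError("X must be a 2-D feature table")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        n_classes = self.classes_.size
        if n_classes < 2:
            raise ValidationError("need at least 2 classes")
        L = X.shape[1]
        k = self.kernel_size
        L1 = L - k + 1
        L2 = L1 - k + 1
        if L2 < 1:
            raise ValidationError(
                f"sequence length {L} too short for two kernel-{k} conv layers"
            )
        rng = np.random.default_rng(self.random_state)
        f1, f2 = self.filters
        he = lambda fan_in, shape: rng.normal(0, np.sqrt(2 / fan_in), shape)  # noqa: E731
        self.W1_ = he(k, (f1, 1, k))
        self.b1_ = np.zeros(f1)
        self.W2_ = he(f1 * k, (f2, f1, k))
        self.b2_ = np.zeros(f2)
        self.W3_ = he(f2 * L2, (f2 * L2, n_classes))
        self.b3_ = np.zeros(n_classes)

        params = [self.W1_, self.b1_, self.W2_, self.b2_, self.W3_, self.b3_]
        opt = _Adam(params, self.learning_rate)
        onehot = np.eye(n_classes)[y_idx]
        xseq = X[:, None, :]
        n = X.shape[0]
        idx = np.arange(n)
        self.loss_curve_ = []
        for _ in range(self.epochs):
            rng.shuffle(idx)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                batch = idx[start:start + self.batch_size]
                loss, grads = self._loss_grads(xseq[batch], onehot[batch])
                opt.step(params, grads)
                epoch_loss += loss * batch.size
            self.loss_curve_.append(epoch_loss / n)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        logits, _ = self._forward(X[:, None, :])
        return _softmax(logits)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def score(self, X: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))
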