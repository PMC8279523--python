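"""Seeded numpy feed-forward regressor used by the deep clock.

A deliberately small engine: fully-connected layers, ELU/ReLU/SELU
activations, inverted dropout on hidden layers, L2 weight decay, MAE loss
minimized by the Adam family (Adam, AMSGrad, Nadam), and exact input
gradients for saliency-based feature selection.  Everything is float64 and
driven by ``numpy.random.Generator`` streams, so a fixed seed reproduces a
run bit-for-bit on the same platform.
"""

from __future__ import annotations

import numpy as np

from ..errors import ConfigurationError, ValidationError

__all__ = ["ACTIVATIONS", "AdamFamily", "MLP", "train_mlp"]

_SELU_LAMBDA = 1.0507009873554805
_SELU_ALPHA = 1.6732632423543772


def _elu(x):
    return np.where(x > 0, x, np.expm1(x))


def _elu_grad(x):
    return np.where(x > 0, 1.0, np.exp(x))


def _relu(x):
    return np.maximum(x, 0.0)


def _relu_grad(x):
    return (x > 0).astype(float)


def _selu(x):
    return _SELU_LAMBDA * np.where(x > 0, x, _SELU_ALPHA * np.expm1(x))


def _selu_grad(x):
    return _SELU_LAMBDA * np.where(x > 0, 1.0, _SELU_ALPHA * np.exp(x))


ACTIVATIONS = {
    "elu": (_elu, _elu_grad),
    "relu": (_relu, _relu_grad),
    "selu": (_selu, _selu_grad),
}


class AdamFamily:
    """Adam / AMSGrad / Nadam updates over a flat list of parameter arrays."""

    def __init__(self, shapes, learning_rate, variant="adam", beta1=0.9, beta2=0.999, eps=1e-8):
        if variant not in {"adam", "amsgrad", "nadam"}:
            raise ConfigurationError(f"unknown optimizer variant {variant!r}")
        if learning_rate <= 0:
            raise ConfigurationError("learning_rate must be positive")
        self.lr = learning_rate
        self.variant = variant
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.vmax = [np.zeros(s) for s in shapes] if variant == "amsgrad" else None

    def step(self, params, grads) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1**self.t
        c2 = 1.0 - b2**self.t
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            m_hat = self.m[i] / c1
            v_hat = self.v[i] / c2
            if self.variant == "amsgrad":
                np.maximum(self.vmax[i], v_hat, out=self.vmax[i])
                v_hat = self.vmax[i]
            if self.variant == "nadam":
                m_hat = b1 * m_hat + (1 - b1) * g / c1
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


class MLP:
    """Fully-connected network: input -> hidden layers -> 1 linear output."""

    def __init__(
        self, layer_sizes, activation="elu", dropout=0.0, l2=0.0, seed=0,
        input_dropout=0.0,
    ):
        if len(layer_sizes) < 2:
            raise ConfigurationError("need at least input and output layer sizes")
        if activation not in ACTIVATIONS:
            raise ConfigurationError(f"unknown activation {activation!r}")
        if not 0.0 <= dropout < 1.0:
            raise ConfigurationError("dropout must lie in [0, 1)")
        if not 0.0 <= input_dropout < 1.0:
            raise ConfigurationError("input_dropout must lie in [0, 1)")
        self.input_dropout = input_dropout
        self.layer_sizes = list(layer_sizes)
        self.activation = activation
        self.dropout = dropout
        self.l2 = l2
        # per-feature input offsets subtracted before the first layer;
        # set from the training data by train_mlp (beta values sit on
        # large per-probe baselines that otherwise ill-condition training)
        self.input_center = np.zeros(layer_sizes[0])
        rng = np.random.default_rng(seed)
        self.W, self.b = [], []
        for fan_in, fan_out in zip(layer_sizes[:-1], layer_sizes[1:]):
            # He-style init for ReLU/ELU, LeCun for SELU (self-normalizing)
            gain = 1.0 if activation == "selu" else 2.0
            self.W.append(rng.normal(0.0, np.sqrt(gain / fan_in), size=(fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))

    # -- parameter plumbing -------------------------------------------------
    @property
    def input_width(self) -> int:
        return self.layer_sizes[0]

    def params(self):
        return self.W + self.b

    def get_state(self):
        return [w.copy() for w in self.W], [b.copy() for b in self.b]

    def set_state(self, state) -> None:
        W, b = state
        self.W = [w.copy() for w in W]
        self.b = [bb.copy() for bb in b]

    # -- forward / backward -------------------------------------------------
    def _forward(self, X, dropout_rng=None):
        """Forward pass keeping caches; dropout active iff a rng is given."""
        act, _ = ACTIVATIONS[self.activation]
        if dropout_rng is not None and self.input_dropout > 0:
            # dropping inputs forces usage to spread across redundant probes,
            # which stabilizes the gradient-saliency ranking
            keep = (dropout_rng.random(X.shape) >= self.input_dropout)
            X = X * keep / (1.0 - self.input_dropout)
        pre, post, masks = [], [X], []
        h = X
        n_hidden = len(self.W) - 1
        for i in range(n_hidden):
            z = h @ self.W[i] + self.b[i]
            h = act(z)
            if dropout_rng is not None and self.dropout > 0:
                mask = (dropout_rng.random(h.shape) >= self.dropout) / (1.0 - self.dropout)
                h = h * mask
            else:
                mask = None
            pre.append(z)
            post.append(h)
            masks.append(mask)
        out = (h @ self.W[-1] + self.b[-1]).ravel()
        return out, (pre, post, masks)

    def predict(self, X) -> np.ndarray:
        """Inference forward pass (dropout disabled)."""
        X = np.asarray(X, dtype=float)
        if not np.all(np.isfinite(X)):
            raise ValidationError("non-finite values in network input")
        if X.shape[1] != self.input_width:
            raise ValidationError(
                f"input width {X.shape[1]} != network input width {self.input_width}"
            )
        return self._forward(X - self.input_center)[0]

    def _backward(self, d_out, caches):
        """Backprop a gradient on the scalar outputs; returns (dW, db, dX)."""
        _, grad = ACTIVATIONS[self.activation]
        pre, post, masks = caches
        dW = [None] * len(self.W)
        db = [None] * len(self.b)
        delta = d_out[:, None]  # (n, 1)
        dW[-1] = post[-1].T @ delta
        db[-1] = delta.sum(axis=0)
        d_h = delta @ self.W[-1].T
        for i in range(len(self.W) - 2, -1, -1):
            if masks[i] is not None:
                d_h = d_h * masks[i]
            d_z = d_h * grad(pre[i])
            dW[i] = post[i].T @ d_z
            db[i] = d_z.sum(axis=0)
            d_h = d_z @ self.W[i].T
        return dW, db, d_h

    def input_gradients(self, X) -> np.ndarray:
        """d(output)/d(input) for every sample; dropout disabled.

        Returns an (n_samples, input_width) array of exact gradients.
        """
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.input_width:
            raise ValidationError(
                f"input width {X.shape[1]} != network input width {self.input_width}"
            )
        out, caches = self._forward(X - self.input_center)
        _, _, dX = self._backward(np.ones_like(out), caches)
        return dX


def train_mlp(
    model: MLP,
    X,
    y,
    epochs: int,
    batch_size: int,
    optimizer: str = "adam",
    learning_rate: float = 1e-4,
    seed: int = 0,
    val_fraction: float = 0.1,
    patience: int = 20,
) -> list[float]:
    """Minimize MAE with minibatch backprop; returns the per-epoch loss trace.

    A ``val_fraction`` seeded holdout drives early stopping (restore-best,
    ``patience`` epochs without improvement); set it to 0 to train for the
    full epoch budget.  L2 decay (``model.l2``) applies to weights only.
    The per-feature training mean is stored as ``model.input_center`` and
    subtracted from every input here and at inference.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if not np.all(np.isfinite(X)):
        raise ValidationError("non-finite values in training inputs")
    if len(y) != X.shape[0]:
        raise ValidationError("X and y disagree on sample count")
    if np.ptp(y) == 0 and len(y) > 1:
        import warnings

        warnings.warn("training target has zero variance", stacklevel=2)
    if epochs == 0:
        return []

    rng = np.random.default_rng(seed)
    dropout_rng = np.random.default_rng(rng.integers(2**31 - 1))
    n = X.shape[0]
    if val_fraction > 0 and n >= 10:
        n_val = max(1, int(round(val_fraction * n)))
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
    else:
        val_idx, tr_idx = np.array([], dtype=int), np.arange(n)

    model.input_center = X[tr_idx].mean(axis=0)
    Xc = X - model.input_center
    opt = AdamFamily([p.shape for p in model.params()], learning_rate, variant=optimizer)
    trace: list[float] = []
    best_val = np.inf
    best_state = None
    stale = 0
    n_tr = len(tr_idx)
    for _ in range(epochs):
        order = rng.permutation(n_tr)
        epoch_abs_err = 0.0
        for start in range(0, n_tr, batch_size):
            idx = tr_idx[order[start : start + batch_size]]
            xb, yb = Xc[idx], y[idx]
            out, caches = model._forward(xb, dropout_rng=dropout_rng)
            resid = out - yb
            epoch_abs_err += np.abs(resid).sum()
            d_out = np.sign(resid) / len(yb)
            dW, db, _ = model._backward(d_out, caches)
            if model.l2 > 0:
                dW = [g + model.l2 * w for g, w in zip(dW, model.W)]
            opt.step(model.W + model.b, dW + db)
        trace.append(epoch_abs_err / n_tr)
        if len(val_idx):
            val_mae = float(np.mean(np.abs(model.predict(X[val_idx]) - y[val_idx])))
            if val_mae < best_val - 1e-12:
                best_val = val_mae
                best_state = model.get_state()
                stale = 0
            else:
                stale += 1
                if stale >= patience:
                    break
    if best_state is not None:
        model.set_state(best_state)
    return trace
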