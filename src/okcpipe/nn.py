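"""A small, fully deterministic numpy convolutional network.

This is the desk-scale trainable classifier of the package: three
3x3-convolution + ReLU + 2x2-max-pool blocks, global average pooling,
one hidden fully connected layer and a 2-unit softmax output, trained
with Adam on the binary cross-entropy of the positive-class
probability (for a 2-unit softmax this equals categorical
cross-entropy).  Everything — initialisation, batch shuffling,
training — is a pure function of the seeds, so two runs with the same
configuration produce bit-identical models.

Images enter as ``(N, H, W, 3)`` float arrays scaled to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EPS = 1e-7  # probability clamp for the loss


def bce_loss(labels: np.ndarray, probs: np.ndarray) -> float:
    """Binary cross-entropy (log loss) of positive-class probabilities.

    ``-(1/N) * sum(y*log(p) + (1-y)*log(1-p))`` with ``p`` clamped to
    ``[EPS, 1-EPS]``; non-negative.
    """
    labels = np.asarray(labels, dtype=np.float64)
    probs = np.asarray(probs, dtype=np.float64)
    if labels.shape != probs.shape:
        raise ValueError(f"shape mismatch: {labels.shape} vs {probs.shape}")
    p = np.clip(probs, EPS, 1.0 - EPS)
    return float(-np.mean(labels * np.log(p) + (1.0 - labels) * np.log(1.0 - p)))


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise normalised exponential; rows sum to 1."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# layer primitives (forward + backward), NHWC layout


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """Extract all kh x kw patches of a padded NHWC tensor.

    Returns ``(N, OH, OW, kh*kw*C)`` for stride 1.
    """
    n, h, w, c = x.shape
    oh, ow = h - kh + 1, w - kw + 1
    s0, s1, s2, s3 = x.strides
    cols = np.lib.stride_tricks.as_strided(
        x, shape=(n, oh, ow, kh, kw, c), strides=(s0, s1, s2, s1, s2, s3)
    )
    return cols.reshape(n, oh, ow, kh * kw * c)


class Conv3x3:
    """3x3 convolution, stride 1, one-pixel zero padding, NHWC."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        fan_in = 9 * in_ch
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(9 * in_ch, out_ch))
        self.b = np.zeros(out_ch)
        self.in_ch = in_ch

    def forward(self, x: np.ndarray) -> np.ndarray:
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        self._cols = _im2col(xp, 3, 3)
        self._in_shape = x.shape
        return self._cols @ self.w + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, oh, ow, _ = grad.shape
        cols2d = self._cols.reshape(-1, self.w.shape[0])
        g2d = grad.reshape(-1, self.w.shape[1])
        self.dw = cols2d.T @ g2d
        self.db = g2d.sum(axis=0)
        # gradient w.r.t. input: scatter the column gradients back
        gcols = (g2d @ self.w.T).reshape(n, oh, ow, 3, 3, self.in_ch)
        h, w = self._in_shape[1:3]
        dxp = np.zeros((n, h + 2, w + 2, self.in_ch))
        for i in range(3):
            for j in range(3):
                dxp[:, i : i + oh, j : j + ow, :] += gcols[:, :, :, i, j, :]
        return dxp[:, 1:-1, 1:-1, :]

    def params(self):
        return [("w", self.w, "dw"), ("b", self.b, "db")]


class ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask

    def params(self):
        return []


class MaxPool2:
    """2x2 max pooling, stride 2; odd trailing rows/cols are dropped."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        xt = x[:, : 2 * h2, : 2 * w2, :].reshape(n, h2, 2, w2, 2, c)
        out = xt.max(axis=(2, 4))
        # ties share the gradient equally (see backward)
        self._mask = xt == out[:, :, None, :, None, :]
        self._x_shape = x.shape
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, h, w, c = self._x_shape
        h2, w2 = h // 2, w // 2
        g = self._mask * grad[:, :, None, :, None, :]
        # normalise ties: distribute equally among tied maxima
        counts = self._mask.sum(axis=(2, 4), keepdims=True)
        g = g / counts
        dx = np.zeros((n, h, w, c))
        dx[:, : 2 * h2, : 2 * w2, :] = g.reshape(n, 2 * h2, 2 * w2, c)
        return dx

    def params(self):
        return []


class GlobalAvgPool:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        return np.broadcast_to(grad[:, None, None, :], self._shape) / (h * w)

    def params(self):
        return []


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dw = self._x.T @ grad
        self.db = grad.sum(axis=0)
        return grad @ self.w.T

    def params(self):
        return [("w", self.w, "dw"), ("b", self.b, "db")]


class Adam:
    """Adam optimiser with the standard bias-corrected moments."""

    def __init__(self, layers, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.layers = layers
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {}
        self.v = {}
        for li, layer in enumerate(layers):
            for name, value, _ in layer.params():
                self.m[(li, name)] = np.zeros_like(value)
                self.v[(li, name)] = np.zeros_like(value)

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for li, layer in enumerate(self.layers):
            for name, value, gname in layer.params():
                g = getattr(layer, gname)
                m = self.m[(li, name)]
                v = self.v[(li, name)]
                m[...] = b1 * m + (1 - b1) * g
                v[...] = b2 * v + (1 - b2) * g * g
                mhat = m / (1 - b1**self.t)
                vhat = v / (1 - b2**self.t)
                value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class TrainingResults:
    """Per-epoch history and the fitted network.

    ``history`` rows carry epoch, train_loss, train_acc and, when a
    validation set was supplied, val_loss and val_acc — the training
    curves one would plot to judge convergence and overfitting.
    """

    model: "SmallCNN"
    history: list[dict] = field(default_factory=list)

    def history_frame(self):
        import pandas as pd

        return pd.DataFrame(self.history)

    def summary(self) -> str:
        lines = ["epoch  train_loss  train_acc  val_loss  val_acc"]
        for row in self.history:
            lines.append(
                "{epoch:>5d}  {train_loss:>10.4f}  {train_acc:>9.4f}  ".format(**row)
                + (
                    "{val_loss:>8.4f}  {val_acc:>7.4f}".format(**row)
                    if "val_loss" in row
                    else "       -        -"
                )
            )
        return "\n".join(lines)


class SmallCNN:
    """Three-block convolutional classifier (~25k parameters).

    Parameters
    ----------
    input_shape
        (H, W, 3) of the images fed to the network.
    filters
        Channel widths of the three conv blocks.
    hidden
        Width of the fully connected hidden layer before the 2-unit
        softmax output.
    seed
        Seeds weight initialisation and the training shuffle.
    """

    def __init__(
        self,
        input_shape: tuple[int, int, int] = (48, 48, 3),
        filters: tuple[int, int, int] = (16, 32, 64),
        hidden: int = 32,
        seed: int = 0,
    ):
        self.input_shape = tuple(input_shape)
        self.seed = seed
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        c_in = input_shape[2]
        layers: list = []
        for f in filters:
            layers += [Conv3x3(c_in, f, rng), ReLU(), MaxPool2()]
            c_in = f
        layers += [GlobalAvgPool(), Dense(c_in, hidden, rng), ReLU(), Dense(hidden, 2, rng)]
        self.layers = layers

    # -- forward/backward ---------------------------------------------------
    def logits(self, x: np.ndarray) -> np.ndarray:
        out = x
        for layer in self.layers:
            out = layer.forward(out)
        return out

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """(N, 2) probabilities, column 1 = positive class."""
        x = self._check_input(x)
        return softmax(self.logits(x))

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 4 or x.shape[1:] != self.input_shape:
            raise ValueError(
                f"expected input of shape (N, {self.input_shape}), got {x.shape}"
            )
        return x

    def _backward_from_logits(self, probs: np.ndarray, y: np.ndarray) -> None:
        n = len(y)
        onehot = np.zeros_like(probs)
        onehot[np.arange(n), y.astype(int)] = 1.0
        grad = (probs - onehot) / n  # d(mean BCE)/d(logits) for 2-unit softmax
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    # -- training -----------------------------------------------------------
    def fit(
        self,
        x: np.ndarray | None = None,
        y: np.ndarray | None = None,
        *,
        epochs: int = 30,
        batch_size: int = 12,
        learning_rate: float = 1e-3,
        validation: tuple[np.ndarray, np.ndarray] | None = None,
        data_fn=None,
    ) -> TrainingResults:
        """Train with Adam on binary cross-entropy; returns history.

        Either pass a fixed ``(x, y)`` or a ``data_fn(epoch) -> (x, y)``
        provider (used for on-the-fly augmentation, where every epoch
        sees fresh draws).  With ``epochs=0`` the model is untouched
        and the history is empty.  Deterministic under the model seed.
        """
        if data_fn is None:
            x = self._check_input(x)
            y = np.asarray(y)
            if len(x) == 0:
                raise ValueError("empty training set")
        opt = Adam(self.layers, lr=learning_rate)
        shuffle_rng = np.random.default_rng(np.random.SeedSequence(self.seed + 1))
        results = TrainingResults(model=self)

        for epoch in range(epochs):
            if data_fn is not None:
                x, y = data_fn(epoch)
                x = self._check_input(x)
                y = np.asarray(y)
                if len(x) == 0:
                    raise ValueError("empty training set")
            order = shuffle_rng.permutation(len(x))
            losses, hits, seen = [], 0, 0
            for start in range(0, len(x), batch_size):
                idx = order[start : start + batch_size]
                xb, yb = x[idx], y[idx]
                probs = softmax(self.logits(xb))
                losses.append(bce_loss(yb, probs[:, 1]) * len(idx))
                hits += int(((probs[:, 1] >= 0.5).astype(int) == yb).sum())
                seen += len(idx)
                self._backward_from_logits(probs, yb)
                opt.step()
            row = {
                "epoch": epoch + 1,
                "train_loss": float(np.sum(losses) / seen),
                "train_acc": hits / seen,
            }
            if validation is not None:
                xv, yv = validation
                pv = self.predict_proba(xv)
                row["val_loss"] = bce_loss(np.asarray(yv), pv[:, 1])
                row["val_acc"] = float(
                    ((pv[:, 1] >= 0.5).astype(int) == np.asarray(yv)).mean()
                )
            results.history.append(row)
        return results

    def n_parameters(self) -> int:
        return sum(p.size for layer in self.layers for _, p, _ in layer.params())
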