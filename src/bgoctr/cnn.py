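"""A small 1-D convolutional network for waveform timestamp regression.

Implemented directly on NumPy (im2col convolutions, max pooling, Adam,
squared-error loss), which keeps training single-threaded and exactly
bit-reproducible from a seed.  The architecture is the five-layer design
used throughout the package: the coincidence pair enters as a 2-channel
sequence, the first convolution spans both channels (a 2x5 kernel, 32
filters), two further 1x3 convolutions (64 filters each) follow, each
convolution is followed by a ReLU and a 1x3 max pooling, then a
256-neuron ReLU layer and a single linear output neuron producing the
time-error estimate t* in ps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .config import TrainSpec

__all__ = ["CnnModel", "train_cnn", "save_model", "load_model"]

_DT = np.float32


class _Conv1d:
    """Valid cross-correlation over the length axis, all input channels."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        fan_in = c_in * k
        # He initialization, fan-in scaled, suited to the ReLU that follows
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(fan_in, c_out)).astype(_DT)
        self.b = np.zeros(c_out, dtype=_DT)
        self.c_in, self.c_out, self.k = c_in, c_out, k

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, L = x.shape
        Lp = L - self.k + 1
        cols = sliding_window_view(x, self.k, axis=2)     # (B, C, L', k)
        cols = np.ascontiguousarray(cols.transpose(0, 2, 1, 3))
        self._cols = cols.reshape(B * Lp, C * self.k)
        self._shape = (B, C, L, Lp)
        y = self._cols @ self.W + self.b                   # (B*L', c_out)
        return y.reshape(B, Lp, self.c_out).transpose(0, 2, 1)

    def backward(self, dy: np.ndarray):
        B, C, L, Lp = self._shape
        dy_mat = dy.transpose(0, 2, 1).reshape(B * Lp, self.c_out)
        self.dW = self._cols.T @ dy_mat
        self.db = dy_mat.sum(axis=0)
        dcols = (dy_mat @ self.W.T).reshape(B, Lp, C, self.k)
        dx = np.zeros((B, C, L), dtype=_DT)
        for off in range(self.k):
            dx[:, :, off:off + Lp] += dcols[:, :, :, off].transpose(0, 2, 1)
        return dx

    @property
    def params(self):
        return [("W", self), ("b", self)]


class _ReLU:
    def forward(self, x):
        self._mask = x > 0
        return np.maximum(x, 0, out=x)  # callers never reuse the input

    def backward(self, dy):
        np.multiply(dy, self._mask, out=dy)
        return dy


class _MaxPool:
    """Non-overlapping max pooling along the length axis (remainder dropped)."""

    def __init__(self, size: int):
        self.size = size

    def forward(self, x):
        B, C, L = x.shape
        Lp = L // self.size
        self._in_len = L
        xr = x[:, :, :Lp * self.size].reshape(B, C, Lp, self.size)
        y = xr.max(axis=3)
        # gradient routing mask; exact ties only occur at zero, where the
        # preceding ReLU's backward pass zeroes the duplicates anyway
        self._eq = xr == y[..., None]
        return y

    def backward(self, dy):
        B, C, Lp = dy.shape
        dx = np.zeros((B, C, self._in_len), dtype=_DT)
        dxr = dx[:, :, :Lp * self.size].reshape(B, C, Lp, self.size)
        np.multiply(dy[..., None], self._eq, out=dxr)
        return dx


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in),
                            size=(n_in, n_out)).astype(_DT)
        self.b = np.zeros(n_out, dtype=_DT)

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.W.T


class _Net:
    def __init__(self, spec: TrainSpec, input_shape: tuple[int, int],
                 rng: np.random.Generator):
        c, L = input_shape
        f1, f2, f3 = spec.conv_filters
        k1, k2, k3 = spec.conv_kernels
        self.conv = [_Conv1d(c, f1, k1, rng),
                     _Conv1d(f1, f2, k2, rng),
                     _Conv1d(f2, f3, k3, rng)]
        self.pool = [_MaxPool(spec.pool_size) for _ in range(3)]
        self.act = [_ReLU() for _ in range(4)]
        for conv in self.conv:
            L = (L - conv.k + 1) // spec.pool_size
            if L < 1:
                raise ValueError("input too short for the conv/pool stack")
        self.flat_dim = L * f3
        self.fc1 = _Dense(self.flat_dim, spec.fc_units, rng)
        self.fc2 = _Dense(spec.fc_units, 1, rng)

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = x.astype(_DT, copy=False)
        for i in range(3):
            h = self.pool[i].forward(self.act[i].forward(self.conv[i].forward(h)))
        B = h.shape[0]
        h = h.reshape(B, self.flat_dim)
        h = self.act[3].forward(self.fc1.forward(h))
        return self.fc2.forward(h)[:, 0]

    def backward(self, dy: np.ndarray):
        g = self.fc2.backward(dy[:, None].astype(_DT))
        g = self.fc1.backward(self.act[3].backward(g))
        # back to the (B, C, L) layout of the last pool output
        g = g.reshape(g.shape[0], self.conv[2].c_out, -1)
        for i in (2, 1, 0):
            g = self.conv[i].backward(self.act[i].backward(self.pool[i].backward(g)))
        return g

    def layers_with_params(self):
        return [*self.conv, self.fc1, self.fc2]

    def get_weights(self):
        return [(lay.W.copy(), lay.b.copy()) for lay in self.layers_with_params()]

    def set_weights(self, weights):
        for lay, (W, b) in zip(self.layers_with_params(), weights):
            lay.W = W.copy()
            lay.b = b.copy()


class _Adam:
    """Adam with bias correction (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, layers):
        self.layers = layers
        self.m = [(np.zeros_like(l.W), np.zeros_like(l.b)) for l in layers]
        self.v = [(np.zeros_like(l.W), np.zeros_like(l.b)) for l in layers]
        self.t = 0

    def step(self, lr: float):
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        corr1 = 1.0 - b1 ** self.t
        corr2 = 1.0 - b2 ** self.t
        for i, lay in enumerate(self.layers):
            for j, (p, g) in enumerate(((lay.W, lay.dW), (lay.b, lay.db))):
                m = self.m[i][j]
                v = self.v[i][j]
                m *= b1
                m += (1 - b1) * g
                v *= b2
                v += (1 - b2) * g * g
                p -= (lr * (m / corr1)
                      / (np.sqrt(v / corr2) + eps)).astype(p.dtype)


@dataclass
class CnnModel:
    """A trained network plus its spec card and training history.

    The network is trained on standardized labels; ``label_mean`` /
    ``label_scale`` (ps) map its raw output back to the time-error scale.
    """

    spec: TrainSpec
    input_shape: tuple[int, int]
    weights: list
    label_mean: float = 0.0
    label_scale: float = 1.0
    history: dict = field(default_factory=dict)
    best_epoch: int = -1

    def predict(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        """t* (ps) for inputs of shape (n, C, L)."""
        x = np.asarray(x)
        if x.ndim != 3 or tuple(x.shape[1:]) != self.input_shape:
            raise ValueError(f"expected inputs of shape (n, {self.input_shape[0]}, "
                             f"{self.input_shape[1]}), got {x.shape}")
        net = _Net(self.spec, self.input_shape, np.random.default_rng(0))
        net.set_weights(self.weights)
        out = np.empty(x.shape[0])
        for i in range(0, x.shape[0], batch_size):
            out[i:i + batch_size] = net.forward(x[i:i + batch_size])
        return self.label_mean + self.label_scale * out


def _mse(pred, y):
    d = pred - y
    return float(np.mean(d * d))


def train_cnn(train_inputs: np.ndarray, train_labels: np.ndarray,
              val_inputs: np.ndarray, val_labels: np.ndarray,
              spec: TrainSpec, seed: int = 0,
              verbose: bool = False) -> CnnModel:
    """Train the regression CNN; the best-validation-loss weights are kept.

    Minibatch SGD with Adam on the squared error, learning rate decayed
    x0.1 at the two scheduled fractions of the epochs.  Labels are
    standardized internally (the network regresses (t_err - mean)/sd of
    the training labels; predictions are mapped back to ps), which keeps
    the output layer at the scale the weight initialization assumes.
    Recorded losses are in ps^2.  Raises on non-finite loss.
    Bit-reproducible from ``seed``.
    """
    errs = spec.validate()
    if errs:
        raise ValueError("; ".join(errs))
    x = np.asarray(train_inputs, dtype=_DT)
    y = np.asarray(train_labels, dtype=np.float64)
    xv = np.asarray(val_inputs, dtype=_DT)
    yv = np.asarray(val_labels, dtype=np.float64)
    if x.ndim != 3:
        raise ValueError("train_inputs must be (n, channels, length)")
    label_mean = float(y.mean())
    label_scale = float(y.std())
    if not label_scale > 0:
        label_scale = 1.0
    y = (y - label_mean) / label_scale
    yv = (yv - label_mean) / label_scale
    ps2 = label_scale ** 2  # report losses on the physical (ps^2) scale
    rng = np.random.default_rng(seed)
    net = _Net(spec, x.shape[1:], rng)
    opt = _Adam(net.layers_with_params())
    decay_epochs = {int(np.floor(f * spec.epochs)) for f in spec.decay_fracs}
    lr = spec.learning_rate
    n = x.shape[0]
    history = {"train_loss": [], "val_loss": [], "lr": []}
    best = (np.inf, net.get_weights(), -1)
    for epoch in range(spec.epochs):
        if epoch in decay_epochs and epoch > 0:
            lr *= 0.1
        perm = rng.permutation(n)
        losses = []
        for start in range(0, n, spec.batch_size):
            sel = perm[start:start + spec.batch_size]
            xb, yb = x[sel], y[sel]
            pred = net.forward(xb)
            diff = pred - yb
            loss = float(np.mean(diff * diff))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, "
                    f"batch {start // spec.batch_size} (lr={lr:g})")
            losses.append(loss)
            net.backward((2.0 / xb.shape[0]) * diff)
            opt.step(lr)
        val_loss = _mse(_predict_with(net, xv), yv) * ps2 if xv.shape[0] else np.nan
        history["train_loss"].append(float(np.mean(losses)) * ps2)
        history["val_loss"].append(val_loss)
        history["lr"].append(lr)
        if verbose:
            print(f"epoch {epoch + 1}/{spec.epochs}  "
                  f"train {history['train_loss'][-1]:.2f}  val {val_loss:.2f}")
        if np.isfinite(val_loss) and val_loss < best[0]:
            best = (val_loss, net.get_weights(), epoch)
    if best[2] < 0:  # no validation set: keep the final weights
        best = (history["train_loss"][-1], net.get_weights(), spec.epochs - 1)
    return CnnModel(spec=spec, input_shape=tuple(x.shape[1:]),
                    weights=best[1], label_mean=label_mean,
                    label_scale=label_scale, history=history,
                    best_epoch=best[2])


def _predict_with(net: _Net, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
    out = np.empty(x.shape[0])
    for i in range(0, x.shape[0], batch_size):
        out[i:i + batch_size] = net.forward(x[i:i + batch_size])
    return out


def save_model(model: CnnModel, path: str) -> None:
    """Persist weights (npz) plus a JSON spec card alongside."""
    arrays = {}
    for i, (W, b) in enumerate(model.weights):
        arrays[f"W{i}"] = W
        arrays[f"b{i}"] = b
    np.savez(path, **arrays)
    card = {
        "spec": model.spec.__dict__,
        "input_shape": list(model.input_shape),
        "label_mean": model.label_mean,
        "label_scale": model.label_scale,
        "best_epoch": model.best_epoch,
        "history": model.history,
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(card, fh, indent=2, default=list)


def load_model(path: str) -> CnnModel:
    with open(str(path) + ".json") as fh:
        card = json.load(fh)
    spec_raw = dict(card["spec"])
    for key in ("decay_fracs", "conv_filters", "conv_kernels"):
        spec_raw[key] = tuple(spec_raw[key])
    spec = TrainSpec(**spec_raw)
    npz_path = str(path) if str(path).endswith(".npz") else str(path) + ".npz"
    data = np.load(npz_path)
    n_layers = len([k for k in data.files if k.startswith("W")])
    weights = [(data[f"W{i}"], data[f"b{i}"]) for i in range(n_layers)]
    return CnnModel(spec=spec, input_shape=tuple(card["input_shape"]),
                    weights=weights,
                    label_mean=card.get("label_mean", 0.0),
                    label_scale=card.get("label_scale", 1.0),
                    history=card.get("history", {}),
                    best_epoch=card.get("best_epoch", -1))
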