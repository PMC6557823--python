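"""The visual-field forecaster: a 6-unit LSTM plus a 52-neuron dense head.

A single recurrent layer of long short-term-memory cells with forget
gates (no peepholes) consumes the six encoded rows and its final hidden
state is mapped through one fully connected layer; each of the 52 output
neurons predicts one visual-field test point on the normalized
(dB / 50) scale.  At the default dimensions — 108 input features,
6 hidden units, 52 outputs — the network has

    LSTM   4 * (h * (d + h) + h) = 4 * (6 * 114 + 6) = 2760
    dense  o * h + o             = 52 * 6 + 52       =  364
    total                                            = 3124

trainable parameters.  The forward pass, backpropagation through time,
and the Adam training loop are implemented directly on numpy arrays:
the network is small enough that a framework would add nothing but a
dependency, and an explicit recurrence keeps every gate inspectable.

Gate order throughout is (input i, forget f, candidate g, output o):

    z_t = W x_t + U h_{t-1} + b
    i, f, o = sigmoid(z_i), sigmoid(z_f), sigmoid(z_o);  g = tanh(z_g)
    c_t = f * c_{t-1} + i * g
    h_t = o * tanh(c_t)
    y   = V h_T + c_out                     (identity output activation)

Cell and hidden states start at zero.  Forget-gate biases are
initialized to 1.0 (keeps memory open early in training), all other
biases to 0; kernels use Glorot-uniform draws from the seeded generator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import encoder
from .vf_core import N_POINTS

GATE_ORDER = ("i", "f", "g", "o")
WEIGHT_FORMAT = "vfforecast-weights/1"


@dataclass
class ModelConfig:
    """Architecture and training hyper-parameters.

    The architecture triple (108, 6, 52) is fixed by the forecasting
    problem; the optimization settings are declared package defaults
    (MSE on normalized TDV, Adam, early stopping on a 9:1 seeded
    train/validation split with best-weight restore).
    """

    input_dim: int = encoder.N_FEATURES
    hidden_units: int = 6
    output_dim: int = N_POINTS
    seed: int = 0
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 500
    early_stop_patience: int = 20
    sequence_order: str = "decreasing"

    def __post_init__(self) -> None:
        if min(self.input_dim, self.hidden_units, self.output_dim) <= 0:
            raise ValueError("model dimensions must be positive")
        if self.sequence_order not in encoder.SEQUENCE_ORDERS:
            raise ValueError(
                f"unknown sequence order {self.sequence_order!r}")


def _glorot(rng: np.random.Generator, n_out: int, n_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=(n_out, n_in))


@dataclass
class ForecastModel:
    """Weight container for the LSTM + dense forecaster."""

    config: ModelConfig
    W: np.ndarray       # input kernels, (4h, d), gate blocks i|f|g|o
    U: np.ndarray       # recurrent kernels, (4h, h)
    b: np.ndarray       # gate biases, (4h,)
    V: np.ndarray       # dense kernel, (o, h)
    c_out: np.ndarray   # dense bias, (o,)
    history: dict = field(default_factory=dict)

    # -- parameter bookkeeping ------------------------------------------
    def parameter_count(self) -> tuple[int, int, int]:
        """(lstm, dense, total) trainable parameter counts."""
        lstm = self.W.size + self.U.size + self.b.size
        dense = self.V.size + self.c_out.size
        return lstm, dense, lstm + dense

    def _params(self) -> list[np.ndarray]:
        return [self.W, self.U, self.b, self.V, self.c_out]

    # -- forward --------------------------------------------------------
    def _gates(self, x: np.ndarray, h: np.ndarray):
        n = self.config.hidden_units
        z = x @ self.W.T + h @ self.U.T + self.b
        zi, zf, zg, zo = (z[..., k * n:(k + 1) * n] for k in range(4))
        return _sigmoid(zi), _sigmoid(zf), np.tanh(zg), _sigmoid(zo)

    def forward(self, seq) -> np.ndarray:
        """Predict the normalized 52-vector for one encoded sequence."""
        return self.forward_batch(
            _rows_of(seq, self.config.sequence_order)[None, :, :])[0]

    def forward_batch(self, X: np.ndarray) -> np.ndarray:
        """Many-to-one forward pass on a (B, T, d) batch."""
        y, _ = self._forward_cached(X)
        return y

    def _forward_cached(self, X: np.ndarray):
        B, T, d = X.shape
        if d != self.config.input_dim:
            raise ValueError(f"input feature dimension {d} != "
                             f"{self.config.input_dim}")
        n = self.config.hidden_units
        h = np.zeros((B, n))
        c = np.zeros((B, n))
        cache = []
        for t in range(T):
            i, f, g, o = self._gates(X[:, t, :], h)
            c_prev = c
            c = f * c_prev + i * g
            tanh_c = np.tanh(c)
            h = o * tanh_c
            cache.append((X[:, t, :], i, f, g, o, c_prev, tanh_c, h))
        y = h @ self.V.T + self.c_out
        return y, cache

    def predict_tdv(self, exams, prediction_date) -> np.ndarray:
        """Forecast the 52 total-deviation values (dB) at a future date."""
        seq = encoder.build_sequence(list(exams), prediction_date)
        return self.forward(seq) * encoder.DB_DIVISOR

    # -- backward -------------------------------------------------------
    def _backward(self, cache, dy: np.ndarray) -> list[np.ndarray]:
        """Gradients of the loss w.r.t. [W, U, b, V, c_out].

        ``dy`` is dLoss/dy at the dense output; backpropagation through
        time runs over the cached per-step activations.
        """
        n = self.config.hidden_units
        h_T = cache[-1][7]
        dV = dy.T @ h_T
        dc_out = dy.sum(axis=0)
        dh = dy @ self.V
        dW = np.zeros_like(self.W)
        dU = np.zeros_like(self.U)
        db = np.zeros_like(self.b)
        dc_next = np.zeros_like(dh)
        for t in range(len(cache) - 1, -1, -1):
            x, i, f, g, o, c_prev, tanh_c, _ = cache[t]
            do = dh * tanh_c
            dc = dc_next + dh * o * (1.0 - tanh_c ** 2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate([
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g ** 2),
                do * o * (1.0 - o),
            ], axis=1)
            dW += dz.T @ x
            h_prev = cache[t - 1][7] if t > 0 else np.zeros_like(dh)
            dU += dz.T @ h_prev
            db += dz.sum(axis=0)
            dh = dz @ self.U
            dc_next = dc * f
        return [dW, dU, db, dV, dc_out]

    # -- serialization --------------------------------------------------
    def save(self, path: str) -> None:
        """Portable weight file: JSON header + flat float64 payload.

        Floats are written through Python's repr-based JSON encoder,
        which round-trips IEEE-754 doubles bit-exactly.
        """
        payload = np.concatenate([p.ravel() for p in self._params()])
        doc = {
            "format": WEIGHT_FORMAT,
            "config": asdict(self.config),
            "layout": [list(p.shape) for p in self._params()],
            "history": self.history,
            "payload": payload.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def load(cls, path: str) -> "ForecastModel":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("format") != WEIGHT_FORMAT:
            raise ValueError(f"unrecognized weight file format "
                             f"{doc.get('format')!r}")
        config = ModelConfig(**doc["config"])
        model = init_model(config)
        flat = np.asarray(doc["payload"], dtype=float)
        offset = 0
        for p, shape in zip(model._params(), doc["layout"]):
            size = int(np.prod(shape))
            p[...] = flat[offset:offset + size].reshape(shape)
            offset += size
        if offset != flat.size:
            raise ValueError("weight payload size mismatch")
        model.history = doc.get("history", {})
        return model


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _rows_of(seq, sequence_order: str) -> np.ndarray:
    if isinstance(seq, encoder.EncodedSequence):
        return seq.ordered_rows(sequence_order)
    return np.asarray(seq, dtype=float)


def init_model(config: ModelConfig | None = None) -> ForecastModel:
    """Fresh model with seeded Glorot kernels and forget bias 1.0."""
    config = config or ModelConfig()
    rng = np.random.default_rng(config.seed)
    d, n, o = config.input_dim, config.hidden_units, config.output_dim
    W = np.concatenate([_glorot(rng, n, d) for _ in GATE_ORDER])
    U = np.concatenate([_glorot(rng, n, n) for _ in GATE_ORDER])
    b = np.zeros(4 * n)
    b[n:2 * n] = 1.0                       # forget gate bias
    V = _glorot(rng, o, n)
    c_out = np.zeros(o)
    return ForecastModel(config, W, U, b, V, c_out)


def parameter_count(model: ForecastModel) -> tuple[int, int, int]:
    """(lstm, dense, total); total = 4(h(d+h)+h) + (oh+o) at any dims."""
    return model.parameter_count()


def split_train_validation(n: int, seed: int,
                           validation_fraction: float = 0.1):
    """Seeded 9:1 index split; floor(0.1 n) validation samples.

    Each sample is one eye (one series yields one sequence), so the
    split never places one eye on both sides.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_val = int(np.floor(validation_fraction * n))
    return np.sort(perm[n_val:]), np.sort(perm[:n_val])


def train(model: ForecastModel, dataset, config: ModelConfig | None = None):
    """Fit by Adam on mean-squared error of normalized TDV.

    ``dataset`` is a list of (EncodedSequence, 52-vector target / 50)
    pairs.  The data are split 9:1 into train/validation (seeded);
    training stops when validation loss fails to improve for
    ``early_stop_patience`` consecutive epochs, and the best-validation
    weights are restored.  Returns ``(model, history)`` with per-epoch
    train/validation losses.
    """
    config = config or model.config
    if len(dataset) == 0:
        raise ValueError("empty training dataset")
    X = np.stack([_rows_of(seq, config.sequence_order)
                  for seq, _ in dataset])
    Y = np.stack([np.asarray(t, dtype=float) for _, t in dataset])
    train_idx, val_idx = split_train_validation(len(dataset), config.seed)
    if len(val_idx) == 0:       # tiny datasets: validate on train loss
        val_idx = train_idx
    Xtr, Ytr = X[train_idx], Y[train_idx]
    Xval, Yval = X[val_idx], Y[val_idx]

    rng = np.random.default_rng(config.seed + 1)
    params = model._params()
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    best_val = np.inf
    best_weights = [p.copy() for p in params]
    best_epoch = 0
    bad_epochs = 0
    history = {"train_loss": [], "val_loss": []}

    for epoch in range(config.max_epochs):
        order = rng.permutation(len(Xtr))
        epoch_loss = 0.0
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb = Xtr[idx], Ytr[idx]
            pred, cache = model._forward_cached(xb)
            err = pred - yb
            epoch_loss += float(np.sum(err ** 2)) / yb.shape[1]
            dy = 2.0 * err / err.size
            grads = model._backward(cache, dy)
            step += 1
            for p, g, mi, vi in zip(params, grads, m, v):
                mi += (1 - beta1) * (g - mi)
                vi += (1 - beta2) * (g * g - vi)
                mhat = mi / (1 - beta1 ** step)
                vhat = vi / (1 - beta2 ** step)
                p -= config.learning_rate * mhat / (np.sqrt(vhat) + eps)
        train_loss = epoch_loss / len(Xtr)
        val_pred = model.forward_batch(Xval)
        val_loss = float(np.mean((val_pred - Yval) ** 2))
        history["train_loss"].append(train_loss)
        history["val_loss"].append(val_loss)
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_weights = [p.copy() for p in params]
            best_epoch = epoch
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs > config.early_stop_patience:
                break
    for p, w in zip(params, best_weights):
        p[...] = w
    history["best_epoch"] = best_epoch
    history["best_val_loss"] = best_val
    history["n_train"] = int(len(train_idx))
    history["n_val"] = int(len(val_idx))
    model.history = history
    return model, history
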