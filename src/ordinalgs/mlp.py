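"""Feedforward ordinal/binary classifier (densely connected network).

One to three hidden ReLU layers with inverted dropout, a softmax output for
C ≥ 3 ordered categories (sigmoid for binary), trained by mini-batch Adam on
cross-entropy.  Hyperparameter selection follows the benchmark protocol:
the last 20% of the shuffled training rows form an inner validation split,
per-epoch validation loss is recorded, the weights of the best epoch (cap
100) are returned, and (layers × units) candidates are compared by their
minimum validation loss.

Input features are the environment one-hots concatenated with each line's
row of the Cholesky factor of the genomic relationship matrix (plus the
environment ⊗ Cholesky interaction block in the G×E variant); see
:func:`ordinalgs.kernels.assemble_features`.

Implemented directly in numpy: explicit forward/backward passes keep the
architecture inspectable and the training loop deterministic under a seed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MLPSpec",
    "MLPModel",
    "forward",
    "train_mlp",
    "tune_mlp",
    "default_grid",
    "OrdinalMLP",
]

#: the benchmark's unit grid: 10 to 490 in steps of 20 (full) or 40 (reduced)
FULL_UNIT_GRID = tuple(range(10, 500, 20))
REDUCED_UNIT_GRID = tuple(range(10, 500, 40))
LAYER_GRID = (1, 2, 3)


def default_grid(full: bool = False) -> list[tuple[int, int]]:
    """(n_layers, units) candidates; 75 points full, 39 reduced."""
    units = FULL_UNIT_GRID if full else REDUCED_UNIT_GRID
    return [(L, u) for L in LAYER_GRID for u in units]


@dataclass
class MLPSpec:
    """Architecture and training hyperparameters."""

    n_layers: int = 1
    units: int = 50
    dropout_rate: float = 0.2
    max_epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.n_layers not in (1, 2, 3):
            raise ValueError("n_layers must be 1, 2 or 3")
        if self.units < 1 or self.max_epochs < 1:
            raise ValueError("units and max_epochs must be >= 1")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass
class MLPModel:
    """Fitted network: weights, biases and the training history."""

    weights: list           # W[l] of shape (fan_in, fan_out)
    biases: list
    n_classes: int
    spec: MLPSpec
    history: dict = field(default_factory=dict)  # train_loss/val_loss per epoch
    best_epoch: int = -1

    @property
    def activations(self) -> list:
        out = "sigmoid" if len(self.biases[-1]) == 1 else "softmax"
        return ["relu"] * (len(self.weights) - 1) + [out]


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def forward(model: MLPModel, X: np.ndarray) -> np.ndarray:
    """Class probabilities for rows of X (dropout disabled).

    Hidden layers apply ReLU; the output layer applies softmax over C ≥ 3
    classes, or sigmoid for a single output unit (returned as (1−p, p)).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.weights[0].shape[0]:
        raise ValueError(
            f"input width {X.shape[1]} != model input width "
            f"{model.weights[0].shape[0]}"
        )
    h = X
    for W, b in zip(model.weights[:-1], model.biases[:-1]):
        h = np.maximum(h @ W + b, 0.0)
    z = h @ model.weights[-1] + model.biases[-1]
    if z.shape[1] == 1:
        p = 1.0 / (1.0 + np.exp(-z[:, 0]))
        return np.column_stack([1.0 - p, p])
    return _softmax(z)


def _init_params(widths, rng):
    weights, biases = [], []
    for fan_in, fan_out in zip(widths[:-1], widths[1:]):
        weights.append(rng.standard_normal((fan_in, fan_out)) * np.sqrt(2.0 / fan_in))
        biases.append(np.zeros(fan_out))
    return weights, biases


def _xent(probs: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(probs[np.arange(len(y)), y], 1e-12, None)
    return float(-np.log(p).mean())


def train_mlp(features: np.ndarray, labels: np.ndarray, spec: MLPSpec) -> MLPModel:
    """Train a network and return the parameters of the best epoch.

    The rows are shuffled once (seeded); the last 20% form the inner
    validation split.  Mini-batch Adam minimises cross-entropy; after each
    epoch both losses are recorded and the parameters achieving the minimum
    validation loss within ``max_epochs`` are kept — an efficient equivalent
    of grid-searching the epoch count.
    """
    X = np.asarray(features, dtype=float)
    y_raw = np.asarray(labels)
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    classes = np.unique(y_raw)
    if classes.size < 2:
        raise ValueError("single-class labels: nothing to classify")
    class_index = {c: k for k, c in enumerate(classes)}
    y = np.array([class_index[c] for c in y_raw])
    C = classes.size
    out_width = 1 if C == 2 else C

    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(len(X))
    n_val = max(1, int(round(0.2 * len(X))))
    tr, va = perm[:-n_val], perm[-n_val:]
    Xtr, ytr, Xva, yva = X[tr], y[tr], X[va], y[va]

    widths = [X.shape[1]] + [spec.units] * spec.n_layers + [out_width]
    weights, biases = _init_params(widths, rng)
    mW = [np.zeros_like(w) for w in weights]
    vW = [np.zeros_like(w) for w in weights]
    mB = [np.zeros_like(b) for b in biases]
    vB = [np.zeros_like(b) for b in biases]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    lr, rate = spec.learning_rate, spec.dropout_rate
    t = 0

    model = MLPModel(weights, biases, C, spec)
    history = {"train_loss": [], "val_loss": []}
    best_val, best_state, best_epoch = np.inf, None, -1

    for epoch in range(spec.max_epochs):
        order = rng.permutation(len(Xtr))
        for start in range(0, len(Xtr), spec.batch_size):
            idx = order[start : start + spec.batch_size]
            xb, yb = Xtr[idx], ytr[idx]
            # forward with inverted dropout on hidden activations
            acts, masks = [xb], []
            h = xb
            for W, b in zip(weights[:-1], biases[:-1]):
                h = np.maximum(h @ W + b, 0.0)
                if rate > 0:
                    mask = (rng.uniform(size=h.shape) >= rate) / (1.0 - rate)
                    h = h * mask
                    masks.append(mask)
                else:
                    masks.append(None)
                acts.append(h)
            z = h @ weights[-1] + biases[-1]
            if out_width == 1:
                p = 1.0 / (1.0 + np.exp(-z))
                delta = (p - yb[:, None]) / len(xb)
            else:
                p = _softmax(z)
                delta = p.copy()
                delta[np.arange(len(yb)), yb] -= 1.0
                delta /= len(xb)
            # backward
            grads_W, grads_B = [None] * len(weights), [None] * len(biases)
            for layer in range(len(weights) - 1, -1, -1):
                grads_W[layer] = acts[layer].T @ delta
                grads_B[layer] = delta.sum(axis=0)
                if layer > 0:
                    delta = delta @ weights[layer].T
                    if masks[layer - 1] is not None:
                        delta = delta * masks[layer - 1]
                    delta = delta * (acts[layer] > 0)
            t += 1
            for l in range(len(weights)):
                for P, G, m, v in (
                    (weights[l], grads_W[l], mW[l], vW[l]),
                    (biases[l], grads_B[l], mB[l], vB[l]),
                ):
                    m *= beta1
                    m += (1 - beta1) * G
                    v *= beta2
                    v += (1 - beta2) * G**2
                    mhat = m / (1 - beta1**t)
                    vhat = v / (1 - beta2**t)
                    P -= lr * mhat / (np.sqrt(vhat) + eps)

        tr_loss = _xent(forward(model, Xtr), ytr)
        va_loss = _xent(forward(model, Xva), yva)
        history["train_loss"].append(tr_loss)
        history["val_loss"].append(va_loss)
        if va_loss < best_val:
            best_val = va_loss
            best_epoch = epoch
            best_state = (copy.deepcopy(weights), copy.deepcopy(biases))

    model.weights, model.biases = best_state
    model.history = history
    model.best_epoch = best_epoch
    model.classes_ = classes  # original labels, for prediction
    return model


def predict_classes(model: MLPModel, X: np.ndarray) -> np.ndarray:
    """Most probable class (original label coding)."""
    probs = forward(model, X)
    classes = getattr(model, "classes_", np.arange(model.n_classes))
    return classes[np.argmax(probs, axis=1)]


def tune_mlp(features, labels, grid=None, spec: MLPSpec | None = None,
             full_output: bool = False):
    """Select (n_layers, units) by minimum inner-validation loss.

    Ties prefer fewer layers, then fewer units (the grid is scanned in that
    order with a strict improvement rule).
    """
    grid = list(grid) if grid is not None else default_grid()
    if not grid:
        raise ValueError("empty hyperparameter grid")
    base = spec or MLPSpec()
    best, best_loss, best_model, trace = None, np.inf, None, []
    for n_layers, units in sorted(grid):
        cand = MLPSpec(
            n_layers=n_layers, units=units, dropout_rate=base.dropout_rate,
            max_epochs=base.max_epochs, batch_size=base.batch_size,
            learning_rate=base.learning_rate, seed=base.seed,
        )
        try:
            model = train_mlp(features, labels, cand)
        except Exception as exc:  # annotate with the grid point
            raise RuntimeError(
                f"training failed at grid point (layers={n_layers}, units={units})"
            ) from exc
        loss = min(model.history["val_loss"])
        trace.append((n_layers, units, loss))
        if loss < best_loss:
            best, best_loss, best_model = cand, loss, model
    if full_output:
        return best, best_model, trace
    return best


class OrdinalMLP:
    """Estimator-style wrapper: ``OrdinalMLP(X, y).fit()`` tunes and trains."""

    def __init__(self, features, labels, grid=None, spec: MLPSpec | None = None):
        self.features = np.asarray(features, dtype=float)
        self.labels = np.asarray(labels)
        self.grid = grid
        self.spec = spec

    def fit(self) -> "OrdinalMLPResults":
        if self.grid is None and self.spec is not None:
            model = train_mlp(self.features, self.labels, self.spec)
            return OrdinalMLPResults(self.spec, model, [])
        best, model, trace = tune_mlp(
            self.features, self.labels, self.grid, self.spec, full_output=True
        )
        return OrdinalMLPResults(best, model, trace)


class OrdinalMLPResults:
    def __init__(self, spec: MLPSpec, model: MLPModel, trace):
        self.spec = spec
        self.model = model
        self.tuning_trace = trace

    def predict(self, X) -> np.ndarray:
        return predict_classes(self.model, X)

    def predict_proba(self, X) -> np.ndarray:
        return forward(self.model, X)
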