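"""The four-linear-layer latent-time regressor.

The same architecture serves both regression passes of the pipeline: the
pre-trained model fitted against a velocity-style latent-time vector over
all cells, and the refinement model fitted only on origin/middle/end cells.
Input is the k-dimensional latent-semantic score of a cell; fc1 maps it to
a 512-dimensional hidden representation, fc2 and fc3 keep that width, fc4
reduces to a single output.  Hidden layers use ReLU, the output is linear,
and the post-activation output of fc3 doubles as a per-cell embedding for
neighbor-graph clustering.

Training minimizes mean squared error with Adam on seeded mini-batches over
a seeded 80/20 train-test split; with a fixed seed the final weights are
bitwise reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .io import ValidationError


@dataclass
class RegressorSpec:
    input_dim: int
    hidden_dim: int = 512
    batch_size: int = 20
    epochs: int = 150
    learning_rate: float = 1e-3
    patience: int = 20
    weight_decay: float = 1e-4
    test_frac: float = 0.2
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RegressorSpec":
        return cls(**d)

    @property
    def layer_dims(self) -> list[tuple[int, int]]:
        h = self.hidden_dim
        return [(self.input_dim, h), (h, h), (h, h), (h, 1)]


@dataclass
class TrainedRegressor:
    spec: RegressorSpec
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    history: dict[str, list[float]] = field(default_factory=dict)
    lsi: object | None = None  # LSIEmbedding for projecting fresh data

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim != 2 or x.shape[1] != self.spec.input_dim:
            raise ValidationError(
                f"input must be (cells, {self.spec.input_dim}); got {x.shape}"
            )
        return x

    def _forward(self, x: np.ndarray) -> list[np.ndarray]:
        """Return activations [h1, h2, h3, y]; h* post-ReLU, y linear."""
        acts = []
        h = x
        for i in range(3):
            h = np.maximum(h @ self.weights[i] + self.biases[i], 0.0)
            acts.append(h)
        acts.append(h @ self.weights[3] + self.biases[3])
        return acts

    def predict_raw(self, x: np.ndarray) -> np.ndarray:
        """Unrescaled network output per cell."""
        return self._forward(self._check_input(x))[-1].ravel()


def _init_params(spec: RegressorSpec, rng: np.random.Generator):
    # He-initialized hidden layers; the output layer starts near zero so
    # the bias fits the target mean first and the hidden representation
    # stays close to its (input-faithful) initialization
    weights, biases = [], []
    dims = spec.layer_dims
    for i, (fan_in, fan_out) in enumerate(dims):
        scale = np.sqrt(2.0 / fan_in) * (0.01 if i == len(dims) - 1 else 1.0)
        weights.append(rng.normal(0.0, scale, (fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return weights, biases


def train_regressor(
    x: np.ndarray, t: np.ndarray, spec: RegressorSpec
) -> TrainedRegressor:
    """Fit the regressor on latent scores ``x`` against targets ``t``.

    A seeded shuffle yields the 80/20 train-test split; mini-batch Adam
    minimizes MSE; per-epoch train loss, test loss and test MAE are kept in
    the history; training stops early when the test loss has not improved
    for ``spec.patience`` epochs and the best-test weights are restored.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(t, dtype=float).ravel()
    if x.ndim != 2 or x.shape[1] != spec.input_dim:
        raise ValidationError(f"x must be (cells, {spec.input_dim}); got {x.shape}")
    if len(t) != x.shape[0]:
        raise ValidationError(f"{len(t)} targets for {x.shape[0]} cells")
    if not np.all(np.isfinite(t)):
        raise ValidationError("targets contain non-finite values")
    n = x.shape[0]
    if n < 10:
        raise ValidationError(f"need at least 10 cells to split; got {n}")

    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    n_test = max(1, int(round(spec.test_frac * n)))
    test_idx, train_idx = perm[:n_test], perm[n_test:]
    xtr, ttr = x[train_idx], t[train_idx]
    xte, tte = x[test_idx], t[test_idx]

    weights, biases = _init_params(spec, rng)
    model = TrainedRegressor(spec=spec, weights=weights, biases=biases)

    # Adam state
    mw = [np.zeros_like(w) for w in weights]
    vw = [np.zeros_like(w) for w in weights]
    mb = [np.zeros_like(b) for b in biases]
    vb = [np.zeros_like(b) for b in biases]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    lr = spec.learning_rate
    step = 0

    history: dict[str, list[float]] = {"train_loss": [], "test_loss": [], "test_mae": []}
    best_loss = np.inf
    best_state = None
    stall = 0

    for _epoch in range(spec.epochs):
        order = rng.permutation(len(xtr))
        epoch_loss = 0.0
        for start in range(0, len(order), spec.batch_size):
            batch = order[start : start + spec.batch_size]
            xb, tb = xtr[batch], ttr[batch]
            b = len(batch)

            # forward
            z = [None] * 4
            a = xb
            acts = [a]
            for i in range(3):
                z[i] = acts[i] @ weights[i] + biases[i]
                acts.append(np.maximum(z[i], 0.0))
            yhat = (acts[3] @ weights[3] + biases[3]).ravel()
            err = yhat - tb
            epoch_loss += float(err @ err)

            # backward (MSE)
            grad_y = (2.0 / b) * err[:, None]
            gw = [None] * 4
            gb = [None] * 4
            gw[3] = acts[3].T @ grad_y
            gb[3] = grad_y.sum(axis=0)
            delta = grad_y @ weights[3].T
            for i in (2, 1, 0):
                delta = delta * (z[i] > 0)
                gw[i] = acts[i].T @ delta
                gb[i] = delta.sum(axis=0)
                if i > 0:
                    delta = delta @ weights[i].T

            step += 1
            corr1 = 1.0 - beta1**step
            corr2 = 1.0 - beta2**step
            for i in range(4):
                g = gw[i] + spec.weight_decay * weights[i]  # L2 penalty
                mw[i] = beta1 * mw[i] + (1 - beta1) * g
                vw[i] = beta2 * vw[i] + (1 - beta2) * g**2
                weights[i] -= lr * (mw[i] / corr1) / (np.sqrt(vw[i] / corr2) + eps)
                mb[i] = beta1 * mb[i] + (1 - beta1) * gb[i]
                vb[i] = beta2 * vb[i] + (1 - beta2) * gb[i] ** 2
                biases[i] -= lr * (mb[i] / corr1) / (np.sqrt(vb[i] / corr2) + eps)

        pred_te = model.predict_raw(xte)
        test_loss = float(np.mean((pred_te - tte) ** 2))
        history["train_loss"].append(epoch_loss / len(xtr))
        history["test_loss"].append(test_loss)
        history["test_mae"].append(float(np.mean(np.abs(pred_te - tte))))

        if test_loss < best_loss:
            best_loss = test_loss
            best_state = ([w.copy() for w in weights], [b.copy() for b in biases])
            stall = 0
        else:
            stall += 1
            if stall >= spec.patience:
                break

    if best_state is not None:
        model.weights, model.biases = best_state
    model.history = history
    return model


def predict_time(model: TrainedRegressor, x: np.ndarray) -> np.ndarray:
    """Predict latent time, min-max rescaled to [0, 1] across the batch.

    The downstream 0.2/0.8 orientation thresholds and 10% state fractions
    presuppose a bounded time, hence the rescaling; a constant raw output
    maps every cell to 0.5.
    """
    raw = model.predict_raw(x)
    lo, hi = raw.min(), raw.max()
    # guard against float jitter between identical inputs: a numerically
    # constant batch maps to 0.5, not to amplified noise
    if hi - lo <= 1e-12 * max(1.0, abs(hi), abs(lo)):
        return np.full_like(raw, 0.5)
    return (raw - lo) / (hi - lo)


def extract_embedding(model: TrainedRegressor, x: np.ndarray) -> np.ndarray:
    """Post-activation output of fc3 (the penultimate layer), one 512-d
    nonnegative vector per cell."""
    return model._forward(model._check_input(x))[2]


def evaluate_mae(pred, truth) -> float:
    pred = np.asarray(pred, dtype=float).ravel()
    truth = np.asarray(truth, dtype=float).ravel()
    if pred.size == 0 or pred.shape != truth.shape:
        raise ValidationError(
            f"pred and truth must be equal-length nonempty vectors; "
            f"got {pred.shape} and {truth.shape}"
        )
    return float(np.mean(np.abs(pred - truth)))
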