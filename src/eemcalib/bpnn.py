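"""One-hidden-layer feed-forward network trained by backpropagation.

The regression network maps a score vector x to a scalar concentration
estimate

    y = sum_J W_J * f(sum_I W_JI x_I + b_J) + b_out,

with logistic-sigmoid hidden units f and a linear output.  Training is
full-batch gradient descent on the mean squared error with classical
momentum,

    dw_n = -mu * dE/dw + alpha * dw_{n-1},

where mu is the learning rate and alpha the momentum coefficient, plus
validation-based early stopping: the state from the epoch with the lowest
validation MSE is returned, and training halts once validation error has
not improved for ``patience`` epochs.

Everything is implemented directly on numpy arrays — the training rule is
the point, not a wrapped library call — and is fully deterministic under a
fixed seed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np


def _sigmoid(z: np.ndarray) -> np.ndarray:
    # clip keeps exp() in range; sigmoid is flat to double precision out there
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500.0, 500.0)))


@dataclass
class NetworkState:
    """Weights, biases, and momentum buffers of an n_i - n_h - 1 network."""

    hidden_weights: np.ndarray  # (n_h, n_i)
    hidden_biases: np.ndarray  # (n_h,)
    output_weights: np.ndarray  # (n_h,)
    output_bias: float
    prev_dW1: np.ndarray = None
    prev_db1: np.ndarray = None
    prev_dw2: np.ndarray = None
    prev_db2: float = 0.0

    def __post_init__(self):
        if self.prev_dW1 is None:
            self.prev_dW1 = np.zeros_like(self.hidden_weights)
        if self.prev_db1 is None:
            self.prev_db1 = np.zeros_like(self.hidden_biases)
        if self.prev_dw2 is None:
            self.prev_dw2 = np.zeros_like(self.output_weights)

    @property
    def n_inputs(self) -> int:
        return self.hidden_weights.shape[1]

    @property
    def n_hidden(self) -> int:
        return self.hidden_weights.shape[0]

    @property
    def n_parameters(self) -> int:
        return self.hidden_weights.size + self.hidden_biases.size + self.output_weights.size + 1

    def copy(self) -> "NetworkState":
        return copy.deepcopy(self)


@dataclass
class ScalingParams:
    """Input standardization + target min-max scaling frozen on calibration data.

    Inputs are standardized to zero mean / unit variance; targets are mapped
    to [0.1, 0.9] so that even with a saturating hidden layer the working
    range stays well inside the sigmoid's linear region.
    """

    x_mean: np.ndarray
    x_sd: np.ndarray
    y_min: float
    y_max: float
    y_lo: float = 0.1
    y_hi: float = 0.9

    @classmethod
    def fit(cls, X: np.ndarray, y: np.ndarray) -> "ScalingParams":
        sd = X.std(axis=0, ddof=0)
        sd = np.where(sd > 0, sd, 1.0)
        y_min, y_max = float(np.min(y)), float(np.max(y))
        if y_max == y_min:
            y_max = y_min + 1.0
        return cls(x_mean=X.mean(axis=0), x_sd=sd, y_min=y_min, y_max=y_max)

    def scale_x(self, X: np.ndarray) -> np.ndarray:
        return (X - self.x_mean) / self.x_sd

    def scale_y(self, y: np.ndarray) -> np.ndarray:
        frac = (np.asarray(y, dtype=float) - self.y_min) / (self.y_max - self.y_min)
        return self.y_lo + frac * (self.y_hi - self.y_lo)

    def unscale_y(self, t: np.ndarray) -> np.ndarray:
        frac = (np.asarray(t, dtype=float) - self.y_lo) / (self.y_hi - self.y_lo)
        return self.y_min + frac * (self.y_max - self.y_min)


@dataclass
class TrainConfig:
    learning_rate: float = 0.7
    momentum: float = 0.2
    max_epochs: int = 300
    patience: int = 50
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.learning_rate <= 1.0):
            raise ValueError("learning_rate must be in [0, 1]")
        if not (0.0 <= self.momentum < 1.0):
            raise ValueError("momentum must be in [0, 1)")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


@dataclass
class TrainResult:
    state: NetworkState
    train_mse: list[float] = field(default_factory=list)
    validation_mse: list[float] = field(default_factory=list)
    stopping_epoch: int = 0
    best_epoch: int = 0
    best_validation_mse: float = np.inf


def init_network(n_inputs: int, n_hidden: int, seed: int = 0) -> NetworkState:
    """Weights uniform on [-0.3, 0.3] (small symmetric init suited to
    sigmoid units); momentum buffers start at zero."""
    if n_inputs < 1 or n_hidden < 1:
        raise ValueError("layer sizes must be >= 1")
    rng = np.random.default_rng(seed)
    return NetworkState(
        hidden_weights=rng.uniform(-0.3, 0.3, size=(n_hidden, n_inputs)),
        hidden_biases=rng.uniform(-0.3, 0.3, size=n_hidden),
        output_weights=rng.uniform(-0.3, 0.3, size=n_hidden),
        output_bias=float(rng.uniform(-0.3, 0.3)),
    )


def forward(state: NetworkState, X: np.ndarray) -> np.ndarray:
    """Network output for a single input vector or a batch (rows = samples)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != state.n_inputs:
        raise ValueError(f"expected {state.n_inputs} inputs, got {X.shape[1]}")
    H = _sigmoid(X @ state.hidden_weights.T + state.hidden_biases)
    out = H @ state.output_weights + state.output_bias
    return out if out.size > 1 else float(out[0])


def _forward_batch(state: NetworkState, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    H = _sigmoid(X @ state.hidden_weights.T + state.hidden_biases)
    return H, H @ state.output_weights + state.output_bias


def mse_loss(state: NetworkState, X: np.ndarray, y: np.ndarray) -> float:
    _, out = _forward_batch(state, np.atleast_2d(X))
    return float(np.mean((out - y) ** 2))


def train_step(state: NetworkState, X: np.ndarray, y: np.ndarray, config: TrainConfig) -> float:
    """One full-batch momentum update in place; returns the pre-update MSE.

    E = mean squared error over the batch; each parameter moves by
    -mu * dE/dw + alpha * (previous move), and the applied move replaces
    the momentum buffer.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if X.shape[0] == 0:
        raise ValueError("empty batch")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite training data")
    n = X.shape[0]
    H, out = _forward_batch(state, X)
    err = out - y  # (n,)
    mse = float(np.mean(err**2))

    # dE/d(out_i) = 2 err_i / n
    g_out = 2.0 * err / n
    grad_w2 = H.T @ g_out  # (n_h,)
    grad_b2 = float(np.sum(g_out))
    # back through sigmoid: dH = H (1 - H)
    g_hidden = np.outer(g_out, state.output_weights) * H * (1.0 - H)  # (n, n_h)
    grad_W1 = g_hidden.T @ X  # (n_h, n_i)
    grad_b1 = g_hidden.sum(axis=0)

    mu, alpha = config.learning_rate, config.momentum
    dW1 = -mu * grad_W1 + alpha * state.prev_dW1
    db1 = -mu * grad_b1 + alpha * state.prev_db1
    dw2 = -mu * grad_w2 + alpha * state.prev_dw2
    db2 = -mu * grad_b2 + alpha * state.prev_db2

    state.hidden_weights += dW1
    state.hidden_biases += db1
    state.output_weights += dw2
    state.output_bias += db2
    state.prev_dW1, state.prev_db1, state.prev_dw2, state.prev_db2 = dW1, db1, dw2, db2
    return mse


def gradients(state: NetworkState, X: np.ndarray, y: np.ndarray) -> dict[str, np.ndarray]:
    """Analytic gradient of the batch MSE w.r.t. every parameter (no update)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    H, out = _forward_batch(state, X)
    g_out = 2.0 * (out - y) / n
    g_hidden = np.outer(g_out, state.output_weights) * H * (1.0 - H)
    return {
        "hidden_weights": g_hidden.T @ X,
        "hidden_biases": g_hidden.sum(axis=0),
        "output_weights": H.T @ g_out,
        "output_bias": np.array(np.sum(g_out)),
    }


def train(
    state: NetworkState,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    config: TrainConfig,
) -> TrainResult:
    """Train with early stopping; returns the best-validation-epoch state.

    Validation MSE is evaluated after every epoch (one full-batch update).
    Training stops once validation MSE has not improved for
    ``config.patience`` consecutive epochs, or at ``max_epochs``; the
    returned state is always the one with minimum recorded validation MSE.
    """
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    X_val = np.atleast_2d(np.asarray(X_val, dtype=float))
    if X_train.shape[0] == 0 or X_val.shape[0] == 0:
        raise ValueError("training and validation sets must be non-empty")

    result = TrainResult(state=state.copy())
    best = state.copy()
    best_val = mse_loss(state, X_val, y_val)
    best_epoch = 0
    since_improve = 0
    for epoch in range(1, config.max_epochs + 1):
        tr_mse = train_step(state, X_train, y_train, config)
        val_mse = mse_loss(state, X_val, y_val)
        result.train_mse.append(tr_mse)
        result.validation_mse.append(val_mse)
        if val_mse < best_val:
            best_val = val_mse
            best = state.copy()
            best_epoch = epoch
            since_improve = 0
        else:
            since_improve += 1
        result.stopping_epoch = epoch
        if since_improve >= config.patience:
            break
    result.state = best
    result.best_epoch = best_epoch
    result.best_validation_mse = best_val
    return result


def predict(state: NetworkState, scaling: ScalingParams, X: np.ndarray) -> np.ndarray:
    """Forward pass on standardized inputs, then inverse target scaling to molar."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    out = np.atleast_1d(forward(state, scaling.scale_x(X)))
    return scaling.unscale_y(out)


# ---------------------------------------------------------------------------
# Plain-text serialization for exact reload

def save_state(state: NetworkState, scaling: ScalingParams, config: TrainConfig, path: str) -> None:
    import json

    payload = {
        "hidden_weights": state.hidden_weights.tolist(),
        "hidden_biases": state.hidden_biases.tolist(),
        "output_weights": state.output_weights.tolist(),
        "output_bias": state.output_bias,
        "scaling": {
            "x_mean": scaling.x_mean.tolist(),
            "x_sd": scaling.x_sd.tolist(),
            "y_min": scaling.y_min,
            "y_max": scaling.y_max,
            "y_lo": scaling.y_lo,
            "y_hi": scaling.y_hi,
        },
        "config": {
            "learning_rate": config.learning_rate,
            "momentum": config.momentum,
            "max_epochs": config.max_epochs,
            "patience": config.patience,
            "seed": config.seed,
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_state(path: str) -> tuple[NetworkState, ScalingParams, TrainConfig]:
    import json

    with open(path) as fh:
        payload = json.load(fh)
    state = NetworkState(
        hidden_weights=np.array(payload["hidden_weights"]),
        hidden_biases=np.array(payload["hidden_biases"]),
        output_weights=np.array(payload["output_weights"]),
        output_bias=float(payload["output_bias"]),
    )
    sc = payload["scaling"]
    scaling = ScalingParams(
        x_mean=np.array(sc["x_mean"]),
        x_sd=np.array(sc["x_sd"]),
        y_min=sc["y_min"],
        y_max=sc["y_max"],
        y_lo=sc["y_lo"],
        y_hi=sc["y_hi"],
    )
    config = TrainConfig(**payload["config"])
    return state, scaling, config
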