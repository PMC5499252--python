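"""Two-layer feed-forward network trained by scaled conjugate gradients.

The classifier is a classical N_I-N_H-1 network: sigmoid hidden units,
a linear output unit, and a (optionally class-weighted) mean-squared
error fitness.  Training uses Moller's scaled conjugate gradient (SCG),
a conjugate-direction method that replaces the line search with a
Levenberg-style model-trust scaling of a finite-difference
Hessian-vector estimate; it needs only gradient evaluations and has no
step-size hyperparameter.

Targets are coded HC = 0, AD = 1 and the decision threshold is 0.5
(outputs exactly at threshold classify as AD).  Class costs enter the
loss as per-class multiplicative weights in a weighted mean:

    F(w) = sum_l c_{class(l)} * (O_l - T_l)^2 / sum_l c_{class(l)}

which reduces to the plain MSE when every cost is 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "NetworkWeights",
    "TrainConfig",
    "initialize_weights",
    "forward_pass",
    "mse_loss",
    "gradient",
    "train_scg",
    "classify",
]


@dataclass
class NetworkWeights:
    """Connection weights: w1 (input->hidden), w2 (hidden->output), biases."""

    w1: np.ndarray  # (N_I, N_H)
    b1: np.ndarray  # (N_H,)
    w2: np.ndarray  # (N_H, N_O)
    b2: np.ndarray  # (N_O,)

    @property
    def sizes(self) -> tuple[int, int, int]:
        return self.w1.shape[0], self.w1.shape[1], self.w2.shape[1]

    def flatten(self) -> np.ndarray:
        return np.concatenate(
            [self.w1.ravel(), self.b1.ravel(), self.w2.ravel(), self.b2.ravel()]
        )

    @classmethod
    def from_flat(cls, vec: np.ndarray, sizes: tuple[int, int, int]) -> "NetworkWeights":
        ni, nh, no = sizes
        parts = np.split(vec, [ni * nh, ni * nh + nh, ni * nh + nh + nh * no])
        return cls(
            w1=parts[0].reshape(ni, nh),
            b1=parts[1].copy(),
            w2=parts[2].reshape(nh, no),
            b2=parts[3].copy(),
        )

    def copy(self) -> "NetworkWeights":
        return NetworkWeights(self.w1.copy(), self.b1.copy(),
                              self.w2.copy(), self.b2.copy())


@dataclass(frozen=True)
class TrainConfig:
    """SCG training settings (sigma and lambda_init are Moller's constants)."""

    max_iterations: int = 500
    mse_goal: float = 0.0
    sigma: float = 1e-5
    lambda_init: float = 1e-6
    seed: int = 0
    class_costs: tuple[float, float] | None = None  # (cost_HC, cost_AD)
    use_bias: bool = True
    grad_tol: float = 1e-10

    def __post_init__(self) -> None:
        if self.max_iterations < 0:
            raise ValueError("max_iterations must be >= 0")
        if self.mse_goal < 0:
            raise ValueError("mse_goal must be >= 0")
        if self.class_costs is not None and any(c <= 0 for c in self.class_costs):
            raise ValueError("class costs must be positive")


def initialize_weights(sizes: tuple[int, int, int], seed: int = 0,
                       use_bias: bool = True) -> NetworkWeights:
    """Symmetric uniform initialisation scaled by fan-in, fully seeded."""
    ni, nh, no = sizes
    rng = np.random.default_rng(seed)
    w1 = rng.uniform(-1.0, 1.0, size=(ni, nh)) / math.sqrt(ni)
    w2 = rng.uniform(-1.0, 1.0, size=(nh, no)) / math.sqrt(nh)
    if use_bias:
        b1 = rng.uniform(-1.0, 1.0, size=nh) / math.sqrt(ni)
        b2 = rng.uniform(-1.0, 1.0, size=no) / math.sqrt(nh)
    else:
        b1 = np.zeros(nh)
        b2 = np.zeros(no)
    return NetworkWeights(w1, b1, w2, b2)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def forward_pass(weights: NetworkWeights, x: np.ndarray):
    """Hidden activations and output for one input vector.

    ``y_j = sigmoid(sum_i w1[i, j] x_i + b1[j])`` and the output is the
    affine map ``O = y . w2 + b2`` (linear output activation).
    """
    x = np.asarray(x, dtype=float)
    ni = weights.w1.shape[0]
    if x.shape[-1] != ni:
        raise ValueError(f"input length {x.shape[-1]} != N_I={ni}")
    y = _sigmoid(x @ weights.w1 + weights.b1)
    out = y @ weights.w2 + weights.b2
    return y, out


def _batch_outputs(weights: NetworkWeights, X: np.ndarray):
    y = _sigmoid(X @ weights.w1 + weights.b1)
    return y, y @ weights.w2 + weights.b2


def _sample_costs(T: np.ndarray, class_costs) -> np.ndarray:
    if class_costs is None:
        return np.ones(T.shape[0])
    c_hc, c_ad = class_costs
    t = T.reshape(T.shape[0], -1)[:, 0]
    return np.where(t >= 0.5, c_ad, c_hc)


def _check_xt(X, T):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    T = np.asarray(T, dtype=float)
    if T.ndim == 1:
        T = T[:, None]
    if X.shape[0] != T.shape[0]:
        raise ValueError(
            f"{X.shape[0]} samples but {T.shape[0]} targets"
        )
    return X, T


def mse_loss(weights: NetworkWeights, X, T, class_costs=None) -> float:
    """Cost-weighted mean squared error over all samples."""
    X, T = _check_xt(X, T)
    _, out = _batch_outputs(weights, X)
    c = _sample_costs(T, class_costs)
    per_sample = ((out - T) ** 2).sum(axis=1)
    return float((c * per_sample).sum() / c.sum())


def gradient(weights: NetworkWeights, X, T, class_costs=None) -> NetworkWeights:
    """Analytic gradient of :func:`mse_loss` (delta rule / backprop)."""
    X, T = _check_xt(X, T)
    c = _sample_costs(T, class_costs)
    y, out = _batch_outputs(weights, X)
    # d loss / d out
    w = (c / c.sum())[:, None]
    dout = 2.0 * w * (out - T)                      # (n, N_O)
    gw2 = y.T @ dout                                # (N_H, N_O)
    gb2 = dout.sum(axis=0)
    dhid = (dout @ weights.w2.T) * y * (1.0 - y)    # (n, N_H)
    gw1 = X.T @ dhid
    gb1 = dhid.sum(axis=0)
    return NetworkWeights(gw1, gb1, gw2, gb2)


def train_scg(X, T, sizes: tuple[int, int, int], config: TrainConfig = TrainConfig()):
    """Train with Moller's scaled conjugate gradient.

    Returns ``(weights, trace)`` where `trace` holds the loss at the
    initial weights and after every accepted step (hence non-increasing).
    Fully deterministic given ``config.seed``.
    """
    X, T = _check_xt(X, T)
    if X.shape[0] == 0:
        raise ValueError("empty training set")
    if X.shape[1] != sizes[0]:
        raise ValueError(f"input dimension {X.shape[1]} != N_I={sizes[0]}")
    costs = config.class_costs

    weights = initialize_weights(sizes, config.seed, config.use_bias)
    w = weights.flatten()
    n_par = w.size
    mask = np.ones(n_par)
    if not config.use_bias:
        ni, nh, no = sizes
        mask[ni * nh: ni * nh + nh] = 0.0
        mask[ni * nh + nh + nh * no:] = 0.0

    def f(vec):
        return mse_loss(NetworkWeights.from_flat(vec, sizes), X, T, costs)

    def g(vec):
        return gradient(NetworkWeights.from_flat(vec, sizes), X, T, costs).flatten() * mask

    fw = f(w)
    trace = [fw]
    if config.max_iterations == 0:
        return NetworkWeights.from_flat(w, sizes), trace

    r = -g(w)
    p = r.copy()
    lam, lam_bar = config.lambda_init, 0.0
    success = True
    delta = 0.0
    for k in range(1, config.max_iterations + 1):
        p2 = float(p @ p)
        pnorm = math.sqrt(p2)
        if pnorm < 1e-300:
            break
        if success:
            sk = config.sigma / pnorm
            s = (g(w + sk * p) - g(w)) / sk
            delta = float(p @ s)
        # Levenberg-style scaling of the curvature estimate
        delta += (lam - lam_bar) * p2
        if delta <= 0:  # make the Hessian estimate positive definite
            lam_bar = 2.0 * (lam - delta / p2)
            delta = -delta + lam * p2
            lam = lam_bar
        mu = float(p @ r)
        alpha = mu / delta
        fw_new = f(w + alpha * p)
        comparison = 2.0 * delta * (fw - fw_new) / (mu * mu)
        if comparison >= 0 and np.isfinite(fw_new):
            # accepted step
            w = w + alpha * p
            fw = fw_new
            r_new = -g(w)
            trace.append(fw)
            lam_bar = 0.0
            success = True
            if k % n_par == 0:
                p = r_new.copy()  # periodic restart along the gradient
            else:
                beta = (float(r_new @ r_new) - float(r_new @ r)) / mu
                p = r_new + beta * p
            r = r_new
            if comparison >= 0.75:
                lam = max(lam / 4.0, 1e-300)
        else:
            if not np.isfinite(fw_new) and not np.isfinite(fw):
                raise FloatingPointError(
                    f"non-finite loss at SCG iteration {k}"
                )
            lam_bar = lam
            success = False
        if comparison < 0.25:
            lam += delta * (1.0 - comparison) / p2
        if not np.isfinite(lam) or lam > 1e100:
            break  # trust region collapsed; no further progress possible
        if fw <= config.mse_goal or float(r @ r) < config.grad_tol ** 2:
            break
    return NetworkWeights.from_flat(w, sizes), trace


def classify(weights: NetworkWeights, X, threshold: float = 0.5) -> np.ndarray:
    """Label samples: AD where the network output >= `threshold`, else HC."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    _, out = _batch_outputs(weights, X)
    return np.where(out[:, 0] >= threshold, "AD", "HC")
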