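"""The risk model: a sigmoid multilayer perceptron trained by full-batch
gradient descent with weight decay.

The network has ``p`` inputs (log adduct concentrations), one hidden layer
of ``m`` logistic nodes and a single logistic output:

.. math::

    f(x, w) = \\sigma\\Big(c_0 + \\sum_{j=1}^{m} d_j\\,
              \\sigma(a_j^\\top x + c_j)\\Big),
    \\qquad \\sigma(z) = \\frac{1}{1 + e^{-z}} .

The parameter vector ``w`` stacks, in order, the output weights ``d``, the
output bias ``c0``, the hidden weight vectors ``a_1 .. a_m`` and the hidden
biases ``c_1 .. c_m`` — ``m (p + 2) + 1`` free parameters in total (61 for
the 4-input, 10-hidden reference panel).  Training minimises mean squared
error with an L2 weight-decay penalty,

.. math::

    V(w) = \\frac{1}{n} \\sum_{k=1}^{n} (y_k - f(x_k, w))^2
           + \\frac{\\alpha}{2} \\lVert w \\rVert^2 ,

by plain full-batch gradient descent ``w <- w - mu * grad V(w)`` for a
fixed number of updates.  No momentum, line search or early stopping is
used; the defaults are ``alpha = 0.0004``, ``mu = 0.02`` and 50 000
updates with a 10-node hidden layer.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import expit

from .cohort_io import FeatureMatrix

__all__ = [
    "MLPParameters",
    "TrainingConfig",
    "TrainingTrace",
    "parameter_count",
    "hidden_activation",
    "forward",
    "objective",
    "gradient",
    "train",
    "save_parameters",
    "load_parameters",
]


def parameter_count(p: int, m: int) -> int:
    """Number of free parameters of a ``p``-input, ``m``-hidden network.

    Each hidden node has ``p`` weights and a bias; the output node has
    ``m`` weights and a bias: ``m * (p + 2) + 1`` in total.
    """
    if p < 1 or m < 1:
        raise ValueError("p and m must both be >= 1")
    return m * (p + 2) + 1


@dataclass(frozen=True)
class MLPParameters:
    """All weights and biases of the two-layer network.

    Attributes
    ----------
    hidden_weights : ndarray, shape (m, p)
        Row ``j`` is the input weight vector ``a_j`` of hidden node ``j``.
    hidden_biases : ndarray, shape (m,)
        Hidden biases ``c_1 .. c_m``.
    output_weights : ndarray, shape (m,)
        Output weights ``d``.
    output_bias : float
        Output bias ``c_0``.
    """

    hidden_weights: np.ndarray
    hidden_biases: np.ndarray
    output_weights: np.ndarray
    output_bias: float

    def __post_init__(self) -> None:
        A = np.atleast_2d(np.asarray(self.hidden_weights, dtype=float))
        c = np.atleast_1d(np.asarray(self.hidden_biases, dtype=float))
        d = np.atleast_1d(np.asarray(self.output_weights, dtype=float))
        if A.ndim != 2:
            raise ValueError("hidden_weights must be a 2-D (m, p) array")
        m = A.shape[0]
        if c.shape != (m,) or d.shape != (m,):
            raise ValueError("hidden_biases and output_weights must have length m")
        object.__setattr__(self, "hidden_weights", A)
        object.__setattr__(self, "hidden_biases", c)
        object.__setattr__(self, "output_weights", d)
        object.__setattr__(self, "output_bias", float(self.output_bias))

    @property
    def n_hidden(self) -> int:
        return self.hidden_weights.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.hidden_weights.shape[1]

    @property
    def size(self) -> int:
        """Total number of free parameters."""
        return parameter_count(self.n_inputs, self.n_hidden)

    def to_vector(self) -> np.ndarray:
        """Flatten to the canonical order ``(d, c0, a_1 .. a_m, c_1 .. c_m)``."""
        return np.concatenate(
            [
                self.output_weights,
                [self.output_bias],
                self.hidden_weights.ravel(),
                self.hidden_biases,
            ]
        )

    @classmethod
    def from_vector(cls, w: Sequence[float], n_inputs: int, n_hidden: int) -> "MLPParameters":
        """Rebuild parameters from a canonical-order flat vector."""
        w = np.asarray(w, dtype=float)
        expected = parameter_count(n_inputs, n_hidden)
        if w.shape != (expected,):
            raise ValueError(f"expected vector of length {expected}, got {w.shape}")
        m, p = n_hidden, n_inputs
        d = w[:m]
        c0 = w[m]
        A = w[m + 1 : m + 1 + m * p].reshape(m, p)
        c = w[m + 1 + m * p :]
        return cls(hidden_weights=A, hidden_biases=c, output_weights=d, output_bias=c0)

    def squared_norm(self) -> float:
        w = self.to_vector()
        return float(w @ w)


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of the gradient-descent fit.

    ``alpha`` is the weight-decay coefficient, ``mu`` the fixed step size
    and ``n_updates`` the exact number of full-batch updates performed.
    The initial parameters are drawn uniformly from
    ``[-init_scale, +init_scale]`` using ``seed``.
    """

    alpha: float = 0.0004
    mu: float = 0.02
    n_updates: int = 50_000
    n_hidden: int = 10
    init_scale: float = 0.5
    seed: int = 0
    trace_every: int = 100

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if not self.mu >= 0:
            raise ValueError("mu must be >= 0")
        if self.n_updates < 1 or self.n_hidden < 1:
            raise ValueError("n_updates and n_hidden must be >= 1")
        if not self.init_scale > 0:
            raise ValueError("init_scale must be > 0")
        if self.trace_every < 1:
            raise ValueError("trace_every must be >= 1")

    def with_seed(self, seed: int) -> "TrainingConfig":
        return replace(self, seed=int(seed))


@dataclass(frozen=True)
class TrainingTrace:
    """Objective values recorded along the descent path.

    ``iterations[i]`` is the update count at which ``objective_values[i]``
    was evaluated (0 is the initialisation, the last entry the final
    parameters).  ``final_error_rate_at_half`` is the training
    misclassification rate at the conventional threshold ``t = 0.5``.
    """

    iterations: np.ndarray
    objective_values: np.ndarray
    final_objective: float
    final_error_rate_at_half: float


def _sigmoid(z: np.ndarray) -> np.ndarray:
    # expit is the numerically safe logistic (no overflow at large |z|)
    return expit(z)


def hidden_activation(x: np.ndarray, a: np.ndarray, c: float) -> float:
    """Logistic response of one hidden node, ``sigma(a . x + c)``."""
    x = np.asarray(x, dtype=float)
    a = np.asarray(a, dtype=float)
    if x.shape != a.shape:
        raise ValueError("x and a must have the same length")
    return float(_sigmoid(np.atleast_1d(x @ a + c))[0])


def _raw_scores(x: np.ndarray, A: np.ndarray, c: np.ndarray,
                d: np.ndarray, c0: float) -> tuple[np.ndarray, np.ndarray]:
    """Hidden activations and network outputs for a batch ``x`` (n, p)."""
    H = _sigmoid(x @ A.T + c)
    f = _sigmoid(H @ d + c0)
    return H, f


def forward(x: np.ndarray, params: MLPParameters) -> float | np.ndarray:
    """Network output(s) in (0, 1) for a single input vector or a batch.

    A 1-D ``x`` of length ``p`` yields a scalar; an ``(n, p)`` array yields
    a length-``n`` vector of risk scores.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    x2 = np.atleast_2d(x)
    if x2.shape[1] != params.n_inputs:
        raise ValueError(
            f"input dimension {x2.shape[1]} does not match model ({params.n_inputs})"
        )
    _, f = _raw_scores(
        x2, params.hidden_weights, params.hidden_biases,
        params.output_weights, params.output_bias,
    )
    return float(f[0]) if single else f


def objective(params: MLPParameters, features: FeatureMatrix, alpha: float) -> float:
    """Mean squared error plus the ``(alpha/2) ||w||^2`` decay penalty."""
    if features.n_subjects < 1:
        raise ValueError("feature matrix is empty")
    f = forward(features.x, params)
    mse = float(np.mean((features.y - f) ** 2))
    return mse + 0.5 * alpha * params.squared_norm()


def _gradient_arrays(
    A: np.ndarray, c: np.ndarray, d: np.ndarray, c0: float,
    x: np.ndarray, y: np.ndarray, alpha: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Analytic gradient of the objective in parameter-array form.

    Backpropagation through both logistic layers: with residual
    ``r_k = -(2/n)(y_k - f_k) f_k (1 - f_k)`` (the derivative of the MSE
    term through the output sigmoid) the output-layer gradients are sums
    of ``r_k`` against the hidden activations, and the hidden-layer
    gradients push ``r_k d_j h_kj (1 - h_kj)`` back onto the inputs.  The
    decay term contributes ``alpha * w`` throughout.
    """
    n = x.shape[0]
    H, f = _raw_scores(x, A, c, d, c0)
    r = -(2.0 / n) * (y - f) * f * (1.0 - f)        # dV/du_k, u = pre-sigmoid output
    g_d = H.T @ r + alpha * d
    g_c0 = float(r.sum() + alpha * c0)
    Q = (r[:, None] * d[None, :]) * H * (1.0 - H)   # dV/dz_kj, z = hidden pre-activation
    g_A = Q.T @ x + alpha * A
    g_c = Q.sum(axis=0) + alpha * c
    return g_A, g_c, g_d, g_c0


def gradient(params: MLPParameters, features: FeatureMatrix, alpha: float) -> MLPParameters:
    """Exact analytic gradient of :func:`objective`, parameter-shaped."""
    if features.n_subjects < 1:
        raise ValueError("feature matrix is empty")
    g_A, g_c, g_d, g_c0 = _gradient_arrays(
        params.hidden_weights, params.hidden_biases,
        params.output_weights, params.output_bias,
        features.x, features.y, alpha,
    )
    return MLPParameters(
        hidden_weights=g_A, hidden_biases=g_c, output_weights=g_d, output_bias=g_c0
    )


def _initial_arrays(p: int, config: TrainingConfig):
    rng = np.random.default_rng(config.seed)
    m, s = config.n_hidden, config.init_scale
    A = rng.uniform(-s, s, size=(m, p))
    c = rng.uniform(-s, s, size=m)
    d = rng.uniform(-s, s, size=m)
    c0 = float(rng.uniform(-s, s))
    return A, c, d, c0


def train(
    features: FeatureMatrix, config: TrainingConfig = TrainingConfig()
) -> tuple[MLPParameters, TrainingTrace]:
    """Fit the network by fixed-step full-batch gradient descent.

    Runs exactly ``config.n_updates`` updates from a seeded uniform
    initialisation and returns the final parameters together with an
    objective trace (recorded at initialisation, every
    ``config.trace_every`` updates and at the end).  The same data and
    configuration always reproduce the same parameters.

    Raises
    ------
    ValueError
        If the training set does not contain both classes (downstream
        threshold selection and AUC would be undefined).
    """
    x, y = features.x, features.y
    if features.n_subjects < 2 or not (0 < features.n_cases < features.n_subjects):
        raise ValueError("training requires at least one case and one control")

    A, c, d, c0 = _initial_arrays(features.n_features, config)
    alpha, mu = config.alpha, config.mu

    def current_objective() -> float:
        _, f = _raw_scores(x, A, c, d, c0)
        w_sq = (A * A).sum() + c @ c + d @ d + c0 * c0
        return float(np.mean((y - f) ** 2) + 0.5 * alpha * w_sq)

    recorded_iters = [0]
    recorded_values = [current_objective()]
    for it in range(1, config.n_updates + 1):
        g_A, g_c, g_d, g_c0 = _gradient_arrays(A, c, d, c0, x, y, alpha)
        A = A - mu * g_A
        c = c - mu * g_c
        d = d - mu * g_d
        c0 = c0 - mu * g_c0
        if it % config.trace_every == 0 or it == config.n_updates:
            recorded_iters.append(it)
            recorded_values.append(current_objective())

    params = MLPParameters(
        hidden_weights=A, hidden_biases=c, output_weights=d, output_bias=c0
    )
    _, f = _raw_scores(x, A, c, d, c0)
    trace = TrainingTrace(
        iterations=np.asarray(recorded_iters),
        objective_values=np.asarray(recorded_values),
        final_objective=recorded_values[-1],
        final_error_rate_at_half=float(np.mean((f >= 0.5) != (y == 1.0))),
    )
    return params, trace


def save_parameters(params: MLPParameters, path: str | Path) -> None:
    """Serialise parameters as plain text (canonical flat-vector order)."""
    path = Path(path)
    lines = [f"# adductrisk mlp parameters p={params.n_inputs} m={params.n_hidden}"]
    lines += [repr(float(v)) for v in params.to_vector()]
    path.write_text("\n".join(lines) + "\n")


def load_parameters(path: str | Path) -> MLPParameters:
    """Load parameters written by :func:`save_parameters` (bit-identical)."""
    path = Path(path)
    lines = path.read_text().strip().splitlines()
    header = lines[0]
    if not header.startswith("# adductrisk mlp parameters"):
        raise ValueError(f"{path}: not an adductrisk parameter file")
    fields = dict(tok.split("=") for tok in header.split() if "=" in tok)
    p, m = int(fields["p"]), int(fields["m"])
    w = np.array([float(v) for v in lines[1:]])
    return MLPParameters.from_vector(w, n_inputs=p, n_hidden=m)
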