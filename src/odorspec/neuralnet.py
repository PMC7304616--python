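"""Sparse autoencoder + mapping network for odor-descriptor-group prediction.

The predictor is a six-layer feed-forward composition:

* a five-layer sparse autoencoder 201 -> K_M -> D_M -> K_M -> 201 (sigmoid
  units throughout) compresses each normalised mass spectrum into a D_M-dim
  bottleneck code.  Its cost is mean squared reconstruction error plus an L2
  weight penalty (coefficient lambda) plus a Kullback-Leibler sparsity penalty
  (coefficient beta) that pushes the mean activation of every encoder hidden
  unit toward a small target rho;
* a four-layer mapping network D_M -> K_p1 -> K_p2 -> k (sigmoid units)
  predicts per-group presence probabilities from the bottleneck code under a
  Bernoulli cross-entropy loss (plus the same L2 penalty).

Both are trained full-batch with Moller's scaled conjugate gradient (SCG),
which is deterministic given the weight initialisation seed and only ever
accepts cost-decreasing steps.  Composing encoder and mapper and binarising
each output with a (p, 1-p) softmax pair — i.e. thresholding the sigmoid at
0.5 — yields the final 201 -> k binary predictor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

N_INPUT = 201  # channels of the 50-250 m/z window


class DivergenceError(RuntimeError):
    """Training produced a non-finite cost; the message reports the epoch."""


@dataclass(frozen=True)
class NetworkArchitecture:
    """Layer widths of the composed predictor (defaults = tuned values)."""

    ae_hidden: int = 60       # K_M
    bottleneck: int = 20      # D_M
    map_hidden1: int = 50     # K_p1
    map_hidden2: int = 15     # K_p2
    n_groups: int = 5         # K_p3
    n_input: int = N_INPUT

    def __post_init__(self) -> None:
        for name in ("ae_hidden", "bottleneck", "map_hidden1", "map_hidden2",
                     "n_groups", "n_input"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def ae_layers(self) -> tuple[int, ...]:
        return (self.n_input, self.ae_hidden, self.bottleneck, self.ae_hidden, self.n_input)

    @property
    def map_layers(self) -> tuple[int, ...]:
        return (self.bottleneck, self.map_hidden1, self.map_hidden2, self.n_groups)


@dataclass(frozen=True)
class TrainingConfig:
    """Optimiser and regularisation settings shared by both networks."""

    learning_rate: float = 0.01      # eta: SCG initial step scale / GD step size
    l2_coefficient: float = 1e-4     # lambda
    sparsity_coefficient: float = 1.0  # beta (autoencoder only)
    sparsity_target: float = 0.05    # rho
    epochs_ae: int = 1000
    epochs_map: int = 1000
    seed: int = 0
    optimizer: str = "scg"           # "scg" or "gd"

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.l2_coefficient < 0 or self.sparsity_coefficient < 0:
            raise ValueError("regularisation coefficients must be >= 0")
        if not 0 < self.sparsity_target < 1:
            raise ValueError("sparsity_target must lie in (0, 1)")
        if self.epochs_ae < 1 or self.epochs_map < 1:
            raise ValueError("epoch counts must be >= 1")
        if self.optimizer not in ("scg", "gd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _init_params(layers: tuple[int, ...], rng: np.random.Generator):
    """Glorot-uniform weights (±sqrt(6/(fan_in+fan_out))), zero biases."""
    weights, biases = [], []
    for fan_in, fan_out in zip(layers[:-1], layers[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return weights, biases


def _pack(weights, biases) -> np.ndarray:
    return np.concatenate([w.ravel() for w in weights] + [b.ravel() for b in biases])


def _unpack(theta: np.ndarray, layers: tuple[int, ...]):
    weights, biases, pos = [], [], 0
    for fan_in, fan_out in zip(layers[:-1], layers[1:]):
        weights.append(theta[pos:pos + fan_in * fan_out].reshape(fan_in, fan_out))
        pos += fan_in * fan_out
    for fan_out in layers[1:]:
        biases.append(theta[pos:pos + fan_out])
        pos += fan_out
    return weights, biases


def _forward(weights, biases, X: np.ndarray) -> list[np.ndarray]:
    activations = [np.asarray(X, dtype=float)]
    for W, b in zip(weights, biases):
        activations.append(_sigmoid(activations[-1] @ W + b))
    return activations


@dataclass
class _FeedForward:
    layers: tuple[int, ...]
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    cost_history: list[float] = field(default_factory=list)

    def pack(self) -> np.ndarray:
        return _pack(self.weights, self.biases)

    def with_parameters(self, theta: np.ndarray) -> "_FeedForward":
        weights, biases = _unpack(np.asarray(theta, dtype=float), self.layers)
        return replace(self, weights=weights, biases=biases)

    def forward(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.layers[0]:
            raise ValueError(f"expected {self.layers[0]} input features, got {X.shape[1]}")
        return _forward(self.weights, self.biases, X)[-1]


class AutoencoderModel(_FeedForward):
    """201 -> K_M -> D_M -> K_M -> 201 sigmoid autoencoder."""

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)


class MappingModel(_FeedForward):
    """D_M -> K_p1 -> K_p2 -> k sigmoid network with per-group probabilities."""

    def predict_proba(self, Z: np.ndarray) -> np.ndarray:
        return self.forward(Z)


# ---------------------------------------------------------------------------
# Costs and analytic gradients
# ---------------------------------------------------------------------------

_RHO_EPS = 1e-10  # keeps the KL penalty finite for saturated units


def _kl_sparsity(rho: float, rho_hat: np.ndarray) -> float:
    rh = np.clip(rho_hat, _RHO_EPS, 1.0 - _RHO_EPS)
    return float(np.sum(rho * np.log(rho / rh) + (1 - rho) * np.log((1 - rho) / (1 - rh))))


def _ae_cost_grad(theta, layers, X, lam, beta, rho):
    weights, biases = _unpack(theta, layers)
    acts = _forward(weights, biases, X)
    Y = acts[-1]
    N = X.shape[0]
    resid = Y - X
    cost = float(np.sum(resid ** 2)) / N
    cost += lam / 2.0 * sum(float(np.sum(W ** 2)) for W in weights)
    # sparsity over the encoder's hidden layers (activations 1 and 2)
    rho_hats = [acts[l].mean(axis=0) for l in (1, 2)]
    cost += beta * sum(_kl_sparsity(rho, rh) for rh in rho_hats)

    grads_W = [None] * len(weights)
    grads_b = [None] * len(biases)
    delta = (2.0 / N) * resid * Y * (1.0 - Y)
    for l in range(len(weights) - 1, -1, -1):
        grads_W[l] = acts[l].T @ delta + lam * weights[l]
        grads_b[l] = delta.sum(axis=0)
        if l > 0:
            back = delta @ weights[l].T
            if l in (1, 2):  # entering an encoder hidden layer: add KL term
                rh = np.clip(rho_hats[l - 1], _RHO_EPS, 1.0 - _RHO_EPS)
                back = back + beta / N * (-(rho / rh) + (1 - rho) / (1 - rh))
            delta = back * acts[l] * (1.0 - acts[l])
    return cost, _pack(grads_W, grads_b)


def _map_cost_grad(theta, layers, Z, Y, lam):
    weights, biases = _unpack(theta, layers)
    acts = _forward(weights, biases, Z)
    P = acts[-1]
    N = Z.shape[0]
    Pc = np.clip(P, 1e-12, 1.0 - 1e-12)
    cost = -float(np.sum(Y * np.log(Pc) + (1 - Y) * np.log(1 - Pc))) / N
    cost += lam / 2.0 * sum(float(np.sum(W ** 2)) for W in weights)

    grads_W = [None] * len(weights)
    grads_b = [None] * len(biases)
    delta = (P - Y) / N  # sigmoid + cross-entropy
    for l in range(len(weights) - 1, -1, -1):
        grads_W[l] = acts[l].T @ delta + lam * weights[l]
        grads_b[l] = delta.sum(axis=0)
        if l > 0:
            delta = (delta @ weights[l].T) * acts[l] * (1.0 - acts[l])
    return cost, _pack(grads_W, grads_b)


def autoencoder_cost(model: AutoencoderModel, X: np.ndarray, l2_coefficient: float,
                     sparsity_coefficient: float, sparsity_target: float) -> float:
    """Reconstruction MSE + (lambda/2)*sum W^2 + beta * KL sparsity penalty."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.layers[0]:
        raise ValueError(f"expected {model.layers[0]} channels, got {X.shape[1]}")
    cost, _ = _ae_cost_grad(model.pack(), model.layers, X, l2_coefficient,
                            sparsity_coefficient, sparsity_target)
    return cost


def autoencoder_grad(model: AutoencoderModel, X: np.ndarray, l2_coefficient: float,
                     sparsity_coefficient: float, sparsity_target: float) -> np.ndarray:
    """Analytic gradient of :func:`autoencoder_cost`, packed like ``model.pack()``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    _, grad = _ae_cost_grad(model.pack(), model.layers, X, l2_coefficient,
                            sparsity_coefficient, sparsity_target)
    return grad


def mapping_cost(model: MappingModel, Z, Y, l2_coefficient: float) -> float:
    """Mean per-sample Bernoulli cross-entropy (summed over groups) + L2."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    cost, _ = _map_cost_grad(model.pack(), model.layers, Z, Y, l2_coefficient)
    return cost


def mapping_grad(model: MappingModel, Z, Y, l2_coefficient: float) -> np.ndarray:
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    _, grad = _map_cost_grad(model.pack(), model.layers, Z, Y, l2_coefficient)
    return grad


# ---------------------------------------------------------------------------
# Optimisers (full-batch, deterministic)
# ---------------------------------------------------------------------------

def scg_minimize(fun, theta0: np.ndarray, max_iter: int, sigma0: float = 1e-5,
                 grad_tol: float = 1e-12):
    """Moller's scaled conjugate gradient (1993).

    ``fun(theta) -> (cost, grad)``.  Full batch, no line searches, no
    randomness; only cost-decreasing steps are accepted, so the recorded cost
    sequence is non-increasing.  Returns ``(theta, costs)`` with one cost per
    iteration (index 0 is the initial cost).
    """
    theta = np.asarray(theta0, dtype=float).copy()
    f, g = fun(theta)
    if not np.isfinite(f):
        raise DivergenceError("non-finite cost at initialisation")
    costs = [f]
    r = -g
    p = r.copy()
    success = True
    lamb, lamb_bar = 1e-6, 0.0
    n = theta.size
    p_norm2 = delta = 0.0
    for k in range(1, max_iter + 1):
        if success:
            mu = float(p @ r)
            if mu <= 0:  # not a descent direction: restart
                p = r.copy()
                mu = float(p @ r)
            p_norm2 = float(p @ p)
            if p_norm2 < 1e-300 or np.sqrt(float(r @ r)) < grad_tol:
                costs.extend([f] * (max_iter - k + 1))
                break
            sigma = sigma0 / np.sqrt(p_norm2)
            _, g_sig = fun(theta + sigma * p)
            delta = float(p @ (g_sig - g)) / sigma
        delta_k = delta + (lamb - lamb_bar) * p_norm2
        if delta_k <= 0:  # make the Hessian approximation positive definite
            lamb_bar = 2.0 * (lamb - delta_k / p_norm2)
            delta_k = -delta_k + lamb * p_norm2
            lamb = lamb_bar
        mu = float(p @ r)
        alpha = mu / delta_k
        f_new, g_new = fun(theta + alpha * p)
        if not np.isfinite(f_new):
            raise DivergenceError(f"non-finite cost at epoch {k}")
        comparison = 2.0 * delta_k * (f - f_new) / (mu ** 2)
        if comparison >= 0:
            theta = theta + alpha * p
            f = f_new
            r_new = -g_new
            g = g_new
            lamb_bar = 0.0
            success = True
            if k % n == 0:
                p = r_new.copy()
            else:
                beta_cg = (float(r_new @ r_new) - float(r_new @ r)) / mu
                p = r_new + beta_cg * p
            r = r_new
            if comparison >= 0.75:
                lamb = max(lamb * 0.25, 1e-30)
        else:
            lamb_bar = lamb
            success = False
        if comparison < 0.25:
            lamb = min(lamb + delta_k * (1.0 - comparison) / p_norm2, 1e100)
        costs.append(f)
    return theta, costs


def gd_minimize(fun, theta0: np.ndarray, max_iter: int, learning_rate: float):
    """Plain full-batch gradient descent with a fixed step size."""
    theta = np.asarray(theta0, dtype=float).copy()
    f, g = fun(theta)
    costs = [f]
    for k in range(1, max_iter + 1):
        theta = theta - learning_rate * g
        f, g = fun(theta)
        if not np.isfinite(f):
            raise DivergenceError(f"non-finite cost at epoch {k}")
        costs.append(f)
    return theta, costs


def _minimize(fun, theta0, epochs, config: TrainingConfig):
    if config.optimizer == "scg":
        # eta scales SCG's second-order probe step; eta=0.01 -> Moller's 1e-5
        return scg_minimize(fun, theta0, epochs, sigma0=config.learning_rate / 1000.0)
    return gd_minimize(fun, theta0, epochs, config.learning_rate)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def train_autoencoder(X: np.ndarray, arch: NetworkArchitecture,
                      config: TrainingConfig) -> AutoencoderModel:
    """Train the sparse autoencoder on normalised spectra (full batch)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 0:
        raise ValueError("empty training matrix")
    if X.shape[1] != arch.n_input:
        raise ValueError(f"expected {arch.n_input} channels, got {X.shape[1]}")
    layers = arch.ae_layers
    rng = np.random.default_rng(config.seed)
    theta0 = _pack(*_init_params(layers, rng))
    fun = lambda th: _ae_cost_grad(th, layers, X, config.l2_coefficient,
                                   config.sparsity_coefficient, config.sparsity_target)
    theta, costs = _minimize(fun, theta0, config.epochs_ae, config)
    weights, biases = _unpack(theta, layers)
    return AutoencoderModel(layers, weights, biases, cost_history=costs)


def encode(model: AutoencoderModel, X: np.ndarray) -> np.ndarray:
    """Bottleneck features: forward pass through the encoder half."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.layers[0]:
        raise ValueError(f"expected {model.layers[0]} channels, got {X.shape[1]}")
    return _forward(model.weights[:2], model.biases[:2], X)[-1]


def _derive_seed(seed: int, stream: int) -> int:
    return int((seed * 1_000_003 + stream) % (2 ** 31))


def train_mapping(Z: np.ndarray, Y: np.ndarray, arch: NetworkArchitecture,
                  config: TrainingConfig) -> MappingModel:
    """Train the bottleneck -> odor-group network under cross-entropy."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Z.shape[0] != Y.shape[0]:
        raise ValueError(f"feature rows ({Z.shape[0]}) != label rows ({Y.shape[0]})")
    layers = (Z.shape[1], arch.map_hidden1, arch.map_hidden2, Y.shape[1])
    rng = np.random.default_rng(_derive_seed(config.seed, 1))
    theta0 = _pack(*_init_params(layers, rng))
    fun = lambda th: _map_cost_grad(th, layers, Z, Y, config.l2_coefficient)
    theta, costs = _minimize(fun, theta0, config.epochs_map, config)
    weights, biases = _unpack(theta, layers)
    return MappingModel(layers, weights, biases, cost_history=costs)


# ---------------------------------------------------------------------------
# The composed predictor
# ---------------------------------------------------------------------------

def binarize(probabilities: np.ndarray) -> np.ndarray:
    """Per-group (p, 1-p) softmax pair, argmax -> {0, 1}.

    Equivalent to thresholding each group's sigmoid output at 0.5.
    """
    p = np.asarray(probabilities, dtype=float)
    # argmax over the (p, 1-p) pair; the p = 0.5 tie resolves to presence
    return (p >= 0.5).astype(int)


@dataclass
class OdorPredictor:
    """Encoder + mapping network composed into the 201 -> k predictor."""

    autoencoder: AutoencoderModel
    mapping: MappingModel

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.mapping.predict_proba(encode(self.autoencoder, X))


def predict_groups(predictor: OdorPredictor, x: np.ndarray) -> np.ndarray:
    """Binary odor-descriptor-group presence for one spectrum or a matrix."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    out = binarize(predictor.predict_proba(np.atleast_2d(x)))
    return out[0] if single else out


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_predictor(predictor: OdorPredictor, path, *, arch: NetworkArchitecture | None = None,
                   config: TrainingConfig | None = None) -> None:
    """Single-archive checkpoint: layer shapes, optional config, weight arrays."""
    meta = {
        "ae_layers": list(predictor.autoencoder.layers),
        "map_layers": list(predictor.mapping.layers),
        "arch": None if arch is None else arch.__dict__,
        "config": None if config is None else config.__dict__,
    }
    arrays = {"meta": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)}
    for i, (w, b) in enumerate(zip(predictor.autoencoder.weights,
                                   predictor.autoencoder.biases)):
        arrays[f"ae_W{i}"], arrays[f"ae_b{i}"] = w, b
    for i, (w, b) in enumerate(zip(predictor.mapping.weights, predictor.mapping.biases)):
        arrays[f"map_W{i}"], arrays[f"map_b{i}"] = w, b
    np.savez(path, **arrays)


def load_predictor(path) -> OdorPredictor:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        ae_layers = tuple(meta["ae_layers"])
        map_layers = tuple(meta["map_layers"])
        ae = AutoencoderModel(
            ae_layers,
            [data[f"ae_W{i}"] for i in range(len(ae_layers) - 1)],
            [data[f"ae_b{i}"] for i in range(len(ae_layers) - 1)])
        mapper = MappingModel(
            map_layers,
            [data[f"map_W{i}"] for i in range(len(map_layers) - 1)],
            [data[f"map_b{i}"] for i in range(len(map_layers) - 1)])
    return OdorPredictor(ae, mapper)
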