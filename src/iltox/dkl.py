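"""Deep-kernel Gaussian-process regression.

The model is a GP whose RBF base kernel acts on the output of a learned
neural feature map g(x, w): k(x_i, x_j) = s^2 exp(-||g(x_i) - g(x_j)||^2 /
(2 l^2)).  Network weights w, kernel hyperparameters (l, s^2) and the noise
variance sigma^2 are learnt jointly by full-batch gradient ascent on the
log marginal likelihood

    L = -1/2 y^T (K + sigma^2 I)^-1 y - 1/2 log|K + sigma^2 I| - n/2 log 2pi

with all gradients computed analytically: dL/dK = 1/2 (a a^T - A^-1) with
a = A^-1 y is chained through the kernel into the latent coordinates and
then backpropagated through the network.

During training the Gram matrix may be replaced by a structured-kernel-
interpolation (SKI) approximation W K_UU W^T over a regular grid of
inducing points in the low-dimensional latent space, with local cubic
interpolation weights.  Because the RBF kernel and the interpolation
weights both factorize over latent dimensions, the SKI Gram is computed as
an elementwise (Hadamard) product of small per-dimension factors and never
materializes K_UU.  Prediction always uses the exact GP posterior on the
cached training latents — at the few hundred training points typical here,
exactness costs nothing.

The public surface follows the statsmodels convention: build a
:class:`DeepKernelGP` from data, call :meth:`~DeepKernelGP.fit`, and work
with the returned :class:`DeepKernelGPResults`.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.spatial.distance import cdist
from scipy import sparse

__all__ = [
    "NetworkConfig",
    "KernelHyperparams",
    "GridConfig",
    "PredictiveDistribution",
    "DeepKernelGP",
    "DeepKernelGPResults",
    "NumericalError",
    "rbf_kernel",
    "log_marginal_likelihood",
    "lml_and_gradients",
    "build_ski_covariance",
    "init_network",
    "nn_forward",
    "fit_dkl",
    "predict",
    "sample_posterior",
]

LOG2PI = float(np.log(2.0 * np.pi))


class NumericalError(RuntimeError):
    """Raised when a covariance factorization fails beyond the jitter budget."""


# ---------------------------------------------------------------------------
# configuration containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NetworkConfig:
    """Architecture of the feature network g(x, w).

    Default: 310 inputs through four hidden layers of 163 units into a
    2-unit latent layer, LeakyReLU (slope 0.01) on hidden layers, linear
    output.
    """

    layer_sizes: tuple[int, ...] = (310, 163, 163, 163, 163, 2)
    activation: str = "leaky_relu"
    negative_slope: float = 0.01

    def __post_init__(self):
        if len(self.layer_sizes) < 2:
            raise ValueError("network needs at least input and output sizes")
        if self.layer_sizes[-1] != 2:
            raise ValueError("the final (latent) layer must have 2 units")
        if self.activation not in ("relu", "leaky_relu", "tanh"):
            raise ValueError(f"unknown activation {self.activation!r}")

    @property
    def latent_dim(self) -> int:
        return self.layer_sizes[-1]


@dataclass(frozen=True)
class KernelHyperparams:
    """RBF kernel hyperparameters: lengthscale l and output scale s^2."""

    lengthscale: float = 1.0
    outputscale: float = 1.0

    def __post_init__(self):
        if self.lengthscale <= 0 or self.outputscale <= 0:
            raise ValueError("kernel hyperparameters must be strictly positive")


@dataclass(frozen=True)
class GridConfig:
    """Inducing-point grid for structured kernel interpolation.

    ``points_per_dim`` grid nodes per latent dimension (default 35, i.e.
    35^2 = 1225 inducing points in the 2-d latent space); ``bounds`` is the
    per-dimension (low, high) data range the grid must cover, or None to
    derive it from the training latents (padded by 10%) each iteration.
    """

    points_per_dim: int = 35
    bounds: Optional[tuple[tuple[float, float], ...]] = None
    interpolation: str = "local_cubic"

    def __post_init__(self):
        if self.points_per_dim < 4:
            raise ValueError("local cubic interpolation needs >= 4 points per dim")
        if self.bounds is not None:
            for lo, hi in self.bounds:
                if not lo < hi:
                    raise ValueError("grid bounds need low < high in every dimension")
        if self.interpolation != "local_cubic":
            raise ValueError("only local cubic interpolation is implemented")


@dataclass
class PredictiveDistribution:
    """Per-query GP posterior on the original logEC50 scale.

    ``latent_sd`` is the posterior sd of the noise-free latent function;
    ``predictive_sd`` additionally carries the learnt observation noise,
    predictive_sd^2 = latent_sd^2 + sigma^2.
    """

    mean: np.ndarray
    latent_sd: np.ndarray
    predictive_sd: np.ndarray
    samples: Optional[np.ndarray] = None  # (n_samples, n_queries)


# ---------------------------------------------------------------------------
# neural feature map
# ---------------------------------------------------------------------------

def init_network(config: NetworkConfig, seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Fan-in-scaled uniform weight init, zero biases, seeded."""
    rng = np.random.default_rng(seed)
    weights = []
    for fan_in, fan_out in zip(config.layer_sizes[:-1], config.layer_sizes[1:]):
        bound = 1.0 / np.sqrt(fan_in)
        w = rng.uniform(-bound, bound, size=(fan_in, fan_out))
        b = np.zeros(fan_out)
        weights.append((w, b))
    return weights


def _act(s: np.ndarray, config: NetworkConfig) -> np.ndarray:
    if config.activation == "relu":
        return np.maximum(s, 0.0)
    if config.activation == "leaky_relu":
        return np.where(s > 0, s, config.negative_slope * s)
    return np.tanh(s)


def _act_grad(s: np.ndarray, config: NetworkConfig) -> np.ndarray:
    if config.activation == "relu":
        return (s > 0).astype(float)
    if config.activation == "leaky_relu":
        return np.where(s > 0, 1.0, config.negative_slope)
    return 1.0 - np.tanh(s) ** 2


def nn_forward(weights: Sequence[tuple[np.ndarray, np.ndarray]],
               config: NetworkConfig,
               x: np.ndarray,
               return_cache: bool = False):
    """Map (standardized) inputs through the feature network.

    Accepts a single vector or an (n, p) matrix; hidden layers use the
    configured activation, the final latent layer is linear.
    """
    single = x.ndim == 1
    a = np.atleast_2d(np.asarray(x, dtype=float))
    if a.shape[1] != config.layer_sizes[0]:
        raise ValueError(
            f"input has {a.shape[1]} features, network expects {config.layer_sizes[0]}")
    pre, post = [], [a]
    n_layers = len(weights)
    for idx, (w, b) in enumerate(weights):
        s = a @ w + b
        pre.append(s)
        a = s if idx == n_layers - 1 else _act(s, config)
        post.append(a)
    out = a[0] if single else a
    if return_cache:
        return out, (pre, post)
    return out


def _nn_backward(weights, config: NetworkConfig, cache, d_latent: np.ndarray):
    """Backpropagate dL/dZ through the network; returns per-layer (dW, db)."""
    pre, post = cache
    grads: list[tuple[np.ndarray, np.ndarray]] = [None] * len(weights)
    delta = d_latent
    for idx in range(len(weights) - 1, -1, -1):
        w, _ = weights[idx]
        grads[idx] = (post[idx].T @ delta, delta.sum(axis=0))
        if idx > 0:
            delta = (delta @ w.T) * _act_grad(pre[idx - 1], config)
    return grads


# ---------------------------------------------------------------------------
# kernel and marginal likelihood
# ---------------------------------------------------------------------------

def rbf_kernel(z1: np.ndarray, z2: np.ndarray,
               params: KernelHyperparams) -> np.ndarray | float:
    """RBF covariance s^2 exp(-||z1 - z2||^2 / (2 l^2)).

    1-d inputs are treated as single points (returns a scalar); 2-d inputs
    as point sets (returns the Gram matrix).
    """
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    scalar = z1.ndim == 1 and z2.ndim == 1
    d2 = cdist(np.atleast_2d(z1), np.atleast_2d(z2), "sqeuclidean")
    k = params.outputscale * np.exp(-d2 / (2.0 * params.lengthscale ** 2))
    return float(k[0, 0]) if scalar else k


def _chol_with_jitter(a: np.ndarray, jitter0: float = 1e-8,
                      jitter_max: float = 1e-4):
    """Lower Cholesky factor with escalating diagonal jitter (x10 steps)."""
    try:
        return np.linalg.cholesky(a), 0.0
    except np.linalg.LinAlgError:
        pass
    jitter = jitter0
    scale = float(np.mean(np.diag(a))) or 1.0
    while jitter <= jitter_max * (1 + 1e-12):
        try:
            return np.linalg.cholesky(a + jitter * scale * np.eye(a.shape[0])), jitter
        except np.linalg.LinAlgError:
            jitter *= 10.0
    cond = np.linalg.cond(a)
    raise NumericalError(
        f"covariance factorization failed at jitter {jitter_max:g} "
        f"(condition number {cond:.3g})")


def log_marginal_likelihood(y: np.ndarray, k: np.ndarray, sigma2: float) -> float:
    """GP evidence -1/2 y^T A^-1 y - 1/2 log|A| - n/2 log 2pi, A = K + sigma^2 I."""
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    a = np.asarray(k, dtype=float) + sigma2 * np.eye(n)
    low, _ = _chol_with_jitter(a)
    alpha = solve_triangular(low.T, solve_triangular(low, y, lower=True), lower=False)
    return float(-0.5 * y @ alpha - np.log(np.diag(low)).sum() - 0.5 * n * LOG2PI)


def _gram_backward(y: np.ndarray, a: np.ndarray):
    """Shared pieces of every LML gradient: alpha, A^-1 and dL/dK.

    dL/dK = 1/2 (alpha alpha^T - A^-1), the implicit derivative of the log
    marginal likelihood with respect to the data covariance.
    """
    low, _ = _chol_with_jitter(a)
    n = a.shape[0]
    alpha = solve_triangular(low.T, solve_triangular(low, y, lower=True), lower=False)
    a_inv = cho_solve((low, True), np.eye(n))
    lml = float(-0.5 * y @ alpha - np.log(np.diag(low)).sum() - 0.5 * n * LOG2PI)
    g = 0.5 * (np.outer(alpha, alpha) - a_inv)
    return lml, alpha, g


def lml_and_gradients(weights, net_config: Optional[NetworkConfig],
                      kernel: KernelHyperparams, sigma2: float,
                      x: np.ndarray, y: np.ndarray):
    """Exact-covariance LML and its gradients.

    Returns ``(lml, grads)`` where grads holds ``d_log_lengthscale``,
    ``d_log_outputscale``, ``d_log_noise`` (derivatives with respect to the
    unconstrained log-scale parameters) and ``d_weights`` (per-layer (dW,
    db), or None for the identity feature map).  Used directly by the
    trainer; the test suite checks every component against central finite
    differences.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if net_config is None:
        z, cache = np.asarray(x, dtype=float), None
    else:
        z, cache = nn_forward(weights, net_config, x, return_cache=True)
    ell, s2 = kernel.lengthscale, kernel.outputscale
    d2 = cdist(z, z, "sqeuclidean")
    k = s2 * np.exp(-d2 / (2.0 * ell ** 2))
    lml, _, g = _gram_backward(y, k + sigma2 * np.eye(n))

    gk = g * k
    grads = {
        "d_log_lengthscale": float((gk * d2).sum() / ell ** 2),
        "d_log_outputscale": float(gk.sum()),
        "d_log_noise": float(np.trace(g) * sigma2),
        "d_weights": None,
    }
    # dL/dz_i = 2/l^2 sum_j (G o K)_ij (z_j - z_i)
    row = gk.sum(axis=1)
    d_z = 2.0 / ell ** 2 * (gk @ z - row[:, None] * z)
    grads["d_latent"] = d_z
    if net_config is not None:
        grads["d_weights"] = _nn_backward(weights, net_config, cache, d_z)
    return lml, grads


# ---------------------------------------------------------------------------
# structured kernel interpolation
# ---------------------------------------------------------------------------

def _cubic_weights(u: np.ndarray):
    """Keys cubic-convolution weights (a = -1/2) and their u-derivatives.

    For a point at fractional position u in [0, 1] between nodes i and
    i+1, returns the weights on nodes (i-1, i, i+1, i+2).  The weights sum
    to one for every u (partition of unity) and interpolate exactly on the
    nodes.
    """
    a = -0.5
    u = np.asarray(u, dtype=float)

    def h_far(s):       # 1 <= s < 2
        return a * s ** 3 - 5 * a * s ** 2 + 8 * a * s - 4 * a

    def h_near(s):      # 0 <= s <= 1
        return (a + 2) * s ** 3 - (a + 3) * s ** 2 + 1

    def dh_far(s):
        return 3 * a * s ** 2 - 10 * a * s + 8 * a

    def dh_near(s):
        return 3 * (a + 2) * s ** 2 - 2 * (a + 3) * s

    w = np.stack([h_far(1 + u), h_near(u), h_near(1 - u), h_far(2 - u)], axis=-1)
    dw = np.stack([dh_far(1 + u), dh_near(u), -dh_near(1 - u), -dh_far(2 - u)], axis=-1)
    return w, dw


def _grid_nodes(lo: float, hi: float, m: int) -> tuple[np.ndarray, float]:
    """Place m nodes so that [lo, hi] sits inside the cubic stencil range."""
    span = hi - lo
    if span <= 0:
        span = 1.0
    h = span / (m - 3)
    nodes = (lo - h) + h * np.arange(m)
    return nodes, h


def _interp_1d(z: np.ndarray, nodes: np.ndarray, h: float):
    """Stencil indices, weights and dweights/dz for each 1-d coordinate."""
    m = nodes.size
    t = (z - nodes[0]) / h
    i = np.floor(t).astype(int)
    i = np.clip(i, 1, m - 3)
    u = t - i
    if np.any(u < -1e-9) or np.any(u > 1 + 1e-9):
        raise ValueError(
            "latent point outside the inducing grid bounds; re-fit the grid "
            "bounds to cover the data")
    u = np.clip(u, 0.0, 1.0)
    w, dw = _cubic_weights(u)
    idx = i[:, None] + np.array([-1, 0, 1, 2])[None, :]
    return idx, w, dw / h


def _auto_bounds(z: np.ndarray, pad: float = 0.10):
    out = []
    for d in range(z.shape[1]):
        lo, hi = float(z[:, d].min()), float(z[:, d].max())
        span = (hi - lo) or 1.0
        out.append((lo - pad * span, hi + pad * span))
    return tuple(out)


def build_ski_covariance(z: np.ndarray, grid: GridConfig,
                         params: KernelHyperparams):
    """Interpolation weights W and inducing-point kernel K_UU of the SKI
    approximation K ~= W K_UU W^T.

    ``z`` is (n, d) with d = 1 or 2; W is a sparse (n, m^d) matrix with at
    most 4^d nonzeros per row (rows sum to 1), K_UU the dense RBF kernel on
    the Cartesian-product grid (dimension-0-major ordering).
    """
    z = np.atleast_2d(np.asarray(z, dtype=float))
    n, d = z.shape
    if d not in (1, 2):
        raise ValueError("SKI grids are built over 1- or 2-d latent spaces")
    bounds = grid.bounds if grid.bounds is not None else _auto_bounds(z)
    if len(bounds) != d:
        raise ValueError("grid bounds dimensionality does not match latents")
    m = grid.points_per_dim

    per_dim = []
    for dd in range(d):
        nodes, h = _grid_nodes(*bounds[dd], m)
        idx, w, dw = _interp_1d(z[:, dd], nodes, h)
        per_dim.append((nodes, idx, w))

    if d == 1:
        nodes, idx, w = per_dim[0]
        rows = np.repeat(np.arange(n), 4)
        wmat = sparse.csr_matrix((w.ravel(), (rows, idx.ravel())), shape=(n, m))
        kuu = rbf_kernel(nodes[:, None], nodes[:, None], params)
        return wmat, kuu

    (nodes1, idx1, w1), (nodes2, idx2, w2) = per_dim
    cols = (idx1[:, :, None] * m + idx2[:, None, :]).reshape(n, 16)
    vals = (w1[:, :, None] * w2[:, None, :]).reshape(n, 16)
    rows = np.repeat(np.arange(n), 16)
    wmat = sparse.csr_matrix((vals.ravel(), (rows, cols.ravel())), shape=(n, m * m))
    grid_pts = np.column_stack([np.repeat(nodes1, m), np.tile(nodes2, m)])
    kuu = rbf_kernel(grid_pts, grid_pts, params)
    return wmat, kuu


def _ski_factors(z: np.ndarray, grid: GridConfig, params: KernelHyperparams):
    """Per-dimension pieces of the SKI Gram, exploiting the product
    structure of the RBF kernel over latent dimensions.

    With W_d the n x m interpolation matrix of dimension d and K_d the 1-d
    kernel on that dimension's nodes, the SKI Gram is the Hadamard product
    over dimensions of A_d = W_d K_d W_d^T (output scale applied once).
    """
    z = np.atleast_2d(z)
    n, d = z.shape
    bounds = grid.bounds if grid.bounds is not None else _auto_bounds(z)
    m = grid.points_per_dim
    ell2 = params.lengthscale ** 2
    factors = []
    for dd in range(d):
        nodes, h = _grid_nodes(*bounds[dd], m)
        idx, w, dw = _interp_1d(z[:, dd], nodes, h)
        d2 = (nodes[:, None] - nodes[None, :]) ** 2
        k1 = np.exp(-d2 / (2.0 * ell2))
        wd = np.zeros((n, m))
        wd[np.arange(n)[:, None], idx] = w
        wderiv = np.zeros((n, m))
        wderiv[np.arange(n)[:, None], idx] = dw
        factors.append({"k1": k1, "d2": d2, "w": wd, "dw": wderiv})
    return factors


def _lml_and_gradients_ski(weights, net_config: Optional[NetworkConfig],
                           kernel: KernelHyperparams, sigma2: float,
                           x: np.ndarray, y: np.ndarray, grid: GridConfig):
    """LML and gradients with the SKI Gram in place of the exact one.

    Grid bounds are held fixed while differentiating (when auto-derived
    they are refreshed from the latents at each call, a standard
    stop-gradient treatment).
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if net_config is None:
        z, cache = np.asarray(x, dtype=float), None
    else:
        z, cache = nn_forward(weights, net_config, x, return_cache=True)
    z = np.atleast_2d(z)
    d = z.shape[1]
    ell, s2 = kernel.lengthscale, kernel.outputscale
    factors = _ski_factors(z, grid, kernel)

    parts = [f["w"] @ f["k1"] @ f["w"].T for f in factors]      # A_d, n x n
    k = s2 * np.prod(parts, axis=0)
    lml, _, g = _gram_backward(y, k + sigma2 * np.eye(n))

    # d/dlog l of each 1-d kernel is k1 o d2 / l^2; product rule over dims.
    d_log_ell = 0.0
    for dd, f in enumerate(factors):
        dk1 = f["k1"] * f["d2"] / ell ** 2
        dpart = f["w"] @ dk1 @ f["w"].T
        other = s2 * np.prod([parts[j] for j in range(d) if j != dd], axis=0) \
            if d > 1 else s2
        d_log_ell += float((g * dpart * other).sum())

    grads = {
        "d_log_lengthscale": d_log_ell,
        "d_log_outputscale": float((g * k).sum()),
        "d_log_noise": float(np.trace(g) * sigma2),
        "d_weights": None,
    }

    # dL/dz through the interpolation weights of that coordinate's factor.
    d_z = np.zeros_like(z)
    for dd, f in enumerate(factors):
        b = f["dw"] @ f["k1"] @ f["w"].T                         # n x n
        other = s2 * np.prod([parts[j] for j in range(d) if j != dd], axis=0) \
            if d > 1 else s2 * np.ones((n, n))
        d_z[:, dd] = 2.0 * (g * other * b).sum(axis=1)
    grads["d_latent"] = d_z
    if net_config is not None:
        grads["d_weights"] = _nn_backward(weights, net_config, cache, d_z)
    return lml, grads


# ---------------------------------------------------------------------------
# optimizers (full-batch, ascent on the LML)
# ---------------------------------------------------------------------------

class _Optimizer:
    def __init__(self, kind: str, lr: float):
        if kind not in ("sgd", "rmsprop", "adam"):
            raise ValueError(f"unknown optimizer {kind!r}")
        self.kind = kind
        self.lr = lr
        self.state: dict[int, tuple] = {}
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]):
        """In-place ascent step (gradients point uphill)."""
        self.t += 1
        for i, (p, gr) in enumerate(zip(params, grads)):
            if self.kind == "sgd":
                p += self.lr * gr
            elif self.kind == "rmsprop":
                sq = self.state.get(i, np.zeros_like(p))
                sq = 0.99 * sq + 0.01 * gr * gr
                self.state[i] = sq
                p += self.lr * gr / (np.sqrt(sq) + 1e-8)
            else:  # adam
                m, v = self.state.get(i, (np.zeros_like(p), np.zeros_like(p)))
                m = 0.9 * m + 0.1 * gr
                v = 0.999 * v + 0.001 * gr * gr
                self.state[i] = (m, v)
                mhat = m / (1 - 0.9 ** self.t)
                vhat = v / (1 - 0.999 ** self.t)
                p += self.lr * mhat / (np.sqrt(vhat) + 1e-8)


# ---------------------------------------------------------------------------
# model and results
# ---------------------------------------------------------------------------

class DeepKernelGP:
    """Deep-kernel GP regression model for logEC50 prediction.

    Parameters
    ----------
    endog : (n,) measured targets (logEC50)
    exog : (n, p) feature matrix; p must match the network input size
    network : NetworkConfig, or None for the identity feature map (the GP
        then acts directly on the standardized features; useful for oracle
        checks and 1-/2-d problems)
    grid : GridConfig for SKI training (ignored with covariance="exact")

    Examples
    --------
    >>> model = DeepKernelGP(y, X)
    >>> res = model.fit(n_iter=1000, seed=0)
    >>> dist = res.predict(X_new)
    """

    def __init__(self, endog, exog, network: Optional[NetworkConfig] = NetworkConfig(),
                 grid: GridConfig = GridConfig()):
        y = np.asarray(endog, dtype=float).ravel()
        x = np.atleast_2d(np.asarray(exog, dtype=float))
        if x.shape[0] != y.size:
            raise ValueError("endog and exog have different numbers of rows")
        if y.size < 5:
            raise ValueError("need at least 5 observations")
        if not (np.all(np.isfinite(y)) and np.all(np.isfinite(x))):
            raise ValueError("non-finite values in the training data")
        if network is not None and x.shape[1] != network.layer_sizes[0]:
            raise ValueError(
                f"exog has {x.shape[1]} columns but the network expects "
                f"{network.layer_sizes[0]} inputs")
        if network is None and x.shape[1] > 2:
            raise ValueError("identity feature map requires <= 2 feature columns")
        self.endog = y
        self.exog = x
        self.network = network
        self.grid = grid

    @classmethod
    def from_dataframe(cls, df, label_col: str = "logEC50",
                       feature_cols: Optional[Sequence[str]] = None, **kwargs):
        feats = [c for c in df.columns if c != label_col] if feature_cols is None \
            else list(feature_cols)
        return cls(df[label_col].to_numpy(), df[feats].to_numpy(), **kwargs)

    # -- training ----------------------------------------------------------

    def fit(self, optimizer: str = "rmsprop", learning_rate: float = 0.0130925,
            n_iter: int = 1000, seed: int = 0, covariance: str = "ski",
            init_kernel: KernelHyperparams = KernelHyperparams(),
            init_noise: float = 0.1,
            init_weights: Optional[list] = None,
            callback: Optional[Callable[[int, float], None]] = None
            ) -> "DeepKernelGPResults":
        """Maximize the log marginal likelihood over {w, l, s^2, sigma^2}.

        Features and targets are z-scored internally with training
        statistics (zero-variance feature columns pass through unscaled).
        ``covariance`` selects the training Gram: "ski" (structured kernel
        interpolation on the latent grid) or "exact".  Reproducible for a
        fixed seed; the LML trace is recorded on the results object.
        ``init_weights`` warm-starts the network in place of the seeded
        fan-in initialization.
        """
        if covariance not in ("ski", "exact"):
            raise ValueError("covariance must be 'ski' or 'exact'")
        use_scaling = covariance == "ski"
        x_mean = self.exog.mean(axis=0)
        x_sd = self.exog.std(axis=0)
        x_sd = np.where(x_sd > 0, x_sd, 1.0)
        y_mean = float(self.endog.mean())
        y_sd = float(self.endog.std()) or 1.0
        xs = (self.exog - x_mean) / x_sd
        ys = (self.endog - y_mean) / y_sd

        if self.network is None:
            weights = None
        elif init_weights is not None:
            weights = [(np.array(w, dtype=float), np.array(b, dtype=float))
                       for w, b in init_weights]
        else:
            weights = init_network(self.network, seed)
        log_ell = float(np.log(init_kernel.lengthscale))
        log_s2 = float(np.log(init_kernel.outputscale))
        log_sig2 = float(np.log(init_noise))

        opt = _Optimizer(optimizer, learning_rate)
        trace: list[float] = []

        def flat_params():
            hyper = [np.array([log_ell]), np.array([log_s2]), np.array([log_sig2])]
            if weights is None:
                return hyper
            return hyper + [arr for pair in weights for arr in pair]

        # With SKI the latent batch is affinely rescaled to [-1, 1] per
        # dimension before the grid kernel (the grid then has fixed bounds,
        # padded 10%).  Without this, nothing anchors the latent scale: the
        # network can inflate latent distances past the grid resolution and
        # the optimizer climbs approximation error instead of evidence.
        lat_dim = self.exog.shape[1] if self.network is None else self.network.latent_dim
        lat_shift = np.zeros(lat_dim)
        lat_scale = np.ones(lat_dim)
        grid = self.grid
        if use_scaling and grid.bounds is None:
            d = self.exog.shape[1] if self.network is None else self.network.latent_dim
            grid = GridConfig(points_per_dim=grid.points_per_dim,
                              bounds=((-1.1, 1.1),) * d,
                              interpolation=grid.interpolation)

        def scaled(z):
            return (z - lat_shift) * lat_scale

        for it in range(n_iter):
            kern = KernelHyperparams(float(np.exp(log_ell)), float(np.exp(log_s2)))
            sig2 = float(np.exp(log_sig2))
            if covariance == "exact":
                lml, grads = lml_and_gradients(
                    weights, self.network, kern, sig2, xs, ys)
            else:
                if self.network is None:
                    z_raw, cache = xs, None
                else:
                    z_raw, cache = nn_forward(weights, self.network, xs,
                                              return_cache=True)
                z_raw = np.atleast_2d(z_raw)
                lo, hi = z_raw.min(axis=0), z_raw.max(axis=0)
                span = np.where(hi > lo, hi - lo, 1.0)
                lat_shift = (lo + hi) / 2.0
                lat_scale = 2.0 / span
                lml, grads = _lml_and_gradients_ski(
                    None, None, kern, sig2, scaled(z_raw), ys, grid)
                # chain dL/d(scaled z) back through the affine (shift and
                # scale held constant within the iteration) into the network
                if self.network is not None:
                    grads["d_weights"] = _nn_backward(
                        weights, self.network, cache,
                        grads["d_latent"] * lat_scale)
            if not np.isfinite(lml):
                raise NumericalError(
                    f"log marginal likelihood became non-finite at iteration {it}")
            trace.append(lml)
            if callback is not None:
                callback(it, lml)

            params = flat_params()
            glist = [np.array([grads["d_log_lengthscale"]]),
                     np.array([grads["d_log_outputscale"]]),
                     np.array([grads["d_log_noise"]])]
            if weights is not None:
                glist += [arr for pair in grads["d_weights"] for arr in pair]
            opt.step(params, glist)
            log_ell, log_s2, log_sig2 = (float(params[0][0]), float(params[1][0]),
                                         float(params[2][0]))
            if weights is not None:
                weights = [(params[3 + 2 * i], params[4 + 2 * i])
                           for i in range(len(weights))]

        kern = KernelHyperparams(float(np.exp(log_ell)), float(np.exp(log_s2)))
        sig2 = float(np.exp(log_sig2))
        z_raw = np.atleast_2d(
            xs if self.network is None else nn_forward(weights, self.network, xs))
        if use_scaling and n_iter > 0:
            lo, hi = z_raw.min(axis=0), z_raw.max(axis=0)
            span = np.where(hi > lo, hi - lo, 1.0)
            lat_shift = (lo + hi) / 2.0
            lat_scale = 2.0 / span
        return DeepKernelGPResults(
            model=self, weights=weights, kernel=kern, noise_variance=sig2,
            x_mean=x_mean, x_sd=x_sd, y_mean=y_mean, y_sd=y_sd,
            latent_train=scaled(z_raw), y_train_std=ys,
            lml_trace=np.array(trace), seed=seed, covariance=covariance,
            latent_shift=lat_shift, latent_scale=lat_scale)


class DeepKernelGPResults:
    """Fitted deep-kernel GP: parameters, training cache and predictions.

    Prediction uses the exact GP posterior on the cached training latents:
    mean = k_*^T A^-1 y, latent variance = k_** - k_*^T A^-1 k_*, with
    A = K + sigma^2 I on the training set, all computed on the
    standardized scale and mapped back to logEC50 units.
    """

    def __init__(self, model: Optional[DeepKernelGP], weights, kernel: KernelHyperparams,
                 noise_variance: float, x_mean, x_sd, y_mean, y_sd,
                 latent_train, y_train_std, lml_trace, seed: int,
                 covariance: str, network: Optional[NetworkConfig] = "from_model",
                 latent_shift=None, latent_scale=None):
        self.model = model
        self.network = model.network if network == "from_model" else network
        self.weights = weights
        self.kernel = kernel
        self.noise_variance = float(noise_variance)
        self.x_mean = np.asarray(x_mean, dtype=float)
        self.x_sd = np.asarray(x_sd, dtype=float)
        self.y_mean = float(y_mean)
        self.y_sd = float(y_sd)
        self.latent_train = np.atleast_2d(latent_train)
        self.y_train_std = np.asarray(y_train_std, dtype=float).ravel()
        self.lml_trace = np.asarray(lml_trace, dtype=float)
        self.seed = seed
        self.covariance = covariance
        d = self.latent_train.shape[1]
        self.latent_shift = np.zeros(d) if latent_shift is None \
            else np.asarray(latent_shift, dtype=float)
        self.latent_scale = np.ones(d) if latent_scale is None \
            else np.asarray(latent_scale, dtype=float)
        self._factorize()

    def _factorize(self):
        k = rbf_kernel(self.latent_train, self.latent_train, self.kernel)
        a = k + self.noise_variance * np.eye(k.shape[0])
        self._chol, _ = _chol_with_jitter(a)
        self._alpha = solve_triangular(
            self._chol.T, solve_triangular(self._chol, self.y_train_std, lower=True),
            lower=False)

    @property
    def lml(self) -> float:
        """Final training log marginal likelihood (standardized scale)."""
        if self.lml_trace.size:
            return float(self.lml_trace[-1])
        return log_marginal_likelihood(
            self.y_train_std,
            rbf_kernel(self.latent_train, self.latent_train, self.kernel),
            self.noise_variance)

    def latent(self, x: np.ndarray) -> np.ndarray:
        """Map raw features through standardization, the feature network and
        the training-time latent rescaling."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        xs = (x - self.x_mean) / self.x_sd
        z = xs if self.network is None else \
            np.atleast_2d(nn_forward(self.weights, self.network, xs))
        return (z - self.latent_shift) * self.latent_scale

    def predict(self, x_query: np.ndarray,
                samples: Optional[int] = None,
                seed: int = 0) -> PredictiveDistribution:
        """Posterior mean and uncertainty for each query, in logEC50 units."""
        zq = self.latent(x_query)
        k_star = rbf_kernel(zq, self.latent_train, self.kernel)
        mean_s = k_star @ self._alpha
        v = solve_triangular(self._chol, k_star.T, lower=True)
        latent_var = np.maximum(self.kernel.outputscale - (v ** 2).sum(axis=0), 1e-12)
        pred_var = latent_var + self.noise_variance
        dist = PredictiveDistribution(
            mean=mean_s * self.y_sd + self.y_mean,
            latent_sd=np.sqrt(latent_var) * self.y_sd,
            predictive_sd=np.sqrt(pred_var) * self.y_sd)
        if samples is not None:
            dist.samples = self.sample_posterior(x_query, samples, seed)
        return dist

    def sample_posterior(self, x_query: np.ndarray, n_samples: int = 20,
                         seed: int = 0) -> np.ndarray:
        """Joint draws from the noisy predictive Gaussian, (n_samples, q)."""
        zq = self.latent(x_query)
        k_star = rbf_kernel(zq, self.latent_train, self.kernel)
        mean_s = k_star @ self._alpha
        v = solve_triangular(self._chol, k_star.T, lower=True)
        cov = rbf_kernel(zq, zq, self.kernel) - v.T @ v \
            + self.noise_variance * np.eye(zq.shape[0])
        low, _ = _chol_with_jitter(cov)
        rng = np.random.default_rng(seed)
        eps = rng.standard_normal((n_samples, zq.shape[0]))
        draws_s = mean_s[None, :] + eps @ low.T
        return draws_s * self.y_sd + self.y_mean

    def summary(self) -> str:
        lines = [
            "Deep-kernel GP regression results",
            "=" * 44,
            f"n training observations   {self.y_train_std.size:>10d}",
            f"feature map               "
            f"{'identity' if self.network is None else 'x'.join(map(str, self.network.layer_sizes))}",
            f"training covariance       {self.covariance:>10s}",
            f"lengthscale (latent)      {self.kernel.lengthscale:>10.4f}",
            f"output scale s^2          {self.kernel.outputscale:>10.4f}",
            f"noise sd (logEC50 units)  {np.sqrt(self.noise_variance) * self.y_sd:>10.4f}",
            f"final log marginal lik.   {self.lml:>10.4f}",
            f"seed                      {self.seed:>10d}",
        ]
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        """Persist everything prediction needs into one .npz archive."""
        header = {
            "format": "iltox-dkl", "version": 1,
            "network": None if self.network is None else {
                "layer_sizes": list(self.network.layer_sizes),
                "activation": self.network.activation,
                "negative_slope": self.network.negative_slope},
            "lengthscale": self.kernel.lengthscale,
            "outputscale": self.kernel.outputscale,
            "noise_variance": self.noise_variance,
            "y_mean": self.y_mean, "y_sd": self.y_sd,
            "seed": self.seed, "covariance": self.covariance,
            "n_layers": 0 if self.weights is None else len(self.weights),
        }
        arrays = {
            "x_mean": self.x_mean, "x_sd": self.x_sd,
            "latent_train": self.latent_train, "y_train_std": self.y_train_std,
            "lml_trace": self.lml_trace,
            "latent_shift": self.latent_shift, "latent_scale": self.latent_scale,
        }
        if self.weights is not None:
            for i, (w, b) in enumerate(self.weights):
                arrays[f"w{i}"] = w
                arrays[f"b{i}"] = b
        np.savez(path, header=json.dumps(header), **arrays)

    @classmethod
    def load(cls, path) -> "DeepKernelGPResults":
        with np.load(path, allow_pickle=False) as arch:
            header = json.loads(str(arch["header"]))
            if header.get("format") != "iltox-dkl":
                raise ValueError(f"{path}: not an iltox model archive")
            net = None
            if header["network"] is not None:
                net = NetworkConfig(
                    layer_sizes=tuple(header["network"]["layer_sizes"]),
                    activation=header["network"]["activation"],
                    negative_slope=header["network"]["negative_slope"])
            weights = None
            if header["n_layers"]:
                weights = [(arch[f"w{i}"], arch[f"b{i}"])
                           for i in range(header["n_layers"])]
                sizes = net.layer_sizes
                for i, (w, _) in enumerate(weights):
                    if w.shape != (sizes[i], sizes[i + 1]):
                        raise ValueError(f"{path}: layer {i} weight shape mismatch")
            return cls(
                model=None, network=net, weights=weights,
                kernel=KernelHyperparams(header["lengthscale"], header["outputscale"]),
                noise_variance=header["noise_variance"],
                x_mean=arch["x_mean"], x_sd=arch["x_sd"],
                y_mean=header["y_mean"], y_sd=header["y_sd"],
                latent_train=arch["latent_train"], y_train_std=arch["y_train_std"],
                lml_trace=arch["lml_trace"], seed=header["seed"],
                covariance=header["covariance"],
                latent_shift=arch["latent_shift"], latent_scale=arch["latent_scale"])


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def fit_dkl(x: np.ndarray, y: np.ndarray,
            net: Optional[NetworkConfig] = NetworkConfig(),
            grid: GridConfig = GridConfig(),
            optimizer: str = "rmsprop", learning_rate: float = 0.0130925,
            n_iter: int = 1000, seed: int = 0,
            covariance: str = "ski", **kwargs) -> DeepKernelGPResults:
    """Convenience wrapper: build a :class:`DeepKernelGP` and fit it."""
    return DeepKernelGP(y, x, network=net, grid=grid).fit(
        optimizer=optimizer, learning_rate=learning_rate, n_iter=n_iter,
        seed=seed, covariance=covariance, **kwargs)


def predict(results: DeepKernelGPResults, x_query: np.ndarray) -> PredictiveDistribution:
    return results.predict(x_query)


def sample_posterior(results: DeepKernelGPResults, x_query: np.ndarray,
                     n_samples: int = 20, seed: int = 0) -> np.ndarray:
    return results.sample_posterior(x_query, n_samples, seed)
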