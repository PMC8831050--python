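"""Base clusterers: Gaussian-mixture EM and the self-organizing map.

Both produce :class:`~updrs.consensus.Partition` objects over the same
rows; ensembles of such partitions (EM at several k, SOM at several map
sizes) are what the consensus functions fuse.

EM alternates the E-step (responsibilities: each row's posterior
probability of belonging to each mixture component) with the M-step
(weight / mean / variance updates that maximise the expected complete
log-likelihood).  The data log-likelihood is nondecreasing across
iterations — that guarantee is asserted in the test suite on every fit.

The SOM trains a small rectangular lattice of prototype vectors
online: for each sample the best-matching node is pulled toward it,
along with its lattice neighbours, under exponentially decaying
learning rate and Gaussian neighbourhood radius.  Each node acts as a
cluster; nodes that win no rows remain as empty clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from sklearn.cluster import kmeans_plusplus

from .consensus import Partition

logger = logging.getLogger(__name__)

VARIANCE_FLOOR_FACTOR = 1e-6


@dataclass
class GaussianMixtureModel:
    k: int
    weights: np.ndarray                 # (k,)
    means: np.ndarray                   # (k, p)
    variances: np.ndarray               # diagonal: (k, p); full: (k, p, p)
    covariance_mode: str
    log_likelihood_trace: np.ndarray = field(default_factory=lambda: np.array([]))
    converged: bool = False

    @property
    def sds(self) -> np.ndarray:
        if self.covariance_mode == "diagonal":
            return np.sqrt(self.variances)
        return np.sqrt(np.einsum("kii->ki", self.variances))


@dataclass
class SOMModel:
    grid_rows: int
    grid_cols: int
    node_weights: np.ndarray            # (grid_rows*grid_cols, p)
    epochs_run: int
    initial_radius: float
    initial_learning_rate: float
    final_value: float = 0.01

    @property
    def n_nodes(self) -> int:
        return self.grid_rows * self.grid_cols


def _log_density(model_means, model_vars, weights, X, mode: str) -> np.ndarray:
    """log(w_m * h(x | mu_m, sigma_m)) for every row and component."""
    n, p = X.shape
    k = model_means.shape[0]
    out = np.empty((n, k))
    if mode == "diagonal":
        for m in range(k):
            var = model_vars[m]
            diff2 = (X - model_means[m]) ** 2 / var
            out[:, m] = -0.5 * (diff2.sum(axis=1) + np.log(2 * np.pi * var).sum())
    else:
        for m in range(k):
            cov = model_vars[m]
            sign, logdet = np.linalg.slogdet(cov)
            if sign <= 0:
                raise FloatingPointError("covariance lost positive definiteness")
            diff = X - model_means[m]
            sol = np.linalg.solve(cov, diff.T).T
            maha = np.einsum("ij,ij->i", diff, sol)
            out[:, m] = -0.5 * (maha + logdet + p * np.log(2 * np.pi))
    return out + np.log(weights)


def em_responsibilities(model: GaussianMixtureModel, features: np.ndarray) -> np.ndarray:
    """Posterior p(m | x_n): row-stochastic responsibility matrix."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    logw = _log_density(model.means, model.variances, model.weights, X, model.covariance_mode)
    return np.exp(logw - logsumexp(logw, axis=1, keepdims=True))


def _em_single(X, k, rng, tol, max_iter, mode, floor):
    n, p = X.shape
    centers, _ = kmeans_plusplus(X, n_clusters=k, random_state=int(rng.integers(2**31)))
    means = centers.astype(float)
    weights = np.full(k, 1.0 / k)
    base_var = X.var(axis=0, ddof=0) + floor
    if mode == "diagonal":
        variances = np.tile(base_var, (k, 1))
    else:
        variances = np.tile(np.diag(base_var), (k, 1, 1))

    trace = []
    converged = False
    for _ in range(max_iter):
        logw = _log_density(means, variances, weights, X, mode)
        lognorm = logsumexp(logw, axis=1)
        ll = float(lognorm.sum())
        resp = np.exp(logw - lognorm[:, None])
        if trace and abs(ll - trace[-1]) < tol:
            trace.append(ll)
            converged = True
            break
        trace.append(ll)

        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-300)
        weights = nk / n
        means = (resp.T @ X) / nk[:, None]
        if mode == "diagonal":
            for m in range(k):
                diff2 = (X - means[m]) ** 2
                variances[m] = (resp[:, m] @ diff2) / nk[m]
            floored = variances < floor
            if floored.any():
                logger.debug("variance floor applied to %d cells", int(floored.sum()))
            variances = np.maximum(variances, floor)
        else:
            for m in range(k):
                diff = X - means[m]
                cov = (resp[:, m][:, None] * diff).T @ diff / nk[m]
                cov[np.diag_indices(p)] = np.maximum(np.diag(cov), floor.mean())
                variances[m] = cov
    return means, variances, weights, np.array(trace), converged


def em_fit(features: np.ndarray, k: int, seed: int = 0, tol: float = 1e-6,
           max_iter: int = 200, covariance_mode: str = "diagonal",
           n_init: int = 5) -> tuple[GaussianMixtureModel, Partition]:
    """Fit a k-component Gaussian mixture by EM.

    Initialisation is k-means++ seeding; ``n_init`` restarts are run and
    the fit with the best final log-likelihood kept.  A per-dimension
    variance floor (1e-6 x the feature variance) prevents component
    collapse.  Rows are assigned to their argmax-responsibility
    component, ties broken toward the lowest component index.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    n, p = X.shape
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds number of rows ({n})")
    if covariance_mode not in ("diagonal", "full"):
        raise ValueError("covariance_mode must be 'diagonal' or 'full'")

    floor = VARIANCE_FLOOR_FACTOR * np.maximum(X.var(axis=0, ddof=0), 1e-12)

    if k == 1:
        means = X.mean(axis=0, keepdims=True)
        if covariance_mode == "diagonal":
            variances = np.maximum(X.var(axis=0, ddof=0), floor)[None, :]
        else:
            variances = np.cov(X.T, ddof=0).reshape(1, p, p)
        model = GaussianMixtureModel(
            k=1, weights=np.array([1.0]), means=means, variances=variances,
            covariance_mode=covariance_mode,
            log_likelihood_trace=np.array([float(
                _log_density(means, variances, np.array([1.0]), X, covariance_mode).sum()
            )]),
            converged=True,
        )
        return model, Partition(labels=np.zeros(n, dtype=int), k=1, source="em(k=1)")

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_init):
        fit = _em_single(X, k, rng, tol, max_iter, covariance_mode, floor)
        if best is None or fit[3][-1] > best[3][-1]:
            best = fit
    means, variances, weights, trace, converged = best
    model = GaussianMixtureModel(
        k=k, weights=weights, means=means, variances=variances,
        covariance_mode=covariance_mode, log_likelihood_trace=trace,
        converged=converged,
    )
    resp = em_responsibilities(model, X)
    labels = np.argmax(resp, axis=1)  # argmax takes the lowest index on ties
    return model, Partition(labels=labels, k=k, source=f"em(k={k})")


def som_fit(features: np.ndarray, grid_rows: int, grid_cols: int,
            epochs: int = 200, seed: int = 0,
            initial_learning_rate: float = 0.5,
            final_value: float = 0.01) -> tuple[SOMModel, Partition]:
    """Train a rectangular SOM online and partition rows by their
    best-matching node.

    The neighbourhood radius starts at max(grid_rows, grid_cols)/2 and
    the learning rate at ``initial_learning_rate``; both decay
    exponentially to ``final_value`` over the epochs.  Sample order is
    reshuffled every epoch from the seed, so training is fully
    deterministic.  Empty nodes are retained as empty clusters.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    n, p = X.shape
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    n_nodes = grid_rows * grid_cols
    if n < n_nodes:
        raise ValueError(f"need at least {n_nodes} rows for a {grid_rows}x{grid_cols} map")

    rng = np.random.default_rng(seed)
    lo, hi = X.min(axis=0), X.max(axis=0)
    W = rng.uniform(lo, hi, size=(n_nodes, p))

    grid = np.array([(r, c) for r in range(grid_rows) for c in range(grid_cols)], dtype=float)
    radius0 = max(grid_rows, grid_cols) / 2.0
    lr0 = initial_learning_rate
    total_steps = epochs

    for epoch in range(epochs):
        frac = epoch / max(total_steps - 1, 1)
        radius = max(radius0 * (final_value / max(radius0, final_value)) ** frac, final_value)
        lr = lr0 * (final_value / lr0) ** frac
        order = rng.permutation(n)
        for i in order:
            x = X[i]
            bmu = int(np.argmin(((W - x) ** 2).sum(axis=1)))
            gdist2 = ((grid - grid[bmu]) ** 2).sum(axis=1)
            h = np.exp(-gdist2 / (2.0 * radius ** 2))
            W += (lr * h)[:, None] * (x - W)

    model = SOMModel(
        grid_rows=grid_rows, grid_cols=grid_cols, node_weights=W,
        epochs_run=epochs, initial_radius=radius0,
        initial_learning_rate=lr0, final_value=final_value,
    )
    part = assign(model, X)
    empty = n_nodes - np.unique(part.labels).size
    if empty:
        logger.info("SOM %dx%d left %d empty node(s)", grid_rows, grid_cols, empty)
    return model, part


def quantization_error(model: SOMModel, features: np.ndarray) -> float:
    """Mean Euclidean distance of each row to its best-matching node."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    d = np.sqrt(((X[:, None, :] - model.node_weights[None]) ** 2).sum(-1))
    return float(d.min(axis=1).mean())


def assign(model, features: np.ndarray) -> Partition:
    """Label rows with a fitted model: argmax responsibility for EM,
    best-matching node for a SOM.  Deterministic."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if isinstance(model, GaussianMixtureModel):
        if X.shape[1] != model.means.shape[1]:
            raise ValueError("feature dimension does not match model")
        labels = np.argmax(em_responsibilities(model, X), axis=1)
        return Partition(labels=labels, k=model.k, source=f"em(k={model.k})")
    if isinstance(model, SOMModel):
        if X.shape[1] != model.node_weights.shape[1]:
            raise ValueError("feature dimension does not match model")
        d2 = ((X[:, None, :] - model.node_weights[None]) ** 2).sum(-1)
        labels = np.argmin(d2, axis=1)
        return Partition(labels=labels, k=model.n_nodes,
                         source=f"som({model.grid_rows}x{model.grid_cols})")
    raise TypeError(f"unsupported model type: {type(model).__name__}")
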