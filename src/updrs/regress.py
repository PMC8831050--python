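"""RBF-kernel support vector regression, grid-search tuning, bootstrap
ensembles, and cluster-wise training/prediction.

Kernel convention
-----------------
The kernel is parameterised as K(x, y) = exp(-||x - y||^2 / gamma^2):
``gamma`` is a length scale in input units, not the reciprocal-scale
``g`` of ``exp(-g ||x-y||^2)``.  The mapping g = 1/gamma^2 is applied
internally when delegating to the libsvm solver, so grid values of
gamma are honoured as length scales.

The tuning grids span gamma in [0.01, 0.1], epsilon in [0.0001, 0.002]
and C in [3, 4.1] — length scales and tube widths of order 1e-2 on
targets of order 1.  The cluster-wise pipeline therefore rescales its
inputs before the kernel ever sees them: PCA scores are standardised
and shrunk so their root-mean-square pairwise distance equals the grid
midpoint gamma = 0.055, and targets are min-max mapped to [0, 1].
Predictions are mapped back to UPDRS units before being returned.  The
low-level operations (``svr_train``, ``grid_search``,
``train_ensemble``) apply no scaling of their own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVR as _SkSVR

from .consensus import Partition
from .dataio import TelemonitoringTable
from .reduce import PCABasis, fit_pca, transform

logger = logging.getLogger(__name__)

GAMMA_REFERENCE = 0.055  # midpoint of the gamma tuning grid
DEFAULT_ENSEMBLE_SIZE = 8


@dataclass(frozen=True)
class SVRParams:
    C: float
    epsilon: float
    gamma: float

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0 or self.epsilon < 0:
            raise ValueError("require C > 0, gamma > 0, epsilon >= 0")


def rbf_kernel(x, y, gamma: float) -> float:
    """K(x, y) = exp(-||x - y||^2 / gamma^2)."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal dimensions")
    return float(np.exp(-np.sum((x - y) ** 2) / gamma ** 2))


def full_grid() -> dict[str, np.ndarray]:
    """The full tuning grids: 19 gamma x 20 epsilon x 221 C values."""
    return {
        "gamma": np.linspace(0.01, 0.1, 19),
        "epsilon": np.linspace(0.0001, 0.002, 20),
        "C": np.linspace(3.0, 4.1, 221),
    }


def fast_grid() -> dict[str, np.ndarray]:
    """A 5 x 5 x 5 subset of the full grids (endpoints included) for
    desk-scale runs; every value is an element of the full grid."""
    g = full_grid()
    return {
        "gamma": g["gamma"][[0, 4, 9, 13, 18]],
        "epsilon": g["epsilon"][[0, 4, 9, 14, 19]],
        "C": g["C"][[0, 55, 110, 165, 220]],
    }


def tiny_grid() -> dict[str, np.ndarray]:
    """A single mid-grid cell — skips tuning entirely for quick runs."""
    g = full_grid()
    return {"gamma": g["gamma"][[9]], "epsilon": g["epsilon"][[9]], "C": g["C"][[110]]}


@dataclass
class FittedSVR:
    """A trained epsilon-insensitive SVR.

    Prediction follows the dual expansion
    y(x) = sum_i (beta_i - beta*_i) K(x, x_i) + b, with the box
    constraint 0 <= beta, beta* <= C and sum_i (beta_i - beta*_i) = 0.
    """

    params: SVRParams
    _sk: _SkSVR

    @property
    def dual_coef(self) -> np.ndarray:
        """beta - beta* for the support points."""
        return self._sk.dual_coef_.ravel()

    @property
    def bias(self) -> float:
        return float(self._sk.intercept_[0])

    @property
    def support_vectors(self) -> np.ndarray:
        return self._sk.support_vectors_

    @property
    def support_indices(self) -> np.ndarray:
        return self._sk.support_

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._sk.predict(np.atleast_2d(np.asarray(X, dtype=float)))

    def predict_dual(self, X: np.ndarray) -> np.ndarray:
        """Explicit evaluation of the dual expansion (audit path)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        sv = self.support_vectors
        d2 = ((X[:, None, :] - sv[None]) ** 2).sum(-1)
        K = np.exp(-d2 / self.params.gamma ** 2)
        return K @ self.dual_coef + self.bias


def svr_train(features: np.ndarray, targets: np.ndarray, params: SVRParams,
              tol: float = 1e-3) -> FittedSVR:
    """Solve the epsilon-insensitive SVR dual (libsvm SMO solver)."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(targets, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training rows")
    if not np.isfinite(y).all():
        raise ValueError("targets must be finite")
    sk = _SkSVR(kernel="rbf", gamma=1.0 / params.gamma ** 2,
                C=params.C, epsilon=params.epsilon, tol=tol,
                max_iter=2_000_000)
    sk.fit(X, y)
    if sk.fit_status_ != 0:
        raise RuntimeError(f"SVR solver did not converge (n_iter={sk.n_iter_})")
    return FittedSVR(params=params, _sk=sk)


def _rmse(a, b) -> float:
    return float(np.sqrt(np.mean((np.asarray(a) - np.asarray(b)) ** 2)))


def grid_search(features: np.ndarray, targets: np.ndarray,
                grids: dict[str, np.ndarray] | None = None,
                folds: int = 5, seed: int = 0) -> SVRParams:
    """Exhaustive grid search minimising mean 5-fold validation RMSE.

    Folds are formed by a seeded shuffle of the rows.  Ties are broken
    toward smaller C, then larger epsilon, then smaller gamma (the
    least-complex model among the tied).
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(targets, dtype=float)
    n = X.shape[0]
    if n < folds:
        raise ValueError(f"need at least {folds} rows for {folds}-fold CV")
    if grids is None:
        grids = fast_grid()
    for key in ("gamma", "epsilon", "C"):
        if key not in grids or len(grids[key]) == 0:
            raise ValueError(f"grid for {key!r} is empty")

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fold_ids = np.empty(n, dtype=int)
    for f, idx in enumerate(np.array_split(order, folds)):
        if idx.size < 1:
            raise ValueError("a fold received no rows")
        fold_ids[idx] = f

    # tie-break order: C ascending, epsilon descending, gamma ascending
    candidates = [
        SVRParams(C=float(C), epsilon=float(e), gamma=float(g))
        for C in np.sort(grids["C"])
        for e in np.sort(grids["epsilon"])[::-1]
        for g in np.sort(grids["gamma"])
    ]
    best_params, best_score = None, np.inf
    for params in candidates:
        errs = []
        for f in range(folds):
            tr = fold_ids != f
            model = svr_train(X[tr], y[tr], params)
            errs.append(_rmse(model.predict(X[~tr]), y[~tr]))
        score = float(np.mean(errs))
        if score < best_score:
            best_score, best_params = score, params
    return best_params


@dataclass
class SVREnsemble:
    members: list[FittedSVR]
    member_seeds: list[int]
    params: SVRParams
    training_rmse: float = np.nan

    @property
    def n_members(self) -> int:
        return len(self.members)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Arithmetic mean of the member predictions."""
        preds = np.stack([m.predict(X) for m in self.members])
        return preds.mean(axis=0)


def train_ensemble(features: np.ndarray, targets: np.ndarray, params: SVRParams,
                   n_members: int = DEFAULT_ENSEMBLE_SIZE, seed: int = 0,
                   bootstrap: bool = True) -> SVREnsemble:
    """Bagging: each member is trained on a with-replacement resample of
    the full training-set size (member i draws from seed + i); the
    ensemble prediction is the mean of the member predictions."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(targets, dtype=float)
    n = X.shape[0]
    if n_members < 1:
        raise ValueError("n_members must be >= 1")
    members, seeds = [], []
    for i in range(n_members):
        member_seed = seed + i
        if bootstrap:
            idx = np.random.default_rng(member_seed).integers(0, n, size=n)
            attempts = 0
            while np.unique(X[idx], axis=0).shape[0] < 2 and attempts < 10:
                # degenerate resample: a single unique row cannot anchor a fit
                attempts += 1
                member_seed = seed + 1000 * (i + 1) + attempts
                idx = np.random.default_rng(member_seed).integers(0, n, size=n)
                logger.info("redrawn degenerate bootstrap resample (member %d)", i)
        else:
            idx = np.arange(n)
        members.append(svr_train(X[idx], y[idx], params))
        seeds.append(member_seed)
    ens = SVREnsemble(members=members, member_seeds=seeds, params=params)
    ens.training_rmse = _rmse(ens.predict(X), y)
    return ens


# ---------------------------------------------------------------------------
# scaling helpers used by the cluster-wise pipeline
# ---------------------------------------------------------------------------

@dataclass
class FeatureScaler:
    """Standardise columns, then shrink so the expected pairwise
    distance matches GAMMA_REFERENCE (see module docstring)."""

    mean: np.ndarray
    sd: np.ndarray
    alpha: float

    @classmethod
    def fit(cls, X: np.ndarray) -> "FeatureScaler":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        sd = np.where(sd > 0, sd, 1.0)
        # for standardised columns E||x - y||^2 = 2p
        rms_dist = np.sqrt(2.0 * X.shape[1])
        return cls(mean=mean, sd=sd, alpha=GAMMA_REFERENCE / rms_dist)

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.mean) / self.sd * self.alpha


@dataclass
class TargetScaler:
    lo: float
    span: float

    @classmethod
    def fit(cls, y: np.ndarray) -> "TargetScaler":
        y = np.asarray(y, dtype=float)
        lo, hi = float(y.min()), float(y.max())
        return cls(lo=lo, span=(hi - lo) if hi > lo else 1.0)

    def transform(self, y: np.ndarray) -> np.ndarray:
        return (np.asarray(y, dtype=float) - self.lo) / self.span

    def inverse(self, y: np.ndarray) -> np.ndarray:
        return np.asarray(y, dtype=float) * self.span + self.lo


# ---------------------------------------------------------------------------
# cluster-wise model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitConfig:
    pca_threshold: float = 0.95
    grid: str = "fast"                  # "fast" | "full"
    folds: int = 5
    n_members: int = DEFAULT_ENSEMBLE_SIZE
    min_cluster_size: int = 25
    max_tune_rows: int | None = 350     # subsample cap for grid search
    seed: int = 0

    def grids(self) -> dict[str, np.ndarray]:
        if self.grid == "fast":
            return fast_grid()
        if self.grid == "full":
            return full_grid()
        if self.grid == "tiny":
            return tiny_grid()
        raise ValueError(f"unknown grid {self.grid!r}")


@dataclass
class _ClusterModel:
    pca: PCABasis
    feat_scaler: FeatureScaler
    motor_scaler: TargetScaler
    total_scaler: TargetScaler
    motor_ensemble: SVREnsemble
    total_ensemble: SVREnsemble
    centroid: np.ndarray
    n_rows: int

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        Z = self.feat_scaler.transform(transform(X, self.pca))
        motor = self.motor_scaler.inverse(self.motor_ensemble.predict(Z))
        total = self.total_scaler.inverse(self.total_ensemble.predict(Z))
        return motor, total


@dataclass
class ClusterwiseSVRModel:
    cluster_models: dict[int, _ClusterModel]
    fallback: _ClusterModel | None
    config: FitConfig

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_models)

    def centroids(self) -> dict[int, np.ndarray]:
        return {c: m.centroid for c, m in self.cluster_models.items()}


def _fit_one(X: np.ndarray, motor: np.ndarray, total: np.ndarray,
             config: FitConfig, seed: int) -> _ClusterModel:
    pca = fit_pca(X, config.pca_threshold)
    scores = transform(X, pca)
    feat_scaler = FeatureScaler.fit(scores)
    Z = feat_scaler.transform(scores)
    grids = config.grids()

    if config.max_tune_rows is not None and Z.shape[0] > config.max_tune_rows:
        idx = np.random.default_rng(seed).choice(Z.shape[0], config.max_tune_rows, replace=False)
    else:
        idx = np.arange(Z.shape[0])

    out = {}
    for name, y in (("motor", motor), ("total", total)):
        scaler = TargetScaler.fit(y)
        ys = scaler.transform(y)
        params = grid_search(Z[idx], ys[idx], grids, folds=config.folds, seed=seed)
        ens = train_ensemble(Z, ys, params, n_members=config.n_members, seed=seed)
        out[name] = (scaler, ens)
    return _ClusterModel(
        pca=pca, feat_scaler=feat_scaler,
        motor_scaler=out["motor"][0], total_scaler=out["total"][0],
        motor_ensemble=out["motor"][1], total_ensemble=out["total"][1],
        centroid=X.mean(axis=0), n_rows=X.shape[0],
    )


def fit_clusterwise(table: TelemonitoringTable, consensus: Partition,
                    config: FitConfig = FitConfig()) -> ClusterwiseSVRModel:
    """Per consensus cluster: PCA -> tuned bootstrap SVR ensembles for
    both targets, plus the cluster centroid for routing.

    Clusters with fewer than ``min_cluster_size`` rows are pooled into a
    global fallback model; if every cluster is too small a single global
    model is fit (with a warning).
    """
    if table.missing_mask.any():
        raise ValueError("table still has masked cells; impute first")
    if consensus.n_rows != table.n_rows:
        raise ValueError("consensus partition does not label the table's rows")
    X = table.features

    cluster_models: dict[int, _ClusterModel] = {}
    small_rows = []
    for c in range(consensus.k):
        rows = np.flatnonzero(consensus.labels == c)
        if rows.size == 0:
            continue
        if rows.size < config.min_cluster_size:
            small_rows.append(rows)
            continue
        cluster_models[c] = _fit_one(
            X[rows], table.motor_updrs[rows], table.total_updrs[rows],
            config, seed=config.seed + 7919 * (c + 1),
        )

    fallback = None
    if not cluster_models:
        logger.warning("every cluster below min_cluster_size; fitting one global model")
        fallback = _fit_one(X, table.motor_updrs, table.total_updrs, config, seed=config.seed)
    elif small_rows:
        pool = np.concatenate(small_rows)
        if pool.size < config.min_cluster_size:
            pool = np.arange(table.n_rows)
        logger.info("pooled %d rows from small clusters into fallback", pool.size)
        fallback = _fit_one(X[pool], table.motor_updrs[pool], table.total_updrs[pool],
                            config, seed=config.seed + 104729)
    return ClusterwiseSVRModel(cluster_models=cluster_models, fallback=fallback, config=config)


def predict_clusterwise(model: ClusterwiseSVRModel,
                        rows: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Route each row to the nearest cluster centroid (Euclidean, in the
    imputed feature space) and predict with that cluster's ensembles.

    Returns ``(motor, total, routing_labels)``; rows served by the
    fallback model get routing label -1.
    """
    X = np.atleast_2d(np.asarray(rows, dtype=float))
    n = X.shape[0]
    motor = np.empty(n)
    total = np.empty(n)
    if not model.cluster_models:
        motor, total = model.fallback.predict(X)
        return motor, total, np.full(n, -1)

    ids = sorted(model.cluster_models)
    cents = np.stack([model.cluster_models[c].centroid for c in ids])
    if X.shape[1] != cents.shape[1]:
        raise ValueError("feature dimension does not match model centroids")
    d2 = ((X[:, None, :] - cents[None]) ** 2).sum(-1)
    nearest = np.asarray(ids)[np.argmin(d2, axis=1)]
    routing = nearest.copy()
    for c in ids:
        sel = nearest == c
        if sel.any():
            m, t = model.cluster_models[c].predict(X[sel])
            motor[sel], total[sel] = m, t
    return motor, total, routing
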