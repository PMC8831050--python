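"""Prediction metrics, clustering agreement, and the experiment harness.

Metrics reported per prediction/observation pairing: RMSE, MAE,
Willmott's Index of Agreement (IA), prediction accuracy (PA = Pearson
correlation of predictions and observations) and adjusted R^2 with
R = PA and m predictors:

    adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - m - 1).

The harness :func:`run_experiment` chains the full pipeline: optional
masking + SVD imputation, base clusterings (EM at several k, SOM at
several map sizes) on the training rows, consensus per requested
method, cluster-wise PCA + SVR ensembles, and subject-grouped held-out
evaluation — no subject's recordings span the train/test boundary, so
the models are scored on unseen patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression
from sklearn.metrics import adjusted_rand_score

from . import cluster as _cluster
from . import consensus as _consensus
from .consensus import ClusterEnsemble, Partition
from .dataio import TelemonitoringTable, mask_random_entries
from .impute import impute, recovery_error
from .regress import FitConfig, fit_clusterwise, predict_clusterwise
from .synthetic import SyntheticConfig, generate


@dataclass
class MetricsReport:
    rmse: float
    mae: float
    ia: float
    pa: float
    r2_adjusted: float
    n: int
    m: int


def compute_metrics(predicted, observed, m: int) -> MetricsReport:
    """Standard regression metrics for n observations and m predictors."""
    P = np.asarray(predicted, dtype=float)
    O = np.asarray(observed, dtype=float)
    if P.shape != O.shape or P.ndim != 1:
        raise ValueError("predicted and observed must be 1-D and equal length")
    n = P.size
    if n < 3 or n <= m + 1:
        raise ValueError(f"need n >= 3 and n > m + 1 (n={n}, m={m})")
    o_bar = O.mean()
    if np.allclose(O, o_bar):
        raise ValueError("observed values have zero variance; metrics undefined")

    err = P - O
    rmse = float(np.sqrt(np.mean(err ** 2)))
    mae = float(np.mean(np.abs(err)))
    ia = float(1.0 - np.sum(err ** 2) / np.sum((np.abs(P - o_bar) + np.abs(O - o_bar)) ** 2))
    if np.allclose(P, P.mean()):
        pa = 0.0  # constant predictions carry no association
    else:
        pa = float(np.corrcoef(P, O)[0, 1])
    r2 = pa ** 2
    r2_adj = float(1.0 - (1.0 - r2) * (n - 1) / (n - m - 1))
    return MetricsReport(rmse=rmse, mae=mae, ia=ia, pa=pa, r2_adjusted=r2_adj, n=n, m=m)


def adjusted_rand_index(a: Partition, b: Partition) -> float:
    """Chance-corrected agreement between two partitions (1 iff they are
    identical up to relabeling)."""
    if a.n_rows != b.n_rows:
        raise ValueError("partitions must label the same rows")
    return float(adjusted_rand_score(a.labels, b.labels))


# ---------------------------------------------------------------------------
# experiment harness
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExperimentConfig:
    """One full pipeline run.

    ``em_k`` / ``som_maps`` define the base clusterers (fit on the
    training rows' standardised features); ``methods`` the consensus
    functions; ``target_k`` the consensus cluster count (default: median
    of the base clusterers' k).  ``test_fraction`` of subjects are held
    out for scoring; with ``outer_scheme="grouped-kfold"`` a grouped
    k-fold rotation is used instead.
    """

    synthetic: SyntheticConfig | None = None
    em_k: tuple[int, ...] = (3, 4)
    som_maps: tuple[tuple[int, int], ...] = ()
    methods: tuple[str, ...] = ("hgpa",)
    target_k: int | None = None
    mask_fraction: float = 0.0
    impute_rank: int | None = None
    fit: FitConfig = field(default_factory=FitConfig)
    outer_scheme: str = "holdout"       # "holdout" | "grouped-kfold"
    test_fraction: float = 0.25
    outer_folds: int = 10
    include_baselines: bool = True
    som_epochs: int = 50
    seed: int = 0


@dataclass
class ExperimentResult:
    report: pd.DataFrame
    consensus_partitions: dict[str, Partition]
    base_partitions: list[Partition]
    imputation: dict | None
    log: list[str]


def _standardize(train: np.ndarray, other: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (train - mu) / sd, (other - mu) / sd


def _subject_split(subject_id: np.ndarray, test_fraction: float, seed: int):
    subjects = pd.unique(subject_id)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    n_test = max(1, int(round(test_fraction * len(subjects))))
    test_subjects = set(subjects[order[:n_test]].tolist())
    test = np.array([s in test_subjects for s in subject_id])
    return ~test, test


def _grouped_folds(subject_id: np.ndarray, n_folds: int, seed: int):
    subjects = pd.unique(subject_id)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    for chunk in np.array_split(order, n_folds):
        fold_subjects = set(subjects[chunk].tolist())
        test = np.array([s in fold_subjects for s in subject_id])
        yield ~test, test


def fit_global_mlr(X_train: np.ndarray, y_train: np.ndarray) -> LinearRegression:
    return LinearRegression().fit(X_train, y_train)


def _consensus_partition(method: str, ensemble: ClusterEnsemble, target_k: int, seed: int) -> Partition:
    if method == "voting":
        return _consensus.majority_vote(ensemble)
    if method == "cspa":
        S = _consensus.build_coassociation(ensemble)
        return _consensus.cspa_partition(S, target_k, seed=seed)
    if method == "hgpa":
        H = _consensus.build_hypergraph(ensemble)
        return _consensus.hgpa_partition(H, target_k, seed=seed)
    raise ValueError(f"unknown consensus method {method!r}; choose voting, cspa or hgpa")


def run_experiment(config: ExperimentConfig,
                   table: TelemonitoringTable | None = None,
                   true_labels: Partition | None = None) -> ExperimentResult:
    """Execute the full pipeline and return a Table-shaped report.

    The run is a pure function of (config, table): identical inputs give
    identical reports.
    """
    log: list[str] = []
    if table is None:
        if config.synthetic is None:
            raise ValueError("provide a table or a synthetic config")
        table, true_labels, _ = generate(config.synthetic)
        log.append(f"generated synthetic table: {table.n_rows} rows")

    imputation = None
    if config.mask_fraction > 0.0 and not table.missing_mask.any():
        masked = mask_random_entries(table, config.mask_fraction, seed=config.seed + 11)
        dense, imodel = impute(masked, rank_d=config.impute_rank)
        imputation = {**recovery_error(masked, dense),
                      "rank_d": imodel.rank_d, "iterations": imodel.n_iterations_run}
        table = dense
        log.append(f"masked {config.mask_fraction:.0%} of feature cells and imputed "
                   f"(rank {imodel.rank_d}, {imodel.n_iterations_run} iterations)")
    elif table.missing_mask.any():
        table, imodel = impute(table, rank_d=config.impute_rank)
        imputation = {"rank_d": imodel.rank_d, "iterations": imodel.n_iterations_run}
        log.append("imputed pre-existing missing cells")

    rows_records = []
    splits = ([_subject_split(table.subject_id, config.test_fraction, config.seed)]
              if config.outer_scheme == "holdout"
              else list(_grouped_folds(table.subject_id, config.outer_folds, config.seed)))

    consensus_parts: dict[str, Partition] = {}
    base_parts: list[Partition] = []
    for split_i, (train, test) in enumerate(splits):
        Xtr_raw, Xte_raw = table.features[train], table.features[test]
        Xtr, _ = _standardize(Xtr_raw, Xte_raw)

        parts = []
        for kk in config.em_k:
            _, part = _cluster.em_fit(Xtr, k=kk, seed=config.seed + 100 + kk)
            parts.append(part)
        for (gr, gc) in config.som_maps:
            _, part = _cluster.som_fit(Xtr, gr, gc, epochs=config.som_epochs,
                                       seed=config.seed + 200 + 10 * gr + gc)
            parts.append(part)
        if split_i == 0:
            base_parts = parts

        ensemble = ClusterEnsemble(partitions=parts, target_k=config.target_k)
        for method in config.methods:
            part = _consensus_partition(method, ensemble, ensemble.target_k,
                                        seed=config.seed + 300)
            if split_i == 0:
                consensus_parts[method] = part
            model = fit_clusterwise(
                _subset_table(table, train), part,
                FitConfig(**{**asdict(config.fit), "seed": config.fit.seed + split_i}),
            )
            motor_pred, total_pred, _ = predict_clusterwise(model, Xte_raw)
            for target, pred, obs in (
                ("motor", motor_pred, table.motor_updrs[test]),
                ("total", total_pred, table.total_updrs[test]),
            ):
                m_pred = int(np.mean([cm.pca.n_retained for cm in model.cluster_models.values()])
                             if model.cluster_models else model.fallback.pca.n_retained)
                rep = compute_metrics(pred, obs, m=m_pred)
                rows_records.append({"split": split_i, "composition": _composition(config),
                                     "ensemble_size": len(parts), "method": method,
                                     "target": target, **asdict(rep)})

        if config.include_baselines:
            single = Partition(labels=np.zeros(int(train.sum()), dtype=int), k=1, source="global")
            gmodel = fit_clusterwise(
                _subset_table(table, train), single,
                FitConfig(**{**asdict(config.fit), "min_cluster_size": 2,
                             "seed": config.fit.seed + split_i}),
            )
            motor_pred, total_pred, _ = predict_clusterwise(gmodel, Xte_raw)
            m_glob = (gmodel.cluster_models[0].pca.n_retained
                      if gmodel.cluster_models else gmodel.fallback.pca.n_retained)
            for target, pred, obs in (("motor", motor_pred, table.motor_updrs[test]),
                                      ("total", total_pred, table.total_updrs[test])):
                rep = compute_metrics(pred, obs, m=m_glob)
                rows_records.append({"split": split_i, "composition": _composition(config),
                                     "ensemble_size": len(parts), "method": "global-svr",
                                     "target": target, **asdict(rep)})
            Xtr_std, Xte_std = _standardize(Xtr_raw, Xte_raw)
            for target, ytr, yte in (
                ("motor", table.motor_updrs[train], table.motor_updrs[test]),
                ("total", table.total_updrs[train], table.total_updrs[test]),
            ):
                mlr = fit_global_mlr(Xtr_std, ytr)
                rep = compute_metrics(mlr.predict(Xte_std), yte, m=Xtr_std.shape[1])
                rows_records.append({"split": split_i, "composition": _composition(config),
                                     "ensemble_size": len(parts), "method": "global-mlr",
                                     "target": target, **asdict(rep)})

    report = pd.DataFrame.from_records(rows_records)
    return ExperimentResult(report=report, consensus_partitions=consensus_parts,
                            base_partitions=base_parts, imputation=imputation, log=log)


def _composition(config: ExperimentConfig) -> str:
    bits = [f"em(k={k})" for k in config.em_k]
    bits += [f"som({r}x{c})" for r, c in config.som_maps]
    return "+".join(bits)


def _subset_table(table: TelemonitoringTable, mask: np.ndarray) -> TelemonitoringTable:
    return TelemonitoringTable(
        subject_id=table.subject_id[mask],
        covariates=table.covariates.loc[mask].reset_index(drop=True),
        features=table.features[mask],
        feature_names=table.feature_names,
        motor_updrs=table.motor_updrs[mask],
        total_updrs=table.total_updrs[mask],
        missing_mask=table.missing_mask[mask],
    )
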