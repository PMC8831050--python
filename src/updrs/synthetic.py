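"""Synthetic telemonitoring data with known cluster structure.

The generator emulates the schema of remote-monitoring voice studies:
~40 subjects, on the order of 100-200 recordings each, a block of
correlated numeric voice features plus age/sex/test_time covariates,
and two targets (Motor-UPDRS, Total-UPDRS) produced by cluster-specific
nonlinear functions of the features plus noise.  Because cluster
membership, the target functions and every generative parameter are
returned alongside the data, each downstream stage of the pipeline has
a ground-truth oracle to be tested against.

Structural assumptions baked in:

* subjects, not individual recordings, carry cluster membership — all
  recordings of a subject share one mixture component;
* within a cluster, features follow a Gaussian factor model: a few
  shared latent factors induce correlation (the multicollinearity that
  PCA is later asked to remove), with strength ``feature_correlation``;
* the per-cluster target functions differ in their coefficients, so a
  cluster-then-regress strategy genuinely outperforms one global
  regressor; setting ``shared_target_function=True`` switches this off
  and yields the null regime in which the two strategies tie.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .consensus import Partition
from .dataio import TelemonitoringTable, MOTOR_RANGE, TOTAL_RANGE, mask_random_entries

N_LATENT_FACTORS = 3


@dataclass(frozen=True)
class SyntheticConfig:
    n_subjects: int = 40
    recordings_per_subject: int = 150
    n_features: int = 16
    n_clusters: int = 3
    cluster_separation: float = 6.0
    feature_correlation: float = 0.5
    target_noise_sd: float = 2.0
    missing_fraction: float = 0.0
    shared_target_function: bool = False
    subject_effect_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.n_subjects < 1 or self.recordings_per_subject < 1 or self.n_features < 1:
            raise ValueError("counts must be >= 1")
        if not 0.0 <= self.feature_correlation < 1.0:
            raise ValueError("feature_correlation must lie in [0, 1)")
        if self.cluster_separation < 0 or self.target_noise_sd < 0:
            raise ValueError("separation and noise SD must be nonnegative")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ValueError("missing_fraction must lie in [0, 1)")


def _cluster_means(rng: np.random.Generator, k: int, p: int, separation: float) -> np.ndarray:
    """Component means with minimum pairwise distance = separation (in
    units of the within-cluster SD, which is 1 by construction)."""
    if k == 1:
        return np.zeros((1, p))
    raw = rng.standard_normal((k, p))
    raw -= raw.mean(axis=0)
    d = np.sqrt(((raw[:, None, :] - raw[None, :, :]) ** 2).sum(-1))
    d_min = d[~np.eye(k, dtype=bool)].min()
    if separation == 0.0:
        return np.zeros((k, p))
    return raw * (separation / d_min)


def _target_coefficients(rng: np.random.Generator, k: int, shared: bool) -> list[dict]:
    """Per-cluster coefficient sets for the smooth nonlinear target map.

    motor = base + a1*x1 + a2*x2^2 + a3*sin(x3) + a4*x1*x2   (+ noise)
    total = t0 + t1*motor_signal + b1*x4                      (+ noise)
    """
    coefs = []
    for c in range(k):
        r = rng if not shared else np.random.default_rng(12345)
        coefs.append({
            "base": 25.0 + (0.0 if shared else 12.0 * c),
            "a1": r.uniform(2.0, 5.0),
            "a2": r.uniform(1.0, 3.0),
            "a3": r.uniform(3.0, 6.0),
            "a4": r.uniform(1.0, 2.5),
            "t0": 8.0,
            "t1": 1.35,
            "b1": r.uniform(1.5, 4.0),
        })
        if not shared:
            # alternate signs across clusters so the functions genuinely differ
            sign = -1.0 if c % 2 else 1.0
            coefs[-1]["a1"] *= sign
            coefs[-1]["a3"] *= -sign
    return coefs


def generate(config: SyntheticConfig) -> tuple[TelemonitoringTable, Partition, dict]:
    """Draw a synthetic telemonitoring table.

    Returns ``(table, true_labels, generative_params)`` where
    ``true_labels`` assigns each row to its generating mixture component
    and ``generative_params`` records everything needed to re-derive the
    noiseless targets (cluster means, factor loadings, coefficients,
    clipping counts).
    """
    rng = np.random.default_rng(config.seed)
    k, p = config.n_clusters, config.n_features
    n = config.n_subjects * config.recordings_per_subject

    means = _cluster_means(rng, k, p, config.cluster_separation)
    # unit-row-norm loadings: marginal feature variance stays 1 for any rho
    loadings = rng.standard_normal((p, N_LATENT_FACTORS))
    loadings /= np.linalg.norm(loadings, axis=1, keepdims=True)
    rho = config.feature_correlation

    # balanced subject->cluster assignment (cycling) keeps cluster sizes even
    subject_cluster = np.arange(config.n_subjects) % k
    subject_effect = rng.normal(0.0, config.subject_effect_sd, size=(config.n_subjects, p))

    subject_id = np.repeat(
        np.array([f"S{s:03d}" for s in range(config.n_subjects)]), config.recordings_per_subject
    )
    labels = np.repeat(subject_cluster, config.recordings_per_subject)

    factors = rng.standard_normal((n, N_LATENT_FACTORS))
    noise = rng.standard_normal((n, p))
    X = (
        means[labels]
        + subject_effect[np.repeat(np.arange(config.n_subjects), config.recordings_per_subject)]
        + np.sqrt(rho) * factors @ loadings.T
        + np.sqrt(1.0 - rho) * noise
    )

    coefs = _target_coefficients(rng, k, config.shared_target_function)
    motor_signal = np.empty(n)
    total_signal = np.empty(n)
    for c in range(k):
        rows = labels == c
        cc = coefs[c]
        x1, x2, x3, x4 = (X[rows, j % p] for j in range(4))
        m = (
            cc["base"]
            + cc["a1"] * x1
            + cc["a2"] * x2 ** 2
            + cc["a3"] * np.sin(x3)
            + cc["a4"] * x1 * x2
        )
        motor_signal[rows] = m
        total_signal[rows] = cc["t0"] + cc["t1"] * m + cc["b1"] * x4

    motor = motor_signal + rng.normal(0.0, config.target_noise_sd, size=n)
    total = total_signal + rng.normal(0.0, config.target_noise_sd, size=n)
    n_clipped = int((motor < MOTOR_RANGE[0]).sum() + (motor > MOTOR_RANGE[1]).sum()
                    + (total < TOTAL_RANGE[0]).sum() + (total > TOTAL_RANGE[1]).sum())
    motor = np.clip(motor, *MOTOR_RANGE)
    total = np.clip(total, *TOTAL_RANGE)

    age = np.repeat(rng.normal(65.0, 9.0, size=config.n_subjects).round(0), config.recordings_per_subject)
    sex = np.repeat((rng.random(config.n_subjects) < 0.65).astype(float), config.recordings_per_subject)
    test_time = rng.uniform(0.0, 180.0, size=n).round(2)

    table = TelemonitoringTable(
        subject_id=subject_id,
        covariates=pd.DataFrame({"age": age, "sex": sex, "test_time": test_time}),
        features=X,
        feature_names=tuple(f"feature_{j:02d}" for j in range(p)),
        motor_updrs=motor,
        total_updrs=total,
        missing_mask=np.zeros_like(X, dtype=bool),
    )
    if config.missing_fraction > 0.0:
        table = mask_random_entries(table, config.missing_fraction, seed=config.seed + 1)

    params = {
        "config": asdict(config),
        "cluster_means": means.tolist(),
        "factor_loadings": loadings.tolist(),
        "target_coefficients": coefs,
        "subject_cluster": subject_cluster.tolist(),
        "n_clipped_targets": n_clipped,
    }
    truth = Partition(labels=labels, k=k, source="truth")
    return table, truth, params
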