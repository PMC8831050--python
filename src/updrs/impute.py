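"""Missing-value prediction by iterated low-rank SVD approximation.

The feature block is treated as a dense matrix B whose masked entries
are first filled with column means.  Each iteration then (1) z-scores
every column over its observed entries, (2) replaces the matrix by its
best rank-d approximation Z_d (truncated SVD), (3) copies Z_d's values
back into the masked cells only, and (4) undoes the normalisation.
Iteration stops once the largest absolute change in any imputed cell
drops below ``tol`` (or after ``max_iter`` sweeps); ``single_pass=True``
performs exactly one sweep.  Observed entries are never altered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataio import TelemonitoringTable


class DegenerateColumnError(ValueError):
    """A feature column has no spread (or too few observed values)."""


@dataclass
class ImputationModel:
    rank_d: int
    column_centers: np.ndarray
    column_scales: np.ndarray
    n_iterations_run: int
    converged: bool
    final_delta: float
    explained_mass: float  # squared-singular-value fraction captured by rank_d


def normalize(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-wise z-score over observed (non-NaN) entries.

    Scale is the sample standard deviation (ddof=1).  Returns
    ``(normalized, centers, scales)``; NaNs pass through untouched.
    """
    X = np.asarray(values, dtype=float)
    centers = np.empty(X.shape[1])
    scales = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        obs = X[~np.isnan(X[:, j]), j]
        if obs.size < 2:
            raise DegenerateColumnError(f"column {j} has fewer than 2 observed values")
        centers[j] = obs.mean()
        scales[j] = obs.std(ddof=1)
        if scales[j] == 0.0:
            raise DegenerateColumnError(f"column {j} is constant; scale undefined")
    return (X - centers) / scales, centers, scales


def denormalize(values: np.ndarray, centers: np.ndarray, scales: np.ndarray) -> np.ndarray:
    return values * scales + centers


def svd_lowrank(block: np.ndarray, rank_d: int) -> np.ndarray:
    """Best rank-d approximation in the least-squares sense."""
    B = np.asarray(block, dtype=float)
    if np.isnan(B).any():
        raise ValueError("block must be fully dense")
    r_max = min(B.shape)
    if not 1 <= rank_d <= r_max:
        raise ValueError(f"rank_d must lie in [1, {r_max}]; got {rank_d}")
    U, s, Vt = np.linalg.svd(B, full_matrices=False)
    return (U[:, :rank_d] * s[:rank_d]) @ Vt[:rank_d]


def _auto_rank(s: np.ndarray, mass: float = 0.9) -> int:
    frac = np.cumsum(s ** 2) / np.sum(s ** 2)
    return int(np.searchsorted(frac, mass) + 1)


def impute(table: TelemonitoringTable, rank_d: int | None = None, max_iter: int = 100,
           tol: float = 1e-6, single_pass: bool = False) -> tuple[TelemonitoringTable, ImputationModel]:
    """Fill masked feature cells by iterative truncated-SVD approximation.

    ``rank_d=None`` selects the smallest rank capturing at least 90% of
    the squared singular-value mass at the first iteration.
    """
    mask = table.missing_mask
    if not mask.any():
        raise ValueError("table has no masked cells to impute")
    if mask.all(axis=0).any():
        cols = np.flatnonzero(mask.all(axis=0))
        raise DegenerateColumnError(f"feature column(s) {cols.tolist()} fully masked")

    X = table.observed_features()
    # initialise masked cells with observed column means
    col_means = np.nanmean(X, axis=0)
    filled = np.where(np.isnan(X), col_means, X)

    centers = scales = None
    n_iter, delta = 0, np.inf
    explained = np.nan
    for it in range(1, max_iter + 1):
        # normalisation statistics come from the current filled matrix:
        # at the fixed point they are the completed matrix's own moments,
        # so centering does not inflate the rank of an exactly low-rank block
        _, centers, scales = normalize(filled)
        Zn = (filled - centers) / scales
        if np.isnan(Zn).any():
            raise FloatingPointError(f"NaN encountered at iteration {it}")
        U, s, Vt = np.linalg.svd(Zn, full_matrices=False)
        if it == 1:
            if rank_d is None:
                rank_d = _auto_rank(s)
            if not 1 <= rank_d <= min(Zn.shape):
                raise ValueError(f"rank_d out of range: {rank_d}")
        explained = float(np.sum(s[:rank_d] ** 2) / np.sum(s ** 2))
        Zd = (U[:, :rank_d] * s[:rank_d]) @ Vt[:rank_d]
        new_vals = denormalize(Zd, centers, scales)[mask]
        delta = float(np.max(np.abs(new_vals - filled[mask])))
        filled[mask] = new_vals
        n_iter = it
        if single_pass or delta < tol:
            break

    out = table.copy()
    out.features = filled
    out.missing_mask = np.zeros_like(mask)
    out.held_out_values = None
    model = ImputationModel(
        rank_d=int(rank_d),
        column_centers=centers,
        column_scales=scales,
        n_iterations_run=n_iter,
        converged=bool(single_pass or delta < tol),
        final_delta=delta,
        explained_mass=explained,
    )
    return out, model


def recovery_error(masked: TelemonitoringTable, imputed: TelemonitoringTable) -> dict:
    """Score imputed values against the truth retained by masking.

    ``masked`` must be the table produced by
    :func:`updrs.dataio.mask_random_entries` (it carries the held-out
    truth); ``imputed`` the dense table returned by :func:`impute`.
    """
    if masked.held_out_values is None:
        raise ValueError("masked table carries no held-out truth")
    truth = masked.held_out_values
    pred = imputed.features[masked.missing_mask]
    abs_err = np.abs(pred - truth)
    denom = np.maximum(np.abs(truth), 1e-12)
    return {
        "rmse": float(np.sqrt(np.mean((pred - truth) ** 2))),
        "mae": float(np.mean(abs_err)),
        "max_relative": float(np.max(abs_err / denom)),
        "n_cells": int(truth.size),
    }
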