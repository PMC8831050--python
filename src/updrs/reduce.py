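"""Pearson correlation and PCA decorrelation.

Voice features in telemonitoring data are heavily collinear; a PCA
projection onto the leading components removes that multicollinearity
before regression.  The basis is fit on training rows only and applied
to held-out rows, so no information leaks across evaluation folds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class PCABasis:
    component_vectors: np.ndarray  # (n_retained, n_features), orthonormal rows
    explained_variance_ratio: np.ndarray
    centers: np.ndarray
    n_retained: int

    def to_dict(self) -> dict:
        return {
            "component_vectors": self.component_vectors.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
            "centers": self.centers.tolist(),
            "n_retained": self.n_retained,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PCABasis":
        return cls(
            component_vectors=np.asarray(d["component_vectors"]),
            explained_variance_ratio=np.asarray(d["explained_variance_ratio"]),
            centers=np.asarray(d["centers"]),
            n_retained=int(d["n_retained"]),
        )


def pcc(x, y) -> float:
    """Pearson's correlation coefficient R between two sequences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be 1-D sequences of equal length >= 2")
    xd = x - x.mean()
    yd = y - y.mean()
    vx = np.dot(xd, xd)
    vy = np.dot(yd, yd)
    if vx == 0.0 or vy == 0.0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(np.dot(xd, yd) / np.sqrt(vx * vy))


def fit_pca(features: np.ndarray, variance_threshold: float = 0.95) -> PCABasis:
    """Fit a PCA basis retaining the fewest components whose cumulative
    explained variance reaches ``variance_threshold``.

    Eigenvector sign is fixed by making each component's largest-magnitude
    loading positive, so the basis is reproducible across linear-algebra
    backends.  Variance uses the n-1 denominator.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a dense 2-D block with >= 2 rows")
    if not 0.0 < variance_threshold <= 1.0:
        raise ValueError("variance_threshold must lie in (0, 1]")
    centers = X.mean(axis=0)
    Xc = X - centers
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigvals = s ** 2 / (X.shape[0] - 1)
    total = eigvals.sum()
    ratio = eigvals / total if total > 0 else np.zeros_like(eigvals)
    cum = np.cumsum(ratio)
    n_retained = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
    n_retained = min(n_retained, len(ratio))
    comps = Vt[:n_retained]
    # sign convention: largest-magnitude loading positive
    for i in range(comps.shape[0]):
        j = np.argmax(np.abs(comps[i]))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    return PCABasis(
        component_vectors=comps,
        explained_variance_ratio=ratio[:n_retained],
        centers=centers,
        n_retained=n_retained,
    )


def transform(features: np.ndarray, basis: PCABasis) -> np.ndarray:
    """Project rows onto the retained components (after centering)."""
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != basis.centers.size:
        raise ValueError(
            f"feature count {X.shape[1]} does not match basis ({basis.centers.size})"
        )
    return (X - basis.centers) @ basis.component_vectors.T
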