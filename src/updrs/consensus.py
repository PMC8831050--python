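"""Cluster-ensemble consensus functions.

Several base clusterings of the same rows (e.g. Gaussian-mixture EM at
several k, SOMs at several map sizes) are fused into a single consensus
partition.  Three consensus functions are provided:

``majority_vote``
    Align every partition's labels to the first via optimal (Hungarian)
    matching, then give each row its modal aligned label.

``cspa_partition``
    Cluster-based Similarity Partitioning: the ensemble induces a
    co-association similarity S (fraction of partitions co-clustering
    each pair); rows are re-clustered by cutting an average-linkage
    dendrogram of 1 - S at the requested number of groups.

``hgpa_partition``
    Hypergraph partitioning: every cluster of every partition becomes a
    hyperedge over the rows; the consensus is a balanced k-way split of
    the rows minimising the number of cut hyperedges, found by
    multi-restart greedy vertex-move refinement.

All three are label-permutation invariant and map an ensemble of B
identical partitions back to that partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform


@dataclass
class Partition:
    """A hard assignment of every row to one of ``k`` clusters.

    Labels live in {0..k-1}; clusters may be empty (a SOM node that won
    no rows keeps its index so map geometry stays addressable).
    """

    labels: np.ndarray
    k: int
    source: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise ValueError("labels must be one-dimensional")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= self.k):
            raise ValueError("labels must lie in {0..k-1}")

    @property
    def n_rows(self) -> int:
        return self.labels.size

    def canonicalize(self) -> "Partition":
        """Relabel clusters in order of first appearance and drop empty
        label slots.  The canonical form is invariant under any
        permutation of the label names, which makes the consensus
        functions that consume it label-permutation invariant."""
        remap: dict[int, int] = {}
        out = np.empty_like(self.labels)
        for i, l in enumerate(self.labels):
            if l not in remap:
                remap[l] = len(remap)
            out[i] = remap[l]
        return Partition(labels=out, k=max(len(remap), 1), source=self.source)

    def clusters(self) -> list[np.ndarray]:
        """Row indices per cluster, including empty clusters."""
        return [np.flatnonzero(self.labels == c) for c in range(self.k)]


@dataclass
class ClusterEnsemble:
    partitions: list[Partition]
    target_k: int | None = None

    def __post_init__(self) -> None:
        if len(self.partitions) < 2:
            raise ValueError("an ensemble needs at least 2 partitions")
        n = self.partitions[0].n_rows
        if any(p.n_rows != n for p in self.partitions):
            raise ValueError("all partitions must label the same row set")
        if self.target_k is None:
            # the consensus k is never dictated by any single member;
            # the median of the members' k is the default
            self.target_k = int(np.median([p.k for p in self.partitions]))

    @property
    def n_rows(self) -> int:
        return self.partitions[0].n_rows

    @property
    def size(self) -> int:
        return len(self.partitions)


@dataclass
class Hypergraph:
    n_vertices: int
    hyperedges: list[np.ndarray]
    weights: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.weights is None:
            self.weights = np.ones(len(self.hyperedges))
        for e in self.hyperedges:
            if len(e) == 0:
                raise ValueError("empty hyperedge")


def build_coassociation(ensemble: ClusterEnsemble) -> np.ndarray:
    """Co-association matrix: S[i, j] = fraction of ensemble partitions
    placing rows i and j in the same cluster.  Symmetric, unit diagonal."""
    n = ensemble.n_rows
    S = np.zeros((n, n))
    for part in ensemble.partitions:
        lab = part.labels
        S += lab[:, None] == lab[None, :]
    return S / ensemble.size


def cspa_partition(S: np.ndarray, target_k: int, seed: int = 0) -> Partition:
    """Re-cluster rows from their co-association similarity.

    Average-linkage agglomeration on the dissimilarity 1 - S, cut at
    ``target_k`` groups.  Agglomeration is deterministic, so ``seed`` is
    accepted only for interface uniformity with the other consensus
    functions.
    """
    n = S.shape[0]
    if S.shape != (n, n):
        raise ValueError("S must be square")
    if not 2 <= target_k <= n:
        raise ValueError(f"target_k must lie in [2, {n}]")
    D = 1.0 - S
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0  # enforce exact symmetry against float asymmetry
    Z = linkage(squareform(D, checks=False), method="average")
    raw = fcluster(Z, t=target_k, criterion="maxclust")
    # relabel to 0..k-1 in order of first appearance (determinism)
    remap: dict[int, int] = {}
    out = np.empty(n, dtype=int)
    for i, r in enumerate(raw):
        if r not in remap:
            remap[r] = len(remap)
        out[i] = remap[r]
    return Partition(labels=out, k=target_k, source=f"cspa(k={target_k})")


def build_hypergraph(ensemble: ClusterEnsemble) -> Hypergraph:
    """One hyperedge per nonempty cluster of every ensemble partition."""
    edges = []
    for part in ensemble.partitions:
        part = part.canonicalize()
        for members in part.clusters():
            if len(members):
                edges.append(members)
    return Hypergraph(n_vertices=ensemble.n_rows, hyperedges=edges)


def _cut_count(assign: np.ndarray, edges: list[np.ndarray]) -> int:
    return sum(1 for e in edges if np.unique(assign[e]).size > 1)


def _rebalance(assign: np.ndarray, k: int, lo: int, hi: int, rng: np.random.Generator) -> np.ndarray:
    """Move vertices out of oversized parts into undersized ones."""
    assign = assign.copy()
    sizes = np.bincount(assign, minlength=k)
    order = rng.permutation(assign.size)
    for v in order:
        p = assign[v]
        if sizes[p] > hi or (sizes[p] > lo and (sizes < lo).any()):
            q = int(np.argmin(sizes))
            if q != p and sizes[q] < hi:
                assign[v] = q
                sizes[p] -= 1
                sizes[q] += 1
    return assign


def _greedy_refine(assign: np.ndarray, k: int, edges: list[np.ndarray],
                   vertex_edges: list[list[int]], lo: int, hi: int,
                   rng: np.random.Generator, max_passes: int = 30) -> tuple[np.ndarray, int]:
    """Single-vertex-move hill climbing on the hyperedge cut.

    Maintains, per hyperedge, the count of its vertices in each part, so
    a move's cut delta costs O(edges incident to the vertex)."""
    n = assign.size
    cnt = np.zeros((len(edges), k), dtype=int)
    for ei, e in enumerate(edges):
        for p, c in zip(*np.unique(assign[e], return_counts=True)):
            cnt[ei, p] = c
    sizes = np.bincount(assign, minlength=k)
    cut = int((np.count_nonzero(cnt, axis=1) > 1).sum())

    for _ in range(max_passes):
        improved = False
        for v in rng.permutation(n):
            p = assign[v]
            if sizes[p] - 1 < lo:
                continue
            inc = vertex_edges[v]
            best_q, best_delta = -1, 0
            for q in range(k):
                if q == p or sizes[q] + 1 > hi:
                    continue
                delta = 0
                for ei in inc:
                    spanned = np.count_nonzero(cnt[ei])
                    was_cut = spanned > 1
                    # simulate moving v from p to q on edge ei
                    new_spanned = spanned
                    if cnt[ei, p] == 1:
                        new_spanned -= 1
                    if cnt[ei, q] == 0:
                        new_spanned += 1
                    now_cut = new_spanned > 1
                    delta += int(now_cut) - int(was_cut)
                if delta < best_delta:
                    best_delta, best_q = delta, q
            if best_q >= 0:
                for ei in inc:
                    cnt[ei, p] -= 1
                    cnt[ei, best_q] += 1
                sizes[p] -= 1
                sizes[best_q] += 1
                assign[v] = best_q
                cut += best_delta
                improved = True
        if not improved:
            break
    return assign, cut


def hgpa_partition(H: Hypergraph, target_k: int, imbalance_tolerance: float = 0.2,
                   n_restarts: int = 20, seed: int = 0) -> Partition:
    """Balanced minimal hyperedge cut by multi-restart greedy refinement.

    Every part's size must stay within (1 +/- imbalance_tolerance) of
    n/target_k.  One restart is seeded from an agglomerative clustering
    of the shared-hyperedge-count similarity (then rebalanced); the rest
    start from random balanced assignments.  The best cut found wins;
    deterministic given ``seed``.
    """
    n = H.n_vertices
    if target_k < 2:
        raise ValueError("target_k must be >= 2")
    lo = int(np.floor((1.0 - imbalance_tolerance) * n / target_k))
    hi = int(np.ceil((1.0 + imbalance_tolerance) * n / target_k))
    lo = max(lo, 1)
    if target_k * lo > n or target_k * hi < n:
        raise ValueError(
            f"imbalance tolerance {imbalance_tolerance} infeasible for "
            f"{n} vertices in {target_k} parts"
        )
    edges = H.hyperedges
    vertex_edges: list[list[int]] = [[] for _ in range(n)]
    for ei, e in enumerate(edges):
        for v in e:
            vertex_edges[v].append(ei)

    rng = np.random.default_rng(seed)
    best_assign, best_cut = None, np.inf

    # informed start: vertices sharing many hyperedges belong together
    S = np.zeros((n, n))
    for e in edges:
        S[np.ix_(e, e)] += 1.0
    S /= max(S.max(), 1.0)
    D = 1.0 - S
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    raw = fcluster(Z, t=target_k, criterion="maxclust") - 1
    informed = _rebalance(raw, target_k, lo, hi, np.random.default_rng(seed))

    starts = [informed]
    for _ in range(max(n_restarts - 1, 0)):
        perm = rng.permutation(n)
        a = np.empty(n, dtype=int)
        bounds = np.linspace(0, n, target_k + 1).astype(int)
        for p in range(target_k):
            a[perm[bounds[p]:bounds[p + 1]]] = p
        starts.append(a)

    for start in starts:
        assign, cut = _greedy_refine(start.copy(), target_k, edges, vertex_edges, lo, hi, rng)
        if cut < best_cut:
            best_cut, best_assign = cut, assign.copy()

    return Partition(labels=best_assign, k=target_k, source=f"hgpa(k={target_k})")


def align_labels(reference: Partition, other: Partition) -> Partition:
    """Relabel ``other`` to maximise overlap with ``reference``.

    Optimal one-to-one matching of cluster labels via the Hungarian
    method on the contingency table; surplus clusters (when other.k >
    reference.k) keep fresh labels beyond reference.k.
    """
    if reference.n_rows != other.n_rows:
        raise ValueError("partitions must label the same rows")
    cont = np.zeros((other.k, reference.k))
    np.add.at(cont, (other.labels, reference.labels), 1)
    rows, cols = linear_sum_assignment(-cont)
    mapping = {int(r): int(c) for r, c in zip(rows, cols)}
    fresh = reference.k
    for c in range(other.k):
        if c not in mapping:
            mapping[c] = fresh
            fresh += 1
    new_labels = np.array([mapping[c] for c in other.labels])
    return Partition(labels=new_labels, k=max(fresh, reference.k), source=other.source)


def majority_vote(ensemble: ClusterEnsemble) -> Partition:
    """Consensus by per-row majority over label-aligned partitions.

    Every partition is aligned to the first; each row then takes its
    most frequent aligned label.  A tie is broken in favour of the label
    held by the earliest partition in ensemble order among the tied.
    """
    canon = [p.canonicalize() for p in ensemble.partitions]
    aligned = [canon[0]]
    for part in canon[1:]:
        aligned.append(align_labels(canon[0], part))
    max_k = max(p.k for p in aligned)
    votes = np.zeros((ensemble.n_rows, max_k), dtype=int)
    for part in aligned:
        votes[np.arange(ensemble.n_rows), part.labels] += 1
    n = ensemble.n_rows
    labels = np.empty(n, dtype=int)
    stacked = np.stack([p.labels for p in aligned])  # (B, n)
    for i in range(n):
        row = votes[i]
        top = row.max()
        tied = np.flatnonzero(row == top)
        if tied.size == 1:
            labels[i] = tied[0]
        else:
            tied_set = set(tied.tolist())
            for b in range(stacked.shape[0]):
                if stacked[b, i] in tied_set:
                    labels[i] = stacked[b, i]
                    break
    return Partition(labels=labels, k=max_k, source="majority_vote")
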