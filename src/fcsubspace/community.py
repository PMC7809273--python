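"""Multi-subject multilayer community detection by modularity maximization.

Each subject's functional connectivity matrix is one layer. The multilayer
quality function uses a uniform (flat) null inside each layer and an
all-to-all categorical coupling between layers::

    Q = sum_s sum_{i != j} (W^s_ij - gamma) [g_is = g_js]
        + 2 omega sum_i sum_{s<r} [g_is = g_ir]

gamma is the structural resolution (larger gamma -> more, smaller
communities); omega rewards a node for keeping one community across
subjects. The uniform null (W - gamma rather than a degree-based null) is
what makes the sampled negative gamma values meaningful on signed
correlation matrices; a Newman-Girvan-style null is available behind a
flag. Q is maximized with a generalized Louvain procedure over node-layer
units (greedy local moves then aggregation, best of ``n_restarts``).

Community variability across subjects is summarized by the per-node
normalized label entropy; the mean of the averaged normalized entropy over
a random (gamma, omega) sample (MANE) anchors the optimal-partition
selection rule: among partitions whose entropy lies within MANE +/- tol
and that contain no single-node community in any subject (optionally with
a total community count inside a given range), pick minimum gamma, then
maximum omega, then highest Q.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import adjusted_rand_score

__all__ = [
    "MultilayerModularity",
    "MultiSubjectPartition",
    "SweepResult",
    "MultiSubjectLouvain",
    "build_multilayer_modularity",
    "louvain_maximize",
    "modularity_value",
    "normalized_entropy",
    "sweep_parameter_space",
    "select_optimal_partition",
    "community_sizes",
    "match_partitions",
]


@dataclass
class MultilayerModularity:
    """Supra-modularity structure held as layer blocks plus a coupling scalar.

    The dense (R*S) x (R*S) supra-matrix is never materialized; the sparse
    form stores S dense R x R intra-layer blocks and the R*S*(S-1) coupling
    entries only.
    """

    layers: list[np.ndarray]
    gamma: float
    omega: float
    null_model: str = "uniform"

    @property
    def n_rois(self) -> int:
        return self.layers[0].shape[0]

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def intra(self, s: int) -> np.ndarray:
        """Intra-layer modularity block B^s (zero diagonal)."""
        w = self.layers[s]
        if self.null_model == "uniform":
            b = w - self.gamma
        else:  # newman-girvan style degree null on the positive weights
            k = w.sum(axis=0)
            two_m = k.sum()
            b = w - self.gamma * np.outer(k, k) / (two_m if two_m != 0 else 1.0)
        b = b.copy()
        np.fill_diagonal(b, 0.0)
        return b

    def to_sparse(self) -> sparse.csr_matrix:
        r, s = self.n_rois, self.n_layers
        blocks = sparse.block_diag([sparse.csr_matrix(self.intra(k)) for k in range(s)])
        if self.omega != 0 and s > 1:
            rows, cols, vals = [], [], []
            for a in range(s):
                for b in range(s):
                    if a == b:
                        continue
                    rows.extend(range(a * r, (a + 1) * r))
                    cols.extend(range(b * r, (b + 1) * r))
                    vals.extend([self.omega] * r)
            coupling = sparse.csr_matrix(
                (vals, (rows, cols)), shape=(r * s, r * s)
            )
            blocks = blocks + coupling
        return sparse.csr_matrix(blocks)


@dataclass
class MultiSubjectPartition:
    """Node-by-subject community labels with quality diagnostics."""

    labels: np.ndarray  # R x S, contiguous ids from 0
    gamma: float
    omega: float
    Q: float
    node_entropy: np.ndarray
    averaged_entropy: float
    community_count: int

    @property
    def n_rois(self) -> int:
        return self.labels.shape[0]

    @property
    def n_subjects(self) -> int:
        return self.labels.shape[1]

    def has_singleton(self) -> bool:
        """True if any subject assigns exactly one node to some community."""
        for s in range(self.labels.shape[1]):
            _, counts = np.unique(self.labels[:, s], return_counts=True)
            if np.any(counts == 1):
                return True
        return False


@dataclass
class SweepResult:
    samples: list[dict] = field(default_factory=list)
    mane: float = float("nan")


def build_multilayer_modularity(
    fc_matrices, gamma: float, omega: float, null_model: str = "uniform"
) -> MultilayerModularity:
    """Validate layers and wrap them with the (gamma, omega) parameters."""
    layers = []
    for idx, m in enumerate(fc_matrices):
        w = np.asarray(getattr(m, "values", m), dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"layer {idx} is not square")
        if not np.allclose(w, w.T, atol=1e-10):
            raise ValueError(f"layer {idx} is not symmetric")
        layers.append(w)
    shapes = {w.shape for w in layers}
    if len(shapes) != 1:
        raise ValueError(f"layers differ in shape: {sorted(shapes)}")
    return MultilayerModularity(layers=layers, gamma=gamma, omega=omega, null_model=null_model)


def modularity_value(labels: np.ndarray, structure: MultilayerModularity) -> float:
    """Unnormalized multilayer Q for an R x S label matrix."""
    labels = np.asarray(labels)
    r, s = labels.shape
    if r != structure.n_rois or s != structure.n_layers:
        raise ValueError("label matrix shape does not match structure")
    q = 0.0
    for k in range(s):
        b = structure.intra(k)
        same = labels[:, k][:, None] == labels[:, k][None, :]
        np.fill_diagonal(same, False)
        q += float(b[same].sum())
    if s > 1 and structure.omega != 0:
        for i in range(r):
            _, counts = np.unique(labels[i], return_counts=True)
            agree_pairs = int(np.sum(counts * (counts - 1) // 2))
            q += 2.0 * structure.omega * agree_pairs
    return q


# ---------------------------------------------------------------------------
# generalized Louvain on a sparse supra matrix


def _local_move(a: sparse.csr_matrix, labels: np.ndarray, rng: np.random.Generator) -> bool:
    """One full local-moving phase; mutates labels, returns whether any move happened."""
    n = a.shape[0]
    indptr, indices, data = a.indptr, a.indices, a.data
    improved_any = False
    improved = True
    while improved:
        improved = False
        for u in rng.permutation(n):
            row = slice(indptr[u], indptr[u + 1])
            nbr, w = indices[row], data[row]
            keep = nbr != u
            nbr, w = nbr[keep], w[keep]
            cur = labels[u]
            # weight from u to each candidate community
            cand = {}
            for v, wv in zip(nbr, w):
                cand[labels[v]] = cand.get(labels[v], 0.0) + wv
            stay = cand.get(cur, 0.0)
            best_c, best_gain = cur, 0.0
            # leaving to a fresh singleton is gain -2*stay
            if -stay > best_gain + 1e-12:
                best_c, best_gain = -1, -stay
            for c, wc in cand.items():
                if c == cur:
                    continue
                gain = wc - stay
                if gain > best_gain + 1e-12:
                    best_c, best_gain = c, gain
            if best_c != cur and best_gain > 1e-12:
                labels[u] = labels.max() + 1 if best_c == -1 else best_c
                improved = True
                improved_any = True
    return improved_any


def _aggregate(a: sparse.csr_matrix, labels: np.ndarray) -> tuple[sparse.csr_matrix, np.ndarray]:
    uniq, compact = np.unique(labels, return_inverse=True)
    k = uniq.size
    agg = sparse.csr_matrix(
        (np.ones(labels.size), (np.arange(labels.size), compact)),
        shape=(labels.size, k),
    )
    return sparse.csr_matrix(agg.T @ a @ agg), compact


def _louvain_once(
    a: sparse.csr_matrix, rng: np.random.Generator, init: np.ndarray | None = None
) -> np.ndarray:
    """One randomized run: local moves, aggregation ladder, then refinement.

    After the hierarchical (aggregate-and-move) ladder converges, the flat
    unit-level labels are refined by another local-move pass; the ladder and
    refinement alternate until a full cycle makes no move. The refinement
    lets single units escape super-nodes the plain hierarchy froze them
    into, which plain two-phase Louvain cannot do. ``init`` seeds the run
    with a starting partition (default: all singletons).
    """
    n = a.shape[0]
    labels = np.arange(n) if init is None else init.copy()
    while True:
        moved_fine = _local_move(a, labels, rng)
        graph, membership = _aggregate(a, labels)
        moved_coarse = False
        while True:
            clabels = np.arange(graph.shape[0])
            if not _local_move(graph, clabels, rng):
                break
            moved_coarse = True
            graph, compact = _aggregate(graph, clabels)
            membership = compact[membership]
        labels = membership
        if not (moved_fine or moved_coarse):
            return labels


def _relabel_contiguous(labels: np.ndarray) -> np.ndarray:
    """Relabel to contiguous ids ordered by first appearance (row-major)."""
    flat = labels.ravel()
    _, first = np.unique(flat, return_index=True)
    order = flat[np.sort(first)]
    mapping = {old: new for new, old in enumerate(order)}
    return np.vectorize(mapping.get)(labels)


def louvain_maximize(
    structure: MultilayerModularity,
    n_restarts: int = 5,
    seed: int | np.random.Generator = 0,
) -> MultiSubjectPartition:
    """Best-of-restarts generalized Louvain over node-layer units.

    Node visit order is shuffled per restart from the seed; Q never
    decreases across phases by construction, and the highest-Q restart is
    returned with labels relabeled to contiguous ids by first appearance.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a = structure.to_sparse()
    r, s = structure.n_rois, structure.n_layers
    n = r * s
    best_labels, best_q = None, -np.inf
    for restart in range(n_restarts):
        # first restart grows from singletons; later ones start from random
        # coarse partitions, which escape local optima the greedy growth
        # cannot (e.g. per-node columns locked by inter-layer coupling)
        init = None
        if restart > 0:
            k = int(rng.integers(2, max(3, min(n, 20))))
            init = rng.integers(0, k, n)
        membership = _louvain_once(a, rng, init)
        labels = membership.reshape(s, r).T  # units ordered layer-major
        q = modularity_value(labels, structure)
        if q > best_q:
            best_q, best_labels = q, labels
    labels = _relabel_contiguous(best_labels)
    node_h, avg_h = normalized_entropy(labels) if s >= 2 else (np.zeros(r), 0.0)
    return MultiSubjectPartition(
        labels=labels,
        gamma=structure.gamma,
        omega=structure.omega,
        Q=float(best_q),
        node_entropy=node_h,
        averaged_entropy=float(avg_h),
        community_count=int(labels.max()) + 1,
    )


class MultiSubjectLouvain(ClusterMixin, BaseEstimator):
    """Sklearn-style front end: fit a list of FC matrices, read ``labels_``.

    Parameters mirror :func:`louvain_maximize`; fitted attributes are
    ``labels_`` (R x S), ``Q_``, ``node_entropy_``, ``averaged_entropy_``
    and ``community_count_``.
    """

    def __init__(
        self,
        gamma: float = 0.0,
        omega: float = 0.1,
        n_restarts: int = 5,
        null_model: str = "uniform",
        random_state: int = 0,
    ):
        self.gamma = gamma
        self.omega = omega
        self.n_restarts = n_restarts
        self.null_model = null_model
        self.random_state = random_state

    def fit(self, X, y=None):
        structure = build_multilayer_modularity(X, self.gamma, self.omega, self.null_model)
        part = louvain_maximize(structure, self.n_restarts, self.random_state)
        self.partition_ = part
        self.labels_ = part.labels
        self.Q_ = part.Q
        self.node_entropy_ = part.node_entropy
        self.averaged_entropy_ = part.averaged_entropy
        self.community_count_ = part.community_count
        return self


def normalized_entropy(labels: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-node label entropy across subjects, normalized to [0, 1].

    h_i = -sum_k p_k ln p_k / ln(max(K, 2)) where p_k is the fraction of
    subjects assigning node i to community k and K the partition's total
    community count; averaged_entropy is the mean over nodes.
    """
    labels = np.asarray(labels)
    if labels.ndim != 2 or labels.shape[1] < 2:
        raise ValueError("need an R x S label matrix with S >= 2")
    k_total = len(np.unique(labels))
    log_norm = np.log(max(k_total, 2))
    r, s = labels.shape
    h = np.empty(r)
    for i in range(r):
        _, counts = np.unique(labels[i], return_counts=True)
        p = counts / s
        h[i] = -np.sum(p * np.log(p)) / log_norm
    h = np.clip(h, 0.0, 1.0)
    return h, float(h.mean())


def sweep_parameter_space(
    fc_matrices,
    n_samples: int = 20000,
    gamma_range: tuple[float, float] = (-0.7, 1.0),
    omega_range: tuple[float, float] = (-0.5, 2.0),
    n_restarts: int = 1,
    seed: int | np.random.Generator = 0,
    null_model: str = "uniform",
) -> SweepResult:
    """Sample (gamma, omega) uniformly and keep one Louvain partition per draw.

    MANE is the mean of the averaged normalized entropy over all sampled
    partitions. Defaults follow the reference protocol (20,000 samples,
    gamma in [-0.7, 1], omega in [-0.5, 2]); pass a smaller ``n_samples``
    for desk-scale runs.
    """
    if n_samples < 10:
        raise ValueError("n_samples must be >= 10")
    if gamma_range[0] > gamma_range[1] or omega_range[0] > omega_range[1]:
        raise ValueError("parameter ranges must be ordered (low, high)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    samples = []
    for _ in range(n_samples):
        g = float(rng.uniform(*gamma_range))
        w = float(rng.uniform(*omega_range))
        structure = build_multilayer_modularity(fc_matrices, g, w, null_model)
        part = louvain_maximize(structure, n_restarts, rng)
        samples.append(
            {
                "gamma": g,
                "omega": w,
                "averaged_entropy": part.averaged_entropy,
                "community_count": part.community_count,
                "has_singleton": part.has_singleton(),
                "partition": part,
            }
        )
    mane = float(np.mean([s["averaged_entropy"] for s in samples]))
    return SweepResult(samples=samples, mane=mane)


def select_optimal_partition(
    sweep: SweepResult,
    tolerance: float = 0.02,
    community_range: tuple[int, int] | None = (5, 23),
) -> MultiSubjectPartition:
    """Apply the MANE +/- tolerance selection rule.

    Survivors must lie within ``tolerance`` of MANE, contain no single-node
    community in any subject, and (optionally) have a total community count
    inside ``community_range``. Ties resolve to minimum gamma, then maximum
    omega, then higher Q.
    """
    if not sweep.samples:
        raise ValueError("empty sweep")
    cands = [
        s
        for s in sweep.samples
        if abs(s["averaged_entropy"] - sweep.mane) <= tolerance and not s["has_singleton"]
    ]
    if community_range is not None:
        lo, hi = community_range
        cands = [s for s in cands if lo <= s["community_count"] <= hi]
    if not cands:
        raise ValueError(
            "no partition satisfies the selection rule; relax the tolerance "
            "or the community-count range"
        )
    best = min(cands, key=lambda s: (s["gamma"], -s["omega"], -s["partition"].Q))
    return best["partition"]


def community_sizes(partition: MultiSubjectPartition | np.ndarray) -> np.ndarray:
    """Subjects x communities node-count table; every row sums to R."""
    labels = partition.labels if isinstance(partition, MultiSubjectPartition) else np.asarray(partition)
    k = int(labels.max()) + 1
    r, s = labels.shape
    counts = np.zeros((s, k), dtype=int)
    for j in range(s):
        counts[j] = np.bincount(labels[:, j], minlength=k)
    assert counts.sum(axis=1).tolist() == [r] * s
    return counts


def _consensus(labels: np.ndarray) -> np.ndarray:
    """Modal label per node across subjects (ties -> smaller label)."""
    r = labels.shape[0]
    out = np.empty(r, dtype=int)
    for i in range(r):
        vals, counts = np.unique(labels[i], return_counts=True)
        out[i] = vals[np.argmax(counts)]
    return out


def match_partitions(p1, p2) -> dict:
    """Greedy maximal-overlap matching between two partitions' consensus labels.

    Returns the label mapping (community of p1 -> community of p2), the
    fraction of nodes whose matched labels agree, and the adjusted Rand
    index of the consensus labelings.
    """
    l1 = p1.labels if isinstance(p1, MultiSubjectPartition) else np.asarray(p1)
    l2 = p2.labels if isinstance(p2, MultiSubjectPartition) else np.asarray(p2)
    c1 = _consensus(l1) if l1.ndim == 2 else l1
    c2 = _consensus(l2) if l2.ndim == 2 else l2
    if c1.size != c2.size:
        raise ValueError("partitions cover different node counts")
    ids1, ids2 = np.unique(c1), np.unique(c2)
    overlap = np.zeros((ids1.size, ids2.size), dtype=int)
    for a, ia in enumerate(ids1):
        for b, ib in enumerate(ids2):
            overlap[a, b] = int(np.sum((c1 == ia) & (c2 == ib)))
    mapping = {}
    used_rows, used_cols = set(), set()
    flat = sorted(
        ((overlap[a, b], a, b) for a in range(ids1.size) for b in range(ids2.size)),
        key=lambda t: (-t[0], t[1], t[2]),
    )
    for val, a, b in flat:
        if a in used_rows or b in used_cols or val == 0:
            continue
        mapping[int(ids1[a])] = int(ids2[b])
        used_rows.add(a)
        used_cols.add(b)
    matched = sum(
        int(np.sum((c1 == a) & (c2 == b))) for a, b in mapping.items()
    )
    return {
        "mapping": mapping,
        "matched_fraction": matched / c1.size,
        "ari": float(adjusted_rand_score(c1, c2)),
    }
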