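"""Functional connectivity matrices, edge vectorization, and edgewise group statistics.

Connectivity is the Pearson correlation between ROI time courses. Edges are
stored as the upper triangle in lexicographic (i, j), i < j, 0-based order;
this convention is shared by every module that serializes edge tables.
Group comparisons run on Fisher-z values with pooled-variance t tests,
Benjamini-Hochberg FDR across edges, and a permutation "tmax" family-wise
correction built from the null distribution of the maximum |t| over edges.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ConnectivityMatrix",
    "EdgeVector",
    "GroupComparisonResult",
    "pearson_fc",
    "fisher_z",
    "fisher_z_values",
    "n_edges",
    "edge_index_pairs",
    "vectorize_edges",
    "devectorize",
    "edgewise_group_test",
    "tmax_permutation_test",
    "regress_global_signal",
    "fd_edge_association",
]

_Z_CLIP = 1.0 - 1e-7


@dataclass
class ConnectivityMatrix:
    """Symmetric R x R connectivity for one subject.

    ``kind`` is ``"pearson"`` (unit diagonal, entries in [-1, 1]) or
    ``"fisher_z"`` (atanh-transformed, zero diagonal).
    """

    values: np.ndarray
    kind: str = "pearson"
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("connectivity matrix must be symmetric")
        if self.kind not in ("pearson", "fisher_z"):
            raise ValueError(f"unknown kind {self.kind!r}")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


@dataclass
class EdgeVector:
    """Vectorized upper triangle of a connectivity matrix.

    ``values[k]`` corresponds to the pair ``edge_index_pairs(R)[k]``; the
    mapping is lexicographic in (i, j) with i < j and round-trips losslessly
    through :func:`devectorize`.
    """

    values: np.ndarray
    n_rois: int
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size != n_edges(self.n_rois):
            raise ValueError(
                f"edge vector length {self.values.size} does not match "
                f"R={self.n_rois} (expected {n_edges(self.n_rois)})"
            )

    @property
    def index_map(self) -> list[tuple[int, int]]:
        i, j = edge_index_pairs(self.n_rois)
        return list(zip(i.tolist(), j.tolist()))


def n_edges(n_rois: int) -> int:
    """Number of undirected edges E = R(R-1)/2."""
    return n_rois * (n_rois - 1) // 2


def edge_index_pairs(n_rois: int) -> tuple[np.ndarray, np.ndarray]:
    """(i, j) index arrays of the upper triangle in lexicographic order."""
    return np.triu_indices(n_rois, k=1)


def pearson_fc(values: np.ndarray, subject_id: str = "") -> ConnectivityMatrix:
    """Pearson correlation matrix across timepoints for an R x T series.

    Raises if any ROI has zero temporal variance (correlation undefined).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2:
        raise ValueError("time series must be 2-D (ROIs x timepoints)")
    if x.shape[1] < 3:
        raise ValueError("need at least 3 timepoints")
    sd = x.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"zero-variance ROI(s): {dead.tolist()}")
    r = np.corrcoef(x)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(r, kind="pearson", subject_id=subject_id)


def fisher_z_values(r: np.ndarray) -> np.ndarray:
    """atanh with clipping at |r| <= 1 - 1e-7 so perfect correlations stay finite."""
    return np.arctanh(np.clip(np.asarray(r, dtype=float), -_Z_CLIP, _Z_CLIP))


def fisher_z(m: ConnectivityMatrix) -> ConnectivityMatrix:
    """Fisher z-transform of a Pearson matrix; diagonal set to 0."""
    if m.kind != "pearson":
        raise ValueError("fisher_z expects a Pearson matrix")
    z = fisher_z_values(m.values)
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(z, kind="fisher_z", subject_id=m.subject_id)


def vectorize_edges(m: ConnectivityMatrix) -> EdgeVector:
    r = m.n_rois
    i, j = edge_index_pairs(r)
    return EdgeVector(m.values[i, j], n_rois=r, subject_id=m.subject_id)


def devectorize(v: EdgeVector, kind: str = "pearson") -> ConnectivityMatrix:
    r = v.n_rois
    out = np.zeros((r, r))
    i, j = edge_index_pairs(r)
    out[i, j] = v.values
    out[j, i] = v.values
    np.fill_diagonal(out, 1.0 if kind == "pearson" else 0.0)
    return ConnectivityMatrix(out, kind=kind, subject_id=v.subject_id)


def _stack(edges: list[EdgeVector] | np.ndarray) -> np.ndarray:
    if isinstance(edges, np.ndarray):
        return np.atleast_2d(np.asarray(edges, dtype=float))
    return np.vstack([e.values for e in edges])


@dataclass
class GroupComparisonResult:
    """Edgewise two-sample comparison with multiplicity control.

    ``q`` is the BH step-up FDR value, ``p_tmax`` the permutation family-wise
    adjusted p (None unless a tmax test ran). Significance masks are nested:
    the alpha=.01 mask is a subset of the alpha=.05 mask.
    """

    t: np.ndarray
    p: np.ndarray
    q: np.ndarray
    p_tmax: np.ndarray | None = None
    masks: dict = field(default_factory=dict)
    n_degenerate: int = 0

    def significant(self, alpha: float = 0.05, method: str = "fdr") -> np.ndarray:
        key = (round(float(alpha), 10), method)
        if key in self.masks:
            return self.masks[key]
        src = self.q if method == "fdr" else self.p_tmax
        if src is None:
            raise ValueError(f"no {method} values available")
        return src <= alpha


def _group_tstats(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pooled-variance two-sample t per column; degenerate columns get t=0, p=1."""
    na, nb = a.shape[0], b.shape[0]
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    df = na + nb - 2
    sp2 = ((na - 1) * va + (nb - 1) * vb) / df
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (ma - mb) / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(se > 0, p, 1.0)
    return t, p


def edgewise_group_test(
    group_a: list[EdgeVector] | np.ndarray,
    group_b: list[EdgeVector] | np.ndarray,
    alpha: float = 0.05,
) -> GroupComparisonResult:
    """Pooled-variance t per edge on Fisher-z values with BH-FDR across edges.

    ``group_a`` / ``group_b`` are per-subject edge vectors (assumed already on
    the Fisher-z scale). Zero-pooled-variance edges are reported with p = 1
    and counted in ``n_degenerate``.
    """
    a, b = _stack(group_a), _stack(group_b)
    if a.shape[1] != b.shape[1]:
        raise ValueError("edge counts differ between groups")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    t, p = _group_tstats(a, b)
    n_degen = int(np.sum((a.var(axis=0) == 0) & (b.var(axis=0) == 0)))
    if n_degen:
        warnings.warn(f"{n_degen} degenerate zero-variance edge(s) set to p=1")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    masks = {
        (round(float(alpha), 10), "fdr"): q <= alpha,
        (0.05, "fdr"): q <= 0.05,
        (0.01, "fdr"): q <= 0.01,
    }
    return GroupComparisonResult(t=t, p=p, q=q, masks=masks, n_degenerate=n_degen)


def tmax_permutation_test(
    group_a: list[EdgeVector] | np.ndarray,
    group_b: list[EdgeVector] | np.ndarray,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    alpha: float = 0.05,
) -> GroupComparisonResult:
    """Family-wise corrected edgewise test via the max-|t| permutation null.

    Subject labels are shuffled ``n_perm`` times; each edge's adjusted p is
    (1 + #{permutations with max|t| >= |t_edge|}) / (n_perm + 1). When the
    number of distinct label assignments does not exceed ``n_perm`` the test
    enumerates them exactly instead (p = count / n_assignments, the identity
    assignment included).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    a, b = _stack(group_a), _stack(group_b)
    if a.shape[1] != b.shape[1]:
        raise ValueError("edge counts differ between groups")
    na, nb = a.shape[0], b.shape[0]
    x = np.vstack([a, b])
    n = na + nb
    t_obs, p_unadj = _group_tstats(a, b)
    abs_obs = np.abs(t_obs)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_exact = math.comb(n, na)
    if n_exact <= n_perm:
        assignments = itertools.combinations(range(n), na)
        max_ts = np.empty(n_exact)
        for k, idx_a in enumerate(assignments):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx_a)] = True
            tp, _ = _group_tstats(x[mask], x[~mask])
            max_ts[k] = np.abs(tp).max()
        p_adj = (max_ts[:, None] >= abs_obs[None, :]).sum(axis=0) / n_exact
    else:
        max_ts = np.empty(n_perm)
        for k in range(n_perm):
            perm = rng.permutation(n)
            tp, _ = _group_tstats(x[perm[:na]], x[perm[na:]])
            max_ts[k] = np.abs(tp).max()
        p_adj = (1.0 + (max_ts[:, None] >= abs_obs[None, :]).sum(axis=0)) / (n_perm + 1.0)

    _, q, _, _ = multipletests(p_unadj, method="fdr_bh")
    masks = {
        (round(float(alpha), 10), "tmax"): p_adj <= alpha,
        (0.05, "tmax"): p_adj <= 0.05,
        (0.01, "tmax"): p_adj <= 0.01,
    }
    return GroupComparisonResult(t=t_obs, p=p_unadj, q=q, p_tmax=p_adj, masks=masks)


def regress_global_signal(values: np.ndarray) -> np.ndarray:
    """Regress the across-ROI mean time course out of every ROI (GSR).

    Each ROI is replaced by its OLS residual on (intercept, global signal);
    output rows are orthogonal to the global signal.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need an R x T matrix with R >= 2")
    gs = x.mean(axis=0)
    if gs.std() == 0:
        raise ValueError("global signal is constant; GSR undefined")
    design = np.column_stack([np.ones_like(gs), gs])
    beta, *_ = np.linalg.lstsq(design, x.T, rcond=None)
    return x - (design @ beta).T


def fd_edge_association(
    edges_a: list[EdgeVector] | np.ndarray,
    edges_b: list[EdgeVector] | np.ndarray,
    fd_a: np.ndarray,
    fd_b: np.ndarray,
) -> dict:
    """Per-edge correlation of mean framewise displacement with edge strength.

    Within each group the across-subject Pearson r of FD vs edge value is
    Fisher-z transformed; groups are compared with the two-sample z test for
    independent correlations, BH-FDR corrected across edges. Swapping the
    groups negates the difference statistic.
    """
    a, b = _stack(edges_a), _stack(edges_b)
    fd_a = np.asarray(fd_a, dtype=float)
    fd_b = np.asarray(fd_b, dtype=float)
    if not (np.all(np.isfinite(fd_a)) and np.all(np.isfinite(fd_b))):
        raise ValueError("FD values must be finite")
    if np.ptp(fd_a) == 0 or np.ptp(fd_b) == 0:
        raise ValueError("FD constant within a group; correlation undefined")
    na, nb = len(fd_a), len(fd_b)
    if na < 4 or nb < 4:
        raise ValueError("need at least 4 subjects per group for the z comparison")

    def _corr_with(fd: np.ndarray, e: np.ndarray) -> np.ndarray:
        fd_c = fd - fd.mean()
        e_c = e - e.mean(axis=0)
        denom = np.sqrt((fd_c**2).sum()) * np.sqrt((e_c**2).sum(axis=0))
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(denom > 0, fd_c @ e_c / np.where(denom > 0, denom, 1.0), 0.0)
        return np.clip(r, -1.0, 1.0)

    r_a = _corr_with(fd_a, a)
    r_b = _corr_with(fd_b, b)
    z_a, z_b = fisher_z_values(r_a), fisher_z_values(r_b)
    se = math.sqrt(1.0 / (na - 3) + 1.0 / (nb - 3))
    z_diff = (z_a - z_b) / se
    p = 2.0 * stats.norm.sf(np.abs(z_diff))
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return {"r_a": r_a, "r_b": r_b, "z_a": z_a, "z_b": z_b, "z_diff": z_diff, "p": p, "q": q}
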