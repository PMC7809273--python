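"""Independent brute-force oracles used by the test suite only."""

from __future__ import annotations

import itertools
import math

import numpy as np


def exhaustive_max_modularity(supra: np.ndarray) -> float:
    """Maximum of Q = sum_{u != v} A_uv [g_u = g_v] over ALL set partitions.

    Backtracking enumeration of restricted-growth strings with incremental
    Q updates; feasible up to ~12 units (Bell(12) ~ 4.2e6 partitions). Uses
    numba when importable for the larger instances; falls back to pure
    Python otherwise.
    """
    a = np.ascontiguousarray(supra, dtype=np.float64)
    n = a.shape[0]
    try:
        from numba import njit

        return float(_numba_enumerate(njit(cache=False))(a, n))
    except Exception:  # pragma: no cover - numba available in practice
        return float(_py_enumerate(a, n))


def _numba_enumerate(jit):
    def kernel(a, n):
        assign = np.zeros(n, dtype=np.int64)
        max_label = np.zeros(n + 1, dtype=np.int64)
        q_partial = np.zeros(n + 1, dtype=np.float64)
        choice = np.zeros(n, dtype=np.int64)
        best = -1e300
        d = 1
        choice[1] = -1
        while d >= 1:
            choice[d] += 1
            if choice[d] > max_label[d] + 1:
                d -= 1
                continue
            b = choice[d]
            gain = 0.0
            for j in range(d):
                if assign[j] == b:
                    gain += a[d, j]
            qd = q_partial[d] + 2.0 * gain
            assign[d] = b
            if d == n - 1:
                if qd > best:
                    best = qd
            else:
                max_label[d + 1] = max(max_label[d], b)
                q_partial[d + 1] = qd
                d += 1
                choice[d] = -1
        return best

    return jit(kernel)


def _py_enumerate(a, n):
    best = -math.inf

    def recurse(d, labels, n_labels, q):
        nonlocal best
        if d == n:
            if q > best:
                best = q
            return
        for b in range(n_labels + 1):
            gain = 2.0 * sum(a[d, j] for j in range(d) if labels[j] == b)
            labels[d] = b
            recurse(d + 1, labels, max(n_labels, b + 1), q + gain)
        labels[d] = -1

    recurse(1, [0] + [-1] * (n - 1), 1, 0.0)
    return best


def tmax_exact_2v2(x_a: np.ndarray, x_b: np.ndarray) -> np.ndarray:
    """Adjusted p by literal enumeration of the C(4,2)=6 label assignments.

    Independent of the package implementation: t statistics computed from
    the textbook pooled-variance formula, one assignment at a time.
    """
    x = np.vstack([x_a, x_b])
    n, e = x.shape
    assert x_a.shape[0] == 2 and x_b.shape[0] == 2

    def pooled_t(ga, gb):
        out = np.zeros(e)
        for k in range(e):
            a, b = ga[:, k], gb[:, k]
            sp2 = (np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2)) / (len(a) + len(b) - 2)
            se = math.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
            out[k] = (a.mean() - b.mean()) / se if se > 0 else 0.0
        return out

    t_obs = np.abs(pooled_t(x_a, x_b))
    maxes = []
    for combo in itertools.combinations(range(n), 2):
        mask = np.zeros(n, dtype=bool)
        mask[list(combo)] = True
        maxes.append(np.max(np.abs(pooled_t(x[mask], x[~mask]))))
    maxes = np.array(maxes)
    return np.array([np.mean(maxes >= t) for t in t_obs])


def bh_stepup(p: np.ndarray) -> np.ndarray:
    """Literal textbook Benjamini-Hochberg step-up adjusted values."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running = min(running, p[idx] * m / rank_from_top)
        adj[idx] = running
    return adj


def noncentral_f_power_series(f2: float, u: int, v: int, alpha: float, n: int) -> float:
    """Power of the overall F test via the Poisson-mixture series.

    P(F' > c) = sum_j Poisson(lam/2)_j * P(F_{u+2j, v} > c*u/(u+2j)),
    an expansion independent of scipy's noncentral F implementation.
    """
    from scipy import stats

    lam = f2 * n
    c = stats.f.isf(alpha, u, v)
    total = 0.0
    for j in range(400):
        w = math.exp(-lam / 2) * (lam / 2) ** j / math.factorial(j)
        if w < 1e-16 and j > lam:
            break
        total += w * stats.f.sf(c * u / (u + 2 * j), u + 2 * j, v)
    return total
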