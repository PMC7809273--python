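"""Group-level common spatial component extraction and removal.

Each subject's R x T series (the "conventional space") is one block. The
top-k left singular vectors of every row-centered block span that subject's
dominant spatial subspace; the group-level common component is the dominant
eigenvector(s) of the average projector M = sum_i B_i B_i^T. Eigenvalues
divided by the number of subjects give a commonness score in (0, 1] — 1
means the direction lies in every subject's top-k subspace. Removing the
common component (projecting onto its orthocomplement) yields the
"individual subspace" that downstream connectivity analyses use.

Groups are always decomposed separately; pooling the groups before
extraction would absorb group differences into the shared component and is
deliberately not offered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .synthetic import CohortTimeSeries, RoiTimeSeries

__all__ = [
    "CommonComponent",
    "CommonBasisExtractor",
    "extract_common_basis",
    "remove_common_component",
    "compare_spatial_maps",
]


@dataclass
class CommonComponent:
    """Group-shared spatial basis.

    ``maps`` is R x C with orthonormal columns, sorted by non-increasing
    ``commonness_scores``; the sign of each column is fixed so its
    largest-magnitude entry is positive (reproducible serialization).
    """

    maps: np.ndarray
    commonness_scores: np.ndarray
    block_rank: int

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim == 1:
            self.maps = self.maps[:, None]
        gram = self.maps.T @ self.maps
        if not np.allclose(gram, np.eye(self.maps.shape[1]), atol=1e-8):
            raise ValueError("common-component columns must be orthonormal")
        if np.any(np.diff(self.commonness_scores) > 1e-12):
            raise ValueError("commonness scores must be non-increasing")

    @property
    def n_rois(self) -> int:
        return self.maps.shape[0]

    @property
    def n_components(self) -> int:
        return self.maps.shape[1]


def _as_blocks(X) -> list[np.ndarray]:
    if isinstance(X, CohortTimeSeries):
        return X.arrays()
    if isinstance(X, np.ndarray) and X.ndim == 3:
        return list(X)
    return [b.values if isinstance(b, RoiTimeSeries) else np.asarray(b, float) for b in X]


class CommonBasisExtractor(TransformerMixin, BaseEstimator):
    """Extract and remove the group-level common spatial component.

    Parameters
    ----------
    n_components : int, default=1
        Number of common spatial maps C. The pipeline default of 1 follows
        the standard recommendation for this decomposition.
    block_rank : int or None, default=None
        Rank k of each subject's retained subspace. ``None`` resolves to
        min(20, R-1, T-1): with full-rank blocks every direction is
        trivially common, so truncation is mandatory.

    Attributes
    ----------
    maps_ : ndarray of shape (R, C)
        Orthonormal common spatial maps.
    commonness_scores_ : ndarray of shape (C,)
        Eigenvalues of the average projector divided by the number of
        subjects; in (0, 1], non-increasing.
    block_rank_ : int
        The rank actually used per subject.
    """

    def __init__(self, n_components: int = 1, block_rank: int | None = None):
        self.n_components = n_components
        self.block_rank = block_rank

    def fit(self, X, y=None):
        blocks = _as_blocks(X)
        if len(blocks) < 2:
            raise ValueError("need at least 2 subjects to define a common component")
        r, t = blocks[0].shape
        for idx, b in enumerate(blocks):
            if b.shape != (r, t):
                raise ValueError(f"subject {idx} has shape {b.shape}, expected {(r, t)}")
        k = self.block_rank if self.block_rank is not None else min(20, r - 1, t - 1)
        if not (1 <= self.n_components <= k <= min(r, t)):
            raise ValueError(
                f"require 1 <= n_components={self.n_components} <= block_rank={k} <= min(R,T)"
            )

        m = np.zeros((r, r))
        for idx, b in enumerate(blocks):
            # remove each ROI's temporal mean (Pearson downstream is invariant
            # to it) and each timepoint's across-ROI mean: the global spatial
            # direction is trivially shared by construction in any multi-block
            # stack, so it must not masquerade as the common component.
            centered = b - b.mean(axis=1, keepdims=True)
            centered = centered - centered.mean(axis=0, keepdims=True)
            u, s, _ = np.linalg.svd(centered, full_matrices=False)
            if s[k - 1] <= max(r, t) * np.finfo(float).eps * s[0]:
                raise ValueError(f"subject {idx} block is rank-deficient below k={k}")
            bk = u[:, :k]
            m += bk @ bk.T
        eigvals, eigvecs = np.linalg.eigh(m)
        order = np.argsort(eigvals)[::-1][: self.n_components]
        maps = eigvecs[:, order]
        # sign convention: largest-magnitude entry positive
        for c in range(maps.shape[1]):
            if maps[np.argmax(np.abs(maps[:, c])), c] < 0:
                maps[:, c] = -maps[:, c]
        self.maps_ = maps
        self.commonness_scores_ = eigvals[order] / len(blocks)
        self.block_rank_ = k
        self.n_features_in_ = r
        return self

    def transform(self, X):
        """Project the common component out: Y - M M^T Y (idempotent)."""
        single = isinstance(X, (RoiTimeSeries, np.ndarray)) and not (
            isinstance(X, np.ndarray) and X.ndim == 3
        )
        blocks = [X.values if isinstance(X, RoiTimeSeries) else np.asarray(X, float)] if single else _as_blocks(X)
        m = self.maps_
        out = []
        for b in blocks:
            if b.shape[0] != m.shape[0]:
                raise ValueError(f"block has {b.shape[0]} rows, maps have {m.shape[0]}")
            out.append(b - m @ (m.T @ b))
        return out[0] if single else out

    def common(self) -> CommonComponent:
        return CommonComponent(
            maps=self.maps_.copy(),
            commonness_scores=self.commonness_scores_.copy(),
            block_rank=self.block_rank_,
        )


def extract_common_basis(
    cohort, n_components: int = 1, block_rank: int | None = None
) -> CommonComponent:
    """Functional wrapper over :class:`CommonBasisExtractor`."""
    return CommonBasisExtractor(n_components, block_rank).fit(cohort).common()


def remove_common_component(ts, common: CommonComponent):
    """Residualize a series (or list of series) against the common maps."""
    m = common.maps
    if isinstance(ts, RoiTimeSeries):
        if ts.n_rois != common.n_rois:
            raise ValueError("ROI count mismatch between series and common component")
        return RoiTimeSeries(ts.subject_id, ts.values - m @ (m.T @ ts.values))
    x = np.asarray(ts, dtype=float)
    if x.shape[0] != common.n_rois:
        raise ValueError("ROI count mismatch between series and common component")
    return x - m @ (m.T @ x)


def compare_spatial_maps(
    c1: CommonComponent,
    c2: CommonComponent,
    cohort_a: CohortTimeSeries | None = None,
    cohort_b: CohortTimeSeries | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """Column-wise |cosine| similarity of two common components.

    When the raw cohorts are supplied, a permutation p-value is attached:
    subjects are regrouped at random (group sizes preserved), the common
    component of each pseudo-group re-extracted, and the mean |cosine|
    between pseudo-group maps recomputed. The p-value is the add-one
    fraction of permutations whose similarity is <= the observed one, so a
    small p flags maps that are *more different* than chance regrouping
    predicts.
    """
    if c1.n_rois != c2.n_rois:
        raise ValueError("ROI count mismatch")
    if c1.n_components != c2.n_components:
        raise ValueError("component count mismatch")
    cosines = np.abs(np.sum(c1.maps * c2.maps, axis=0))
    report = {"abs_cosine": cosines, "mean_abs_cosine": float(cosines.mean())}
    if cohort_a is not None and cohort_b is not None:
        rng = np.random.default_rng(seed)
        blocks = cohort_a.arrays() + cohort_b.arrays()
        na = len(cohort_a)
        observed = report["mean_abs_cosine"]
        count = 0
        c, k = c1.n_components, c1.block_rank
        for _ in range(n_perm):
            perm = rng.permutation(len(blocks))
            ca = extract_common_basis([blocks[i] for i in perm[:na]], c, k)
            cb = extract_common_basis([blocks[i] for i in perm[na:]], c, k)
            sim = float(np.abs(np.sum(ca.maps * cb.maps, axis=0)).mean())
            if sim <= observed:
                count += 1
        report["p_permutation"] = (1.0 + count) / (n_perm + 1.0)
        report["n_perm"] = n_perm
    return report
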