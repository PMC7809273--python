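"""Synthetic two-group ROI time-series cohorts with planted structure.

The generator emulates denoised, parcellated resting-state data for two
groups at desk scale: each subject's R x T series mixes (i) a unit-variance
community time course shared within each of K communities, (ii) white
noise, and (iii) a group-shared spatial component with a subject-specific
temporal course. A configurable set of edges gains extra shared signal in
group B only, and behavioral scores are driven linearly by a sparse edge
set plus Gaussian noise. Ground truth (common map, partitions, planted
edges, behavior weights) is returned for recovery tests.

Signal model for node i of subject s (before the planted-edge boost)::

    x_i(t) = sqrt(a) * g_{c(i,s)}(t) + sqrt(1-a) * eps_i(t)
             + common_strength * m_i * h_s(t)

with a = ``intra_community_corr``, g_k independent standardized community
courses, eps white noise, m the unit-norm common map and h_s a standardized
per-subject course. For a planted pair (i, j) in group B the community+noise
part of both endpoints is scaled by sqrt(1 - diff_effect) and a shared
standardized latent enters with weight sqrt(diff_effect / n_i) where n_i is
the number of planted edges the node belongs to, so disjoint planted pairs
gain an extra correlation share of about ``diff_effect``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .connectivity import EdgeVector, fisher_z, pearson_fc, vectorize_edges

__all__ = [
    "CohortParams",
    "GroundTruth",
    "RoiTimeSeries",
    "CohortTimeSeries",
    "generate_cohort",
    "generate_behavior",
]


@dataclass
class RoiTimeSeries:
    """One subject's R x T denoised ROI signal."""

    subject_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or min(self.values.shape) < 2:
            raise ValueError("time series must be R x T with R, T >= 2")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite values in series for {self.subject_id}")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


@dataclass
class CohortTimeSeries:
    """Ordered collection of same-shape subject series for one group."""

    group_label: str
    subjects: list[RoiTimeSeries]
    roi_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        shapes = {s.values.shape for s in self.subjects}
        if len(shapes) > 1:
            raise ValueError(f"subjects differ in shape: {sorted(shapes)}")
        if self.subjects and not self.roi_labels:
            r = self.subjects[0].n_rois
            self.roi_labels = [f"ROI{k:03d}" for k in range(r)]
        if self.subjects and len(self.roi_labels) != self.subjects[0].n_rois:
            raise ValueError("roi_labels length does not match R")

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def n_rois(self) -> int:
        return self.subjects[0].n_rois

    def arrays(self) -> list[np.ndarray]:
        return [s.values for s in self.subjects]


@dataclass
class CohortParams:
    """Study conditions for the synthetic cohort.

    Defaults mirror a 116-ROI, 240-timepoint acquisition with roughly 20
    subjects per group and 7 communities; distributional choices for the
    covariates follow typical adult clinical-cohort demographics (age
    ~N(28, 7) truncated to [21, 65], education ~N(14.5, 2), sex Bernoulli(.5),
    mean FD ~ |N(0.074, 0.04)| mm).
    """

    n_rois: int = 116
    n_timepoints: int = 240
    n_subjects_per_group: tuple[int, int] = (22, 20)
    n_communities: int = 7
    common_strength: float = 1.0
    intra_community_corr: float = 0.6
    node_reassign_prob: float = 0.1
    diff_edges: tuple[tuple[int, int], ...] = ()
    diff_effect: float = 0.4
    behavior_edges: tuple[tuple[tuple[int, int], float], ...] = ()
    behavior_noise_sd: float = 1.0
    ar_coefficient: float = 0.0
    shared_base_partition: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_rois < 4:
            raise ValueError("n_rois must be >= 4")
        if self.n_timepoints < 8:
            raise ValueError("n_timepoints must be >= 8")
        if self.n_communities < 2:
            raise ValueError("n_communities must be >= 2")
        if self.n_communities > self.n_rois:
            raise ValueError("n_communities cannot exceed n_rois")
        if not (0 <= self.intra_community_corr < 1):
            raise ValueError("intra_community_corr must be in [0, 1)")
        if not (0 <= self.node_reassign_prob <= 1):
            raise ValueError("node_reassign_prob must be in [0, 1]")
        if self.common_strength < 0 or self.behavior_noise_sd < 0:
            raise ValueError("common_strength and behavior_noise_sd must be nonnegative")
        if self.diff_edges and not (0 <= self.diff_effect <= 1 - self.intra_community_corr):
            raise ValueError(
                "diff_effect must lie in [0, 1 - intra_community_corr]: the planted "
                "pair latent draws on the endpoints' private-noise share"
            )
        for i, j in self.diff_edges:
            if i == j:
                raise ValueError(f"self-loop planted edge ({i},{j})")
            if not (0 <= i < self.n_rois and 0 <= j < self.n_rois):
                raise ValueError(f"planted edge ({i},{j}) references node >= R")
        for (i, j), _ in self.behavior_edges:
            if i == j or not (0 <= i < self.n_rois and 0 <= j < self.n_rois):
                raise ValueError(f"invalid behavior edge ({i},{j})")


@dataclass
class GroundTruth:
    """Planted structure returned alongside the generated cohort."""

    common_map: np.ndarray
    base_partition: dict[str, np.ndarray]
    subject_partitions: dict[str, np.ndarray]  # R x n_subjects per group
    true_diff_edges: frozenset[tuple[int, int]]
    behavior_weights: dict[tuple[int, int], float]
    clinical_table: pd.DataFrame


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    x = x - x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, keepdims=True)
    return x / np.where(sd > 0, sd, 1.0)


def _latent(rng: np.random.Generator, shape: tuple[int, ...], ar: float) -> np.ndarray:
    """i.i.d. standard normal courses, optional AR(1), standardized per course."""
    x = rng.standard_normal(shape)
    if ar:
        for t in range(1, shape[-1]):
            x[..., t] = ar * x[..., t - 1] + np.sqrt(1 - ar**2) * x[..., t]
    return _standardize_rows(x)


def _base_partition(rng: np.random.Generator, r: int, k: int) -> np.ndarray:
    labels = np.repeat(np.arange(k), int(np.ceil(r / k)))[:r]
    return rng.permutation(labels)


def _subject_partition(rng: np.random.Generator, base: np.ndarray, k: int, p: float) -> np.ndarray:
    labels = base.copy()
    flip = rng.random(base.size) < p
    for node in np.flatnonzero(flip):
        choices = np.delete(np.arange(k), base[node])
        labels[node] = rng.choice(choices)
    return labels


def generate_cohort(params: CohortParams) -> tuple[CohortTimeSeries, CohortTimeSeries, GroundTruth]:
    """Generate both groups plus ground truth; bit-identical for equal params."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    r, t, k = params.n_rois, params.n_timepoints, params.n_communities
    a = params.intra_community_corr

    # zero spatial mean: keeps the planted map identifiable against the
    # global across-ROI direction that any community signal shares exactly
    common_map = rng.standard_normal(r)
    common_map -= common_map.mean()
    common_map /= np.linalg.norm(common_map)
    if common_map[np.argmax(np.abs(common_map))] < 0:
        common_map = -common_map

    diff_set = frozenset(tuple(sorted(e)) for e in params.diff_edges)
    diff_membership = np.zeros(r)
    for i, j in diff_set:
        diff_membership[i] += 1
        diff_membership[j] += 1

    groups: dict[str, CohortTimeSeries] = {}
    base_partition: dict[str, np.ndarray] = {}
    subject_partitions: dict[str, np.ndarray] = {}
    clinical_rows = []

    shared_base = _base_partition(rng, r, k) if params.shared_base_partition else None
    for g_idx, (label, n_sub) in enumerate(zip(("A", "B"), params.n_subjects_per_group)):
        # groups share one base community layout by default so that, apart
        # from the planted diff edges, no edge differs in expectation;
        # shared_base_partition=False plants group-specific architectures
        base = shared_base if shared_base is not None else _base_partition(rng, r, k)
        base_partition[label] = base
        parts = np.empty((r, n_sub), dtype=int)
        subjects = []
        boosted = label == "B" and params.diff_effect > 0 and diff_set
        for s in range(n_sub):
            labels = _subject_partition(rng, base, k, params.node_reassign_prob)
            parts[:, s] = labels
            g = _latent(rng, (k, t), params.ar_coefficient)
            eps = _latent(rng, (r, t), params.ar_coefficient)
            x = np.sqrt(a) * g[labels] + np.sqrt(1 - a) * eps
            if boosted:
                # the pair latent replaces part of the endpoints' *private
                # noise*, leaving their community weights (and hence all
                # other edges) untouched
                d = params.diff_effect
                d_lat = {e: _latent(rng, (t,), params.ar_coefficient) for e in diff_set}
                for node in np.flatnonzero(diff_membership):
                    extra = sum(
                        d_lat[e] for e in diff_set if node in e
                    ) / np.sqrt(diff_membership[node])
                    x[node] = (
                        np.sqrt(a) * g[labels[node]]
                        + np.sqrt(1 - a - d) * eps[node]
                        + np.sqrt(d) * extra
                    )
            if params.common_strength > 0:
                h = _latent(rng, (t,), params.ar_coefficient)
                x = x + params.common_strength * common_map[:, None] * h
            sid = f"{label}{s:03d}"
            subjects.append(RoiTimeSeries(subject_id=sid, values=x))
            age = float(np.clip(rng.normal(28, 7), 21, 65))
            clinical_rows.append(
                {
                    "subject_id": sid,
                    "group": label,
                    "age": age,
                    "sex": int(rng.random() < 0.5),
                    "education": float(rng.normal(14.5, 2)),
                    "fd": float(abs(rng.normal(0.074, 0.04))),
                }
            )
        subject_partitions[label] = parts
        groups[label] = CohortTimeSeries(group_label=label, subjects=subjects)

    clinical = pd.DataFrame(clinical_rows)
    truth = GroundTruth(
        common_map=common_map,
        base_partition=base_partition,
        subject_partitions=subject_partitions,
        true_diff_edges=diff_set,
        behavior_weights={tuple(sorted(e)): float(w) for e, w in params.behavior_edges},
        clinical_table=clinical,
    )

    # Behavioral scores driven by planted edges of the Fisher-z connectome.
    fc_all = [
        vectorize_edges(fisher_z(pearson_fc(s.values, s.subject_id)))
        for grp in (groups["A"], groups["B"])
        for s in grp.subjects
    ]
    score_rng = np.random.default_rng(rng.integers(2**31))
    score = generate_behavior(fc_all, truth, params, rng=score_rng)
    clinical["score"] = score
    # Companion scales: correlated stand-ins so covariate models have inputs.
    z = (score - score.mean()) / (score.std() if score.std() > 0 else 1.0)
    clinical["hama"] = 0.6 * z + 0.8 * score_rng.standard_normal(len(score))
    clinical["hdrs"] = 0.5 * z + 0.9 * score_rng.standard_normal(len(score))
    truth.clinical_table = clinical

    return groups["A"], groups["B"], truth


def generate_behavior(
    fc_per_subject: list[EdgeVector],
    truth: GroundTruth,
    params: CohortParams,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Linear edge-driven scores: y_s = sum_e w_e z_e(s) + Normal(0, sd^2).

    ``fc_per_subject`` must hold Fisher-z edge vectors; weights come from
    ``truth.behavior_weights``. Deterministic given the generator state.
    """
    if params.behavior_noise_sd == 0 and not truth.behavior_weights:
        raise ValueError("no behavior_edges planted but a noiseless signal was requested")
    if rng is None:
        rng = np.random.default_rng(params.seed + 1)
    n = len(fc_per_subject)
    y = np.zeros(n)
    if truth.behavior_weights:
        r0 = fc_per_subject[0].n_rois
        pair_to_idx = {pair: idx for idx, pair in enumerate(fc_per_subject[0].index_map)}
        for pair, w in truth.behavior_weights.items():
            if pair not in pair_to_idx:
                raise ValueError(f"behavior edge {pair} not in edge index for R={r0}")
            idx = pair_to_idx[pair]
            y += w * np.array([v.values[idx] for v in fc_per_subject])
    if params.behavior_noise_sd > 0:
        y = y + params.behavior_noise_sd * rng.standard_normal(n)
    return y


def with_seed(params: CohortParams, seed: int) -> CohortParams:
    """Convenience copy with a new seed."""
    return replace(params, seed=seed)
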