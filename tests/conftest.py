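"""Shared fixtures: small synthetic cohorts reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from fcsubspace.connectivity import fisher_z, pearson_fc, vectorize_edges
from fcsubspace.synthetic import CohortParams, generate_cohort


@pytest.fixture(scope="session")
def planted_diff_cohort():
    """Two groups with five disjoint planted edges boosted in group B."""
    diff = ((0, 5), (2, 9), (4, 13), (7, 16), (11, 19))
    params = CohortParams(
        n_rois=24,
        n_timepoints=240,
        n_subjects_per_group=(20, 20),
        n_communities=4,
        common_strength=0.0,
        intra_community_corr=0.5,
        diff_edges=diff,
        diff_effect=0.4,
        seed=5,
    )
    cohort_a, cohort_b, truth = generate_cohort(params)
    return params, cohort_a, cohort_b, truth


@pytest.fixture(scope="session")
def common_component_cohort():
    """Cohort with a strong planted common spatial component."""
    params = CohortParams(
        n_rois=30,
        n_timepoints=120,
        n_subjects_per_group=(20, 20),
        n_communities=4,
        common_strength=2.0,
        seed=3,
    )
    cohort_a, cohort_b, truth = generate_cohort(params)
    return params, cohort_a, cohort_b, truth


def edges_of(cohort):
    """Fisher-z edge vectors for every subject of a cohort."""
    return [vectorize_edges(fisher_z(pearson_fc(s.values, s.subject_id))) for s in cohort.subjects]


@pytest.fixture(scope="session")
def planted_diff_edges(planted_diff_cohort):
    _, cohort_a, cohort_b, truth = planted_diff_cohort
    ea = edges_of(cohort_a)
    eb = edges_of(cohort_b)
    pair_to_idx = {pair: i for i, pair in enumerate(ea[0].index_map)}
    planted_idx = {pair_to_idx[e] for e in truth.true_diff_edges}
    return ea, eb, planted_idx
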