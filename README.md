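# fcsubspace

Individual-subspace functional connectivity analysis for two-group
resting-state fMRI studies, with a synthetic cohort generator for
validation.

## The problem

Case-control comparisons of functional connectivity (Pearson correlation
between parcellated ROI time courses) often find nothing after multiple
comparison correction, because a large fraction of each subject's signal
is shared across everyone in the group and drowns the individual
differences the comparison is after. This package implements an
individual-based pipeline built around that observation:

1. **Common component removal.** Stack each group's subject blocks
   (R x T ROI time-series matrices), extract the group-level common
   spatial component — the dominant eigenvector of the average projector
   `M = Σᵢ BᵢBᵢᵀ` over the subjects' rank-k left-singular subspaces — and
   project it out of every subject: `Y ← Y − MMᵀY`. The residual is the
   subject's *individual subspace*.
2. **Edgewise group statistics.** Fisher-z transformed edges compared with
   pooled-variance t tests, Benjamini–Hochberg FDR across the
   E = R(R−1)/2 edges, and a permutation *tmax* family-wise correction
   (null distribution of the maximum |t| over edges under label shuffles).
3. **Connectome-based prediction.** Elastic net
   `(1/2n)‖y − β₀ − Xβ‖² + λ[α‖β‖₁ + ((1−α)/2)‖β‖₂²]` in nested
   leave-one-out CV: nuisance regression of the clinical score on
   age/sex/education (train-fold coefficients applied to the test fold),
   top-50% feature selection by |r| with the residualized score,
   inner-LOO grid search over (α, λ). Evaluated by the leave-one-out
   bootstrap (out-of-bag scoring over B resampled training sets), by
   cross-group train/test designs, and by Jaccard overlap of the
   groups' selected-edge sets.
4. **Multi-subject community detection.** Each subject's FC matrix is one
   layer of a multilayer modularity
   `Q = Σₛ Σ_{i≠j} (Wˢᵢⱼ − γ)δ(gᵢₛ, gⱼₛ) + 2ω Σᵢ Σ_{s<r} δ(gᵢₛ, gᵢᵣ)`
   maximized by a generalized Louvain procedure; partitions are sampled
   over (γ, ω), and the working partition is selected by the
   mean-averaged-normalized-entropy (MANE ± 0.02) rule with minimum γ,
   maximum ω, and no single-node communities.
5. **Community-size association.** OLS of clinical scores on
   per-community node counts with covariates and BH-FDR across community
   predictors, plus the standard clinical group statistics
   (tie-corrected Mann–Whitney U with r = z/√N, 2x2 chi-square,
   Bonferroni, noncentral-F power).

Because raw patient scans are rarely shareable, the package ships a
first-class synthetic cohort generator (`fcsubspace.synthetic`) that
plants a common spatial component, subject-specific community structure,
group-different edges, and edge-driven behavioral scores — with ground
truth returned so every stage's recovery can be tested.

## Worked example

```python
import numpy as np
from fcsubspace import CohortParams, CommonBasisExtractor, generate_cohort
from fcsubspace.connectivity import (
    edgewise_group_test, fisher_z, pearson_fc, vectorize_edges)

params = CohortParams(
    n_rois=24, n_timepoints=240, n_subjects_per_group=(20, 20),
    n_communities=4, common_strength=3.0, intra_community_corr=0.5,
    diff_edges=((0, 5), (2, 9), (4, 13), (7, 16), (11, 19)),
    diff_effect=0.1, seed=12)
group_a, group_b, truth = generate_cohort(params)

def significant_edges(remove_common):
    arrays = {"A": [s.values for s in group_a.subjects],
              "B": [s.values for s in group_b.subjects]}
    if remove_common:
        for g in arrays:
            ext = CommonBasisExtractor(n_components=1).fit(arrays[g])
            arrays[g] = [ext.transform(v) for v in arrays[g]]
    edges = {g: [vectorize_edges(fisher_z(pearson_fc(v))) for v in arrays[g]]
             for g in arrays}
    return int(np.sum(edgewise_group_test(edges["A"], edges["B"]).q <= 0.05))

print("conventional space:", significant_edges(False))
print("individual subspace:", significant_edges(True))
```

prints

```
conventional space: 0
individual subspace: 3
```

— with a strong shared component and modest planted differences, the
conventional comparison finds nothing while the individual subspace
recovers three of the five planted edges. The contrast grows with the
number and size of planted differences.

A command-line interface mirrors the library
(`fcsubspace simulate|subspace|connectivity|community|run-all`); see
`fcsubspace --help`.

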