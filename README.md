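# brainmodes

Eigen-microstate analysis of spontaneous brain activity: extract the
*basic modes* that coexist across the instantaneous activity patterns of
a multivariate time series, decide how many of them lead, rebuild
functional connectivity from them, and quantify how individual-specific
and state-sensitive they are.

## Who this is for

Researchers working with parcellated resting-state fMRI (or any
node × time biological recording) who want a tested, reusable
implementation of the eigen-microstate pipeline: decomposition,
leading-mode selection, low-rank FC reconstruction, connectome
fingerprinting, cross-state comparison, and
spatial-autocorrelation-corrected map association — plus a synthetic
cohort generator with planted ground truth, so every stage can be
validated end to end without any restricted data.

## The model

Z-score each node's time course, concatenate sessions into an N × M
ensemble matrix, and divide by the root-sum-square of its elements (a
dataset constant S) so the total energy is 1. Each column A_t is a
*microstate* — the brain's activity pattern at one instant. The SVD

    A = U Σ Vᵀ,   E_i = A v_i = σ_i u_i,   w_i = E_iᵀE_i = σ_i²

yields the basic modes E_i (eigen-microstates) with weights w_i summing
to 1: orthogonal spatial patterns whose weighted combinations compose
every instantaneous state. A mode is **leading** if it (i) lies before
the scree elbow of the weight curve (Kneedle), (ii) has weight above
the mean 1/N, and (iii) beats a spatial permutation null in which node
labels are shuffled within every time column.

Because on z-scored data FC is `A_raw A_rawᵀ/(M−1)` (Pearson), the
decomposition implies an exact superposition of rank-1 coactivation
patterns:

    FC_ij = (S²/(M−1)) Σ_k E_ik E_jk

Truncating at the leading modes gives a low-rank FC reconstruction;
comparing per-subject reconstructed FC across runs gives identification
accuracy and differential identifiability
`I_diff = (I_self − I_others) × 100`.

## Worked example

```python
import numpy as np
from brainmodes import (
    CohortManifest, generate_basis, generate_cohort,
    zscore_time_courses, build_ensemble, decompose,
    select_leading_modes, compute_fc, reconstruct_fc, fc_similarity,
)
from brainmodes import fingerprint as fp
from brainmodes.decomposition import ActivityMatrix

# 20 subjects x 2 runs of 100-node series with 5 planted modes and
# subject-specific signatures
basis = generate_basis(n_nodes=100, k_modes=5, seed=1)
cohort = generate_cohort(basis, CohortManifest(n_subjects=20, n_runs=2, seed=2))

sessions = [cohort.sessions[k] for k in sorted(cohort.sessions)]
zscored = [zscore_time_courses(s) for s in sessions]
ensemble = build_ensemble(zscored)
modes = decompose(ensemble)
print(f"S = {ensemble.S:.2f}, rank = {modes.rank}, "
      f"top-5 weights = {np.round(modes.weights[:5], 3)}")

sel = select_leading_modes(modes, ensemble, n_perm=200, seed=3, sessions=sessions)
print(f"elbow at rank {sel.elbow_rank}, {sel.n_leading} leading modes "
      f"(total weight {modes.weights[:sel.n_leading].sum():.1%})")

concat = ActivityMatrix(values=np.hstack([z.values for z in zscored]),
                        node_ids=zscored[0].node_ids, zscored=True)
original = compute_fc(concat)
for k in (1, 5, modes.rank):
    print(f"FC reconstruction, k={k:3d}: "
          f"r = {fc_similarity(reconstruct_fc(modes, k), original):.4f}")

table = fp.similarity_matrix(
    [fp.session_fc(s) for s in cohort.runs(0)],
    [fp.session_fc(s) for s in cohort.runs(1)],
)
rep = fp.report(table)
print(f"identification accuracy = {rep.accuracy:.0%}, I_diff = {rep.I_diff:.1f}")
```

Output:

```
S = 1093.62, rank = 100, top-5 weights = [0.053 0.038 0.031 0.025 0.023]
elbow at rank 7, 6 leading modes (total weight 19.1%)
FC reconstruction, k=  1: r = 0.5948
FC reconstruction, k=  5: r = 0.8205
FC reconstruction, k=100: r = 1.0000
identification accuracy = 100%, I_diff = 92.6
```

Reading the numbers: the population ensemble concentrates ~19% of all
variance in six leading modes (the five planted patterns plus the
dimension opened up by between-subject basis variability); FC
reconstructed from those few modes already correlates strongly with the
full FC and at full rank the identity is exact; and subject signatures
make every one of the 20 individuals identifiable across runs, with
intra-subject similarity exceeding inter-subject similarity by 0.93.

`EigenMicrostates` and `LeadingModeSelector` in
`brainmodes.estimators` expose the decomposition and selection as
scikit-learn estimators (`fit`/`transform` on time × node arrays) that
compose with sklearn pipelines.

## Command line

```bash
brainmodes simulate --out cohort/ --n-nodes 100 --k-modes 5 --n-subjects 20 --seed 1
brainmodes select cohort/sub-*_run-1.tsv --out selection.tsv --n-perm 1000 --seed 1
brainmodes reconstruct-fc cohort/sub-*_run-1.tsv --k-sweep 10 --out fc_by_k.tsv
brainmodes fingerprint --run1 cohort/sub-000_run-1.tsv ... --run2 ... --out table.tsv
brainmodes compare-states --state-a ... --state-b ... --partition cohort/partition.tsv --out diff/
brainmodes map-assoc --mode-map m.tsv --target-map t.tsv --coords coords.tsv
brainmodes run --out full-pipeline/ --seed 1        # everything at once
```

Sessions are TSV (rows = nodes, header column = node ids); every
artifact is written with a JSON provenance sidecar.

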