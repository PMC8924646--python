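# gmnet

Single-subject grey-matter network analysis for prognosis in prodromal
Alzheimer's disease: from a tissue-probability volume to a covariance-style
brain network, its small-world summary metrics, prognostic cut-offs for
2-year progression to dementia, combined-biomarker classification, and
clinical-trial sample-size estimation.

## Who this is for

Researchers working with structural MRI in neurodegeneration who want a
tested, scriptable implementation of the individual (atlas-free) grey-matter
network approach and the survival-aware statistics around it — without
depending on MATLAB toolboxes — plus synthetic-data generators that make
every stage testable end to end with no patient data.

## What it computes

**Networks.** A grey-matter probability volume (2 mm isotropic working
grid) is tiled into 3×3×3-voxel cube nodes (6 mm edge). Every pair of cubes
is scored with the rotation-maximized Pearson correlation — the maximum over
22 discrete orientations in 45° steps about each axis, accommodating
cortical curvature — and the similarity matrix is binarized at a
subject-specific permutation threshold that keeps the expected fraction of
spurious connections among retained edges at or below 5%.

**Small-world metrics.** Mean clustering coefficient C and characteristic
path length L, normalized by their means over five degree-preserving
(Maslov–Sneppen) randomized reference networks:

    γ = C / C_rand,   λ = L / L_rand,   σ = γ / λ

σ near 1 indicates random-like topology; in prodromal disease these
measures drift toward randomness (lower γ, σ).

**Prognosis.** Time-dependent ROC curves (cumulative/dynamic,
nearest-neighbour estimator) for censored time-to-dementia data give each
marker (γ, λ, σ, CSF p-tau181, TIV-corrected hippocampal volume) an AUC for
progression by 2 years and a Youden-optimal cut-off; subjects are then
labelled marker-normal/abnormal and followed with Kaplan–Meier curves.

**Classification.** Logistic regression of abnormal markers against
progression (odds ratios with Wald 95% CIs, sensitivity/specificity/
accuracy, AIC model comparison), including the count-of-abnormal-biomarkers
model (small-world + p-tau + hippocampal volume vs the all-normal
reference), and random-slope mixed models for MMSE/CDR-SB decline.

**Trial sizing.** Per-arm sample size for a two-arm trial detecting a
fractional slowing Δ of cognitive decline,

    n/arm = ⌈ 2 (z₁₋α/₂ + z₁₋β)² (σ_b² + σ_e²/Σᵢ(tᵢ − t̄)²) / Δ² ⌉

with variance components from the mixed model, plus a Monte-Carlo
power/type-I oracle and subject-level bootstrap CIs.

## Worked example

The `gmnet` CLI wires the stages through files; every stage takes
`--config`, `--seed`, `--output-dir` and writes a run manifest. With a small
synthetic phantom (24³ voxels, 6 planted patterns of 12 cubes) and a
300-subject cohort:

```bash
cat > cfg.yaml <<EOF
volume: {shape: [24, 24, 24], n_patterns: 6, members_per_pattern: 12}
cohort: {n_subjects: 300}
EOF
gmnet simulate      --config cfg.yaml --seed 7 --output-dir demo
gmnet build-network --config cfg.yaml --seed 7 --output-dir demo
gmnet metrics       --config cfg.yaml --seed 7 --output-dir demo
gmnet cutoffs       --config cfg.yaml --seed 7 --output-dir demo
```

prints

```
INFO gmnet: network: 512 nodes, 340 edges, threshold r=0.7372, density 0.0026
INFO gmnet: gamma=7.682 lambda=0.510 sigma=15.063
INFO gmnet: gamma: cutoff=1.672 AUC=0.588
INFO gmnet: lambda_: cutoff=1.087 AUC=0.501
INFO gmnet: sigma: cutoff=1.456 AUC=0.580
INFO gmnet: ptau_pg_ml: cutoff=45.800 AUC=0.567
INFO gmnet: hv_norm_ml: cutoff=3.996 AUC=0.550
```

Reading the numbers: the permutation threshold (r ≥ 0.737) retains 340 of
~131k candidate edges — essentially the planted cube pairs; the phantom's
planted cliques make it far more clustered than its degree-matched random
references (γ ≫ 1), which is what the phantom is designed to show, not a
brain-like value. The prognostic cut-offs derived from the synthetic cohort
(e.g. γ ≤ 1.672 abnormal, AUC 0.59) land on the scale of published clinical
values because the cohort generator brackets those cut-offs by construction.
Marker AUCs near 0.5–0.6 reflect single markers being weak individual
predictors; combining them (the `classify` stage) is what raises accuracy.

Continuing with the trial-sizing stage,

```bash
gmnet samplesize --config cfg.yaml --seed 7 --output-dir demo
```

prints

```
INFO gmnet: all: n/arm=239 [181-307]
INFO gmnet: network_abnormal: n/arm=63 [51-83]
```

— per-arm sample sizes (with 95% bootstrap CIs) to detect a 25% slowing of
MMSE decline: restricting enrolment to subjects with abnormal network
topology, who decline faster, shrinks the required trial roughly four-fold
in this simulated cohort.

The same operations are available as a library
(`gmnet.network_construction`, `gmnet.graph_metrics`, `gmnet.prognosis`,
`gmnet.classification`, `gmnet.trial_design`, `gmnet.synthetic_data`,
`gmnet.volume_io`) — see `docs/methods.md` for the models and conventions.

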