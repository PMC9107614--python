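# Methods

This note documents the models, numerical choices and known limitations of
`eptkit`, in the order data flows through the pipeline.

## Synthetic BOLD model

Each subject's run follows the linear mixing model

```
X(v,t) = Σ_k m_k(v)·c_k(t) + trend(t) + motion-coupled signal + spikes + ε,
ε ~ N(0, σ²)
```

with `K ≥ 2` network maps `m_k` (sums of 3-D Gaussians, σ = 2 voxels by
default, max-normalised to 1, centres placed by greedy repulsion at ≥ 3σ
separation; an `overlap` fraction adds a bridging blob between adjacent
networks) and per-network courses `c_k` under one of two regimes:

- **continuous** — white noise band-limited to 0.01–0.15 Hz by the same
  fifth-order forward–backward Butterworth design the cleaning stage uses,
  standardised to zero mean and unit variance. Keeping the generator and
  the analysis filter identical guarantees the simulated spectra sit inside
  the analysis band.
- **event** — a Bernoulli spike train (default 2 events per 100 frames)
  convolved with a canonical double-gamma HRF (response peak 6 s,
  undershoot peak 16 s, undershoot ratio 1/6, kernel truncated at 1% of its
  maximum so the support is finite), rescaled to unit variance *without*
  demeaning. The course is therefore exactly zero outside the HRF support
  of its events — the defining property of the event hypothesis, and the
  property the regime-separation experiments rely on.

Defaults are a 20×20×10 grid, T = 200 frames, TR = 2 s — a typical
2-second-TR acquisition at toy spatial scale. **SNR** is defined at the
peak network voxel: `noise_sd = sqrt(peak signal variance / SNR)`; with
max-normalised maps and unit-variance courses, SNR 2 gives
`noise_sd = 1/√2 ≈ 0.707`. Artifacts: polynomial trends with per-voxel
random amplitude, six slow random-walk motion parameters coupled into a
random 20% of voxels, and rare spikes of 6 robust standard deviations
(median absolute deviation × 1.4826).

What the generator does **not** emulate: anatomical folding, spatially
correlated (smoothed) noise, physiological (cardiac/respiratory)
components, regional heterogeneity *within* a network — every network is
spatially rank-1. Passing tests therefore demonstrate algorithmic
correctness and the continuous/event contrast under idealised conditions,
not performance on real data. The rank-1 assumption matters most for the
event-absent-time-point analyses (below).

The cohort layer draws covariates (age U(18,65), sex, 3-level site, mean
framewise displacement U(0.05,0.25)), assigns case/control labels, and
generates a symptom score as a linear function of designated
functional-network-connectivity (FNC) pairs plus covariate effects plus
N(0,1) noise. Subject FNC targets (base U(0.15,0.45), across-subject sd
0.15 — a realistic between-subject spread for resting FNC) are realised
exactly by Cholesky-mixing the latent courses. A lightweight variant
(`make_symptom_cohort`) draws the FNC vectors directly, without imaging,
for validating the association stage at realistic cohort sizes; it can
also plant effects unique to one temporal portion (all/EPT/EAT) to test
that each portion carries recoverable, portion-specific information.

## Cleaning

Fixed order: cubic polynomial detrend → OLS regression on six motion
parameters and their first differences (first row of the derivative zero)
→ MAD despiking → band-pass.

- Despiking flags frame t when `|x(t) − median| > 2.5 × 1.4826 × MAD` and
  replaces flagged frames with an interpolating cubic spline through the
  clean frames (boundary spikes by extrapolation). Interpolation was chosen
  over a smoothing spline because it is parameter-free and never alters
  unflagged frames. More than 30% flagged frames is treated as a data
  quality failure, MAD = 0 as "flag nothing, warn".
- Band-pass: fifth-order Butterworth, 0.01–0.15 Hz, applied forward and
  backward (zero phase; effective order doubles). Runs shorter than the
  filter's padding requirement are rejected with the minimum length named.

## Nodes and time-point selection

Nodes are cubes/spheres in world mm (voxel-centre membership), the top-n
voxels of a statistic map (ties broken by flat voxel index, warned), or a
subject-specific network from reference-guided ICA. Node courses are
unweighted voxel means. EPTs/EATs are the n = 20 frames of largest /
smallest signed amplitude — 20 matching the conventional ICA model order —
with ties broken toward the earlier frame. An absolute-amplitude variant
and two literature detectors (threshold in SD units, local maxima) are
provided. A control removes strict local minima from an EAT selection.

## Group ICA

Variance normalisation (z-score per voxel course) → subject spatial PCA
keeping the smallest component count reaching 99% variance → group PCA of
the time-concatenated reductions to the model order, whitened so
`Y·Yᵀ/V = I` → Infomax. The Infomax unmixing is full-batch natural-gradient
ascent with the logistic nonlinearity, learning rate 0.5 annealed on
overshoot, convergence at weight-change norm < 1e-6 (max 512 epochs;
non-convergence is flagged, never silent). Component sign is fixed so each
spatial map has positive skewness.

Stability: Infomax is repeated (default 20 runs) from random orthogonal
initialisations, the pooled components are average-linkage clustered on
`1 − |spatial r|` into K clusters, and each cluster is scored
`Iq = mean within-cluster |r| − mean between-cluster |r|` and represented
by its centrotype. Components with `Iq > 0.8` are used for network
identification. At realistic model order (≈20) pure-noise inputs give
median Iq well below 0.5; in very low dimension (K ≤ 6) the finite-sample
optima are few and reproducible, so noise can look "stable" — stability
filtering is meaningful only at adequate order.

The default model order at toy scale is 8 (5 when the expected network
count is known, 20 for EAT-subset analyses, preserving the n = 20 ↔ model
order coupling).

## GIG-ICA (reference-guided subject estimates)

For each z-scored reference map: the subject's voxel-centred data are
reduced to a whitened spatial subspace (rank-limited, default ≤ 60 dims);
the unit vector is initialised from the projection of the reference and
iterated with the one-unit log-cosh fixed point under a closeness
constraint — whenever the estimate's spatial correlation with the
reference falls below ρ_min = 0.2 it is blended back toward the reference
direction. If the reference correlates with none of the subject PCA
component maps at |r| ≥ 0.2 the estimate falls back to plain dual
regression and is flagged. Back-reconstruction is joint: courses come from
regressing the data on all internal maps at once, final maps from
regressing the raw data on all courses at once (removing cross-network
contamination), denoised by projection onto the subject PCA subspace.
Working on voxel-*centred* rather than voxel-*standardised* data avoids a
flattening bias: at high local SNR, per-voxel standardisation equalises
all in-network voxels and destroys the map's shape (and makes noiseless
single-source data degenerate).

## Recursive ICA

Group ICA on the current data; stop with success when any component
matches the reference at |r| ≥ 0.5 (configurable); otherwise regress the
stable non-target components (Iq > 0.8 *and* reference match below
threshold — a candidate target is never removed) out of every subject and
repeat, up to 3 iterations. Residual Frobenius norm decreases strictly
whenever components are removed. The module exists for the case where 20
event-absent frames are dominated by other sources: a single pass at low
model order captures only the dominant components, the second pass finds
the target in the residual.

## Event-absent time points: what is detectable

With rank-1 networks, the information a network leaves in its own EATs
decomposes into (a) a conditional *mean* pattern — the 20 lowest-amplitude
frames of a continuous course sit near −1.8 sd, so the map appears with a
nearly constant negative loading — and (b) conditional *variance* — the
spread of those tail amplitudes (≈0.35 sd). Per-voxel standardisation of
the 20-frame subset (the group-ICA convention, kept here) removes (a), so
EAT recovery rests on (b). This is the honest discriminator: an
event-driven course is exactly zero at well-selected EATs and leaves
neither mean nor variance, whereas mean-based analyses are confounded by
the negative imprint that any demeaning/filtering stamps onto event-regime
baselines. Consequences, measured at the study conditions (10 subjects,
SNR 2):

- EAT-subset ICA recovers a continuous-regime network at matched |r|
  ≈ 0.45–0.62 per network (mean ≈ 0.5 across the five replicate networks)
  and an event-regime network at ≈ 0.1–0.23 (mean ≈ 0.16). Per-network
  values at this scale carry component-matching noise of roughly ±0.07, so
  regime separation is summarised across networks.
- Selection accuracy matters asymmetrically: a noisy single-voxel seed
  mis-selects EATs (admitting event frames and inflating apparent
  event-regime recovery), so the regime experiments use the accurate
  top-27 stat-map node.
- EAT seed-connectivity maps inherit a self-seed artifact: the node's own
  voxels correlate with the node course by construction, which alone
  produces a spatial correlation ≈ 0.3–0.4 with the true map even when the
  network is absent. FC-map evidence of presence is therefore only read
  from the continuous regime, where it reaches ≈ 0.56–0.69.

## Association stage

FNC vectors are Pearson correlations over the frame selection, NaN-flagged
for degenerate courses; Fisher-z transformation is available but off by
default. Covariate residualisation uses OLS on intercept + age + sex +
mFD + one-hot site (first level dropped); correlation of residuals equals
the partial correlation (tested against an independent implementation).

LASSO selection repeats 10-fold cross-validation over 50 Monte-Carlo fold
draws. Within each repetition the penalty is chosen from the CV curve at
the minimum mean MSE, **with ties resolved at the resolution of the CV
estimate itself**: all lambdas whose mean CV MSE lies within one standard
error of the minimum are considered tied and the heaviest such penalty
wins (`se_tolerance=1.0`; set 0 for the literal minimum). The literal
minimum sits in a valley that is flat relative to the CV standard error
and admits every predictor carrying a fixed-dataset chance correlation —
measured: each truly-null FNC pair selected in 52–100% of repetitions,
versus 0% under the default, with planted pairs selected in 100% of
repetitions either way and the all-zero model returned on null cohorts.
Per repetition the model is refit on all data at the chosen lambda; the
final reported set refits at the repetition-median lambda, and an all-zero
final model is reported explicitly. Predictors are not standardised (FNC
pairs share a scale).

Group discrimination fits a logistic model on residualised features with
Wald p-values and Benjamini–Hochberg correction; perfect separation
triggers a lightly ridge-penalised Newton refit (ε = 1e-3), flagged in the
output. Voxel-wise group comparison is a per-voxel OLS contrast with the
same confounds and BH-FDR across voxels.

## Per-frame contribution curves

The contribution of a network at frame t is the OLS coefficient of its map
in `X(·,t) ~ intercept + map`. Ranked (sorted) curves distinguish the
regimes: continuous engagement gives a smooth curve — on curves averaged
across 50 subjects, the largest inter-rank gap within the central 80% of
ranks stays below 3× the median gap (the tails of any finite Gaussian
sample necessarily contain larger gaps, which is why the comparison is
made on the central ranks of the subject-averaged curve) — while
event-driven engagement produces a near-zero plateau covering the
off-support fraction of frames (plateau defined as |contribution| below
10% of the maximum).

## Pipeline and reproducibility

The orchestrator runs the three-arm design (all frames / EPTs / EATs):
cleaning, group ICA for reference networks, GIG-ICA per subject for the
target course, per-arm selection, maps, subset group ICA (recursive ICA on
the EAT arm), FNC and association (skipped with a note when fewer than 50
scored subjects survive). All randomness derives from one master seed
expanded per stage; the manifest records the configuration hash, seeds,
per-subject frame selections and all numeric summaries, and a rerun with
identical inputs reproduces it bit-for-bit. Indices are 0-based; world
coordinates go through the NIfTI affine.

## Problem sizes

Validation runs use 10 subjects at 20×20×10 (T = 200) for recovery and
regime separation, 8 subjects at toy scale for the recursive fixture, 50
single-subject datasets at 15×15×8 for the adaptation experiment, n = 300
subjects for the association stage, and a 100-subject 12×12×6 cohort for
the end-to-end determinism check — sizes at which every experiment
completes in minutes on a single CPU while keeping the qualitative
contrasts (dominant vs weak sources, continuous vs event regimes) intact.

## Known limitations

- Rank-1 networks make EAT analyses conservative relative to real data,
  where within-network heterogeneity leaves additional recoverable
  structure at event-absent frames.
- The stability index is computed over random restarts only (no
  bootstrapping of voxels/frames).
- The GIG-ICA closeness constraint is a hard correlation floor with
  reference blending, not a tuned multi-objective weighting.
- The recursive-ICA stopping rule (reference match ≥ threshold) presumes a
  reference map is available.
- Homoscedastic noise means variance normalisation is nearly a no-op on
  synthetic voxels; its failure modes on heteroscedastic real data are not
  exercised.
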