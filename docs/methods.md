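# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of the `hubdisrupt` pipeline and of its synthetic
validation cohort. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Preprocessing model

The cleaning chain operates on voxel × time matrices and follows a fixed,
logged order: discard the first 4 volumes → grand-mean intensity scaling
(global mean 10,000; the conventional choice — nothing downstream of a
correlation depends on it) → high-pass 0.008 Hz → nuisance regression →
spike detection → band-pass 0.008–0.1 Hz on a uniform grid → deletion of
censored volumes.

* **Framewise displacement** is the sum of absolute backward differences of
  the three translations (mm) plus 50 × those of the three rotations
  (radians); 50 mm is the standard head-radius conversion. FD and DVARS are
  set to 0 at the first volume (backward differences are undefined there),
  so the first volume can never trigger motion censoring by itself.
* **DVARS** is the RMS over gray-matter voxels of the backward temporal
  difference; **SD** is the per-volume intensity standard deviation over
  the same mask. Both are z-normalized using moments computed over volumes
  2..T (volume 1 is a convention-filled placeholder); a series that is
  constant up to floating-point rounding yields all-zero z-scores and a
  warning rather than dividing by ~0.
* **Censoring**: a volume is flagged when FD > 0.5 mm or z-DVARS > 2.3 or
  z-SD > 2.3 (strict inequalities), and each flagged volume i expands to
  {i−2..i+2}, clipped at the series boundary. Spike measures are computed
  on the data entering the censoring step, i.e. after nuisance regression
  — the natural reading when the pipeline stages are applied in order; the
  choice is logged here because either convention is defensible.
* **Filtering vs. scrubbing order**: the band-pass is specified to act on
  scrubbed series, but deleting volumes breaks uniform sampling and with it
  the frequency interpretation of a Butterworth filter. Censored volumes
  are therefore bridged by per-voxel linear interpolation, the zero-phase
  (forward–backward, hence effectively 8th-order) band-pass is applied on
  the uniform grid, and the censored volumes are deleted afterwards.
* **Nuisance set**: exactly the six motion parameters plus mean CSF, mean
  WM and the global signal — no derivatives or quadratic expansions. OLS
  through a pseudo-inverse, so collinear regressors degrade gracefully
  (with a warning). When no CSF/WM masks exist (the synthetic cohort has
  no ventricles), those regressors are zero columns.
* **Quality control**: fewer than 120 retained volumes (5 min at TR 2.5 s)
  excludes the subject.
* **Grid downsampling** (for inputs on finer grids) is block-mean
  aggregation over factor³ neighborhoods; coordinates become block indices
  and the voxel size scales by the factor.

## Networks and nodal metrics

Pairwise Pearson correlations are Fisher-z transformed with |r| capped at
1 − 1e−7 (duplicated time series stay finite); zero-variance voxels get all
entries −∞ and can never be selected. Thresholding retains the
L = round-half-up(d·V(V−1)/2) strongest links by **signed** z — at the
1–10% densities used here this selects positive correlations, the common
binary-FC convention; an absolute-value mode exists behind a flag. Ties
break by ascending (i, j) order, which makes edge sets exactly nested
across densities and identical across platforms.

Degree maps exclude links whose center-to-center Euclidean distance is
≤ 2 grid units (12 mm on the 6 mm analysis grid) — the most literal reading
of excluding links "within two adjacent voxels"; a Chebyshev mode is
available since the exact geometry is not standardized. Excluded links
remain in the network object; only the counting ignores them. ROI-seeded
maps count surviving links between each voxel and the ROI voxel set
(link-count reading; the seed-mean-time-series alternative answers a
different question and is intentionally not the default).

The five nodal metrics use these conventions: betweenness is unnormalized
Brandes counting (each unordered pair once) — normalization would only
rescale disruption slopes; nodal efficiency is the global-integration form
E_i = mean_j 1/d_ij with unreachable pairs contributing 0; the
participation coefficient requires a module partition, which binary-graph
toolboxes leave to the user — the default is a deterministic greedy
modularity partition computed per network (igraph fast-greedy), and a
fixed partition (e.g. from the control-mean network) can be supplied
instead to remove subject-level partition noise.

## The hub-disruption index

K_D is the OLS slope, **with intercept**, of (individual − reference) on
the reference profile; omitting the intercept would bias slopes toward −1
for mean-shifted profiles. It equals cov(ind − ref, ref)/var(ref), is
invariant to adding a constant to the individual profile, and is unchanged
by common rescaling of both profiles. Controls are scored against the
leave-one-out reference: self-inclusion shrinks control slopes toward 0 by
construction and would inflate group contrasts (the full-mean mode exists
behind a flag). Voxels with zero reference value are retained — they carry
information near the origin — with a configurable exclusion. A reference
profile that is constant (e.g. all-zero clustering at a very sparse
density) carries no topology; the profile table records K_D = 0 there with
a warning.

## Inference

* **Group test on K_D profiles**: the between-subject effect of the
  classical split-plot (repeated-measures) model is exactly a one-way
  ANCOVA on each subject's density-mean score, so the test regresses
  mean-over-densities K_D on [group, age, gender] and reports the group F
  with (1, N−4) df. This needs no sphericity assumption because only the
  between-subject stratum is tested; the within-subject density factor is
  retained in the output table but is not an endpoint.
* **Covariate-adjusted Spearman**: rank-transform both variables,
  residualize on [1, covariates], correlate the residuals; p from the t
  approximation on n−2−k df. With no covariates this is exactly the plain
  Spearman coefficient (midrank ties).
* **Voxel-wise permutation GLM**: Freedman–Lane — residualize the maps on
  the nuisance partition (intercept + covariates), permute residual rows,
  add the nuisance fit back, recompute the full-model t map. TFCE with
  E = 0.5, H = 2, dh = max(stat)/100 per map, 26-connectivity (the cited
  permutation tool's defaults; all configurable), and the familywise-
  corrected p of voxel v is (1 + #{permutation max ≥ observed})/(n_perm+1)
  — the add-one convention guarantees validity and p > 0. Each one-sided
  contrast direction is its own family at its nominal level, matching
  standard practice of testing two one-sided contrasts. When fewer
  distinct relabelings exist than permutations requested, the scheme
  enumerates exhaustively and says so.
* **TFCE implementation**: the discrete sum Σ_h e(h,v)^E h^H dh is
  evaluated by an incremental union-find sweep over decreasing thresholds
  (numba-compiled), numerically identical to explicit per-threshold
  connected-component labeling (the test suite verifies equality to 1e−9
  against a scipy.ndimage oracle) but ~100× faster, which is what makes
  500-permutation × 200-replicate calibration runs cheap.
* **Summary-table tests**: Welch t with Satterthwaite df (reproduces the
  published age comparison), Pearson chi-squared without continuity
  correction (reproduces the published 2×2 comparisons), Bonferroni
  threshold α/m (the threshold reading of a corrected significance level;
  the adjusted-p reading is the same decision rule).

## The synthetic cohort

The generator's purpose is planted, recoverable ground truth for every
pipeline stage, at desk scale.

**Reference topology.** Nodes are partitioned into cliques ("functional
modules") whose heavy-tailed sizes come from a Pareto draw bisected so that
~95–98% of the edge budget L = round(d·V(V−1)/2) is intra-module; the
remainder is a node-disjoint matching of inter-module bridges, and the
total edge count is exact. Hubs are members of large modules. Two reasons
for this design over a preferential-attachment graph: functional brain
networks are strongly modular, with hubs embedded in correlated
communities; and the covariance construction Σ = load·I + w·A is positive
definite only for w < load/|λ_min(A)|. Clique-plus-matching structure
bounds λ_min ≥ −2 (eigenvalue subadditivity of the two overlays), so
realistic edge correlations (w = 0.9·load/|λ_min| ≈ 0.45) are feasible,
whereas tree-like hub topologies force λ_min ≈ −√k_max and cap edge
correlations near 0.1 — too weak for any finite-scan pipeline to recover.

**Patient disruption.** A patient with slope κ gets a network whose degree
profile is the tilted reference mean + (1+κ)(ref − mean): nodes are
re-partitioned into cliques sized by their tilted target degrees (clique
membership of size c gives degree c−1), plus the same sparse bridge
matching. The construction plants the slope essentially exactly (the
recovered-vs-planted correlation and bias are recomputed by the acceptance
script). The κ distribution is N(−0.3, 0.25) clipped to (−0.8, 0.3):
only the direction of the group effect is published for the motivating
design, but the strong published brain–behavior association implies large
between-patient heterogeneity, which the wide spread emulates.

**BOLD signal.** Volumes are i.i.d. Gaussian draws with the subject's
spatial covariance (temporal autocorrelation is available behind an AR(1)
flag but off by default — the correlation/thresholding logic under test
does not depend on hemodynamics). On top of the network signal every
subject receives a shared global fluctuation (sd 2 in voxel-sd units).
This is not a physiological noise model (still out of scope); it is the
single global confound that gives the global-signal-regression step its
purpose. It also matters structurally: without any shared component, each
voxel's covariance with the global mean is proportional to its degree, and
GSR then removes precisely the hub gradient the study measures. With a
dominant shared component, GSR removes the confound and leaves the network
structure (this mirrors real data, where the global signal is dominated by
non-neural fluctuations).

**Motion and censoring truth.** Baseline jitter is a random walk rescaled
to keep FD < 0.5 mm everywhere; planted spikes are persistent translation
steps, so FD exceeds the threshold exactly at the spike volumes and the
implied censor set is the ±2-expanded union. A quarter of subjects get two
spikes at random volumes.

**Behavior.** The designated ROI is the top-degree hub set (6 voxels).
Patients' baseline motor scores are a logistic squashing into [0, 66] of a
latent decreasing in the planted ROI degree (coupling 1.2 latent units per
SD of ROI degree, noise sd 0.35); the recovery ratio increases with ROI
degree (slope 0.3 per SD, noise sd 0.12, offset 0.45 so most patients
improve); follow-up = baseline·(1+ratio) clipped to the scale. Signs
emulate the published pattern: worse baseline function but better recovery
for patients with higher hub-region connectivity.

**Scale and determinism.** Defaults: 32 controls / 28 patients (the
published right-sided arm), V = 150 gray-matter voxels on a 6 mm grid
(desk scale; the published analysis used ~tens of thousands), T = 230
volumes at TR = 2.5 s. One master seed fans out via
`numpy.random.SeedSequence` spawning in a fixed order (stream 0 topology
and spatial layout, stream 1 demographics, streams 2+i subject i, final
stream behavioral noise); every generator is a pure function of
(config, seed). Voxel coordinates are a random permutation of a compact
grid so that hubs are spatially scattered, as in real cortex, rather than
index-adjacent.

**What passing tests do and do not show.** The generator produces Gaussian,
temporally white signals with uniform edge weights, block-modular truth,
exact group-shared topology, and no registration error, lesion geometry,
physiological noise, or hemodynamic response. Passing the suite therefore
validates the *computational* chain — censoring arithmetic, filter
response, thresholding, metric formulas, slope estimation, calibration and
FWE control of the permutation engine — under known truth; it does not
certify effect sizes or anatomical conclusions on real data, and the
published cohort's F statistics, correlation magnitudes and cluster
anatomy are explicitly not reproduction targets (the raw data are not
available).

## Problem sizes used by tests and the acceptance script

Simulation sizes were chosen as the smallest that make the planted effects
and calibration bands statistically crisp: slope recovery uses 200
subjects on a 150-voxel profile; FWE calibration uses 200 null replicates
of 500 permutations on a 5×5×5 grid with 20 subjects; the ANCOVA type-I
check uses 1000 replicates of 30+30 subjects; end-to-end sign recovery
uses 20 (tests) or 10 (acceptance script) seeded cohorts at the default
cohort scale; the full pipeline report runs the complete default cohort
once. The default `RunConfig.n_perm` is 500 for the desk-scale synthetic
run; 5,000 is the convention for a full-scale voxel-wise comparison and is
the default of the `permutation_fwe` function itself.

## Known limitations

* The repeated-measures decomposition reports only the between-subject
  group effect; within-subject (density × group) effects are out of scope.
* The degrees of freedom of the published group tests suggest an error
  structure the source does not describe; the df convention here,
  (1, N−4), is documented rather than matched.
* The partition source for the participation coefficient is not
  standardized; both per-subject and fixed-partition modes are exposed
  rather than silently choosing one.
* Edge ranking uses signed z; at much higher densities than 10% the
  absolute-value mode may be preferable.
* `rm_ancova_group` treats gender as a binary covariate and age as linear;
  no interaction terms.
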