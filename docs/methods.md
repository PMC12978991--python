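# Methods

## The mapping procedure

The package derives, per direction of reported change, a consensus
network from per-contrast peak coordinates and a resting-state cohort.
The chain is: sphere seeds per contrast → per-subject seed-to-voxel
Pearson correlation with Fisher z → voxel-wise one-sample t over
subjects (one-sided, right tail) → voxel-level multiple-comparison
correction → binarization with the t > 0 conjunction → overlay into a
contrast-fraction probability map → 50 % consensus threshold. The
assumptions are those of the method itself: all volumes share one grid
and affine; subjects are exchangeable (plain one-sample t, no
covariates); only positive connectivity is biologically interpreted, so
the right tail carries the inference; each contrast is one independent
vote in the consensus regardless of its number of peaks.

## Parameters

| parameter | default | meaning and rationale |
|---|---|---|
| `radius_mm` | 4 (alternates 1, 7) | seed sphere radius in mm around each reported peak; 4 mm is the conventional size for coordinate seeds on a 3 mm grid, and the two alternates are used to show results do not hinge on it |
| `correction` | `FDR_BH` | voxel-level Benjamini–Hochberg; `FWE_bonferroni` for large cohorts where the stricter bound still has power |
| `alpha` | 0.05 | level of the voxel-wise correction |
| `consensus_fraction` | 0.5 | a voxel enters the network when at least half the contrasts include it; inclusive at the boundary (see tie rule) |
| `bandpass_hz` | (0.01, 0.1) | resting-state fluctuation band |
| `fd_spike_mm` | 0.5 | framewise-displacement threshold (strictly greater) above which a volume gets its own spike regressor |
| `fwhm_mm` | 6 | Gaussian smoothing kernel; set to 0 in the synthetic experiments (below) |
| `discard_volumes` | 10 | dummy scans dropped at load for signal equilibrium |
| `trans_limit_mm`, `rot_limit_deg` | 2, 2 | subject-level motion exclusion; compared against max absolute translation / rotation (rotations stored in radians, converted explicitly) |
| `n_null` | 1000 | random-seed null networks for the chance baseline |

## Geometry and numerical choices

- Sphere membership is a closed ball on voxel-center distances computed
  in mm after mapping through the grid affine — no prior rounding to the
  nearest voxel — so anisotropic grids are exact and the ≤-vs-<
  boundary rule is explicit (it changes voxel counts at exact-boundary
  radii: r = 4 mm on a 3 mm grid gives 7 voxels, r = 1 mm gives 1).
- Spheres are clipped to the brain mask; a focus whose whole sphere
  falls outside contributes nothing and is logged; an entirely empty
  contrast seed is a hard error naming the contrast.
- Correlations are clipped to |r| ≤ 1 − 1e-7 before atanh so
  seed-internal voxels stay finite; seed voxels are *not* excluded from
  the map (downstream thresholding handles them).
- Zero variance is detected with a relative tolerance
  (‖x − x̄‖ > 1e-8·√T·(1+|x̄|)): a constant series leaves centering
  round-off that must not masquerade as variance. Such voxels are
  flagged invalid, excluded from the correction's m, never silently
  zeroed. A zero-variance seed series is a hard error.
- The band-pass is zero-phase frequency-domain masking with a
  0.005 Hz cosine-tapered transition: deterministic, idempotent on the
  passband to < 2 %, with the edge effects of periodic extension. DC is
  always removed when the low cutoff is positive. A cutoff above
  Nyquist is an error that reports the Nyquist for the given TR.
- Nuisance regression is ordinary least squares; residuals are
  orthogonal to the design to < 1e-6 relative. The rank check runs on
  unit-norm columns (squared radians are ~1e-12 the scale of mm
  columns; a scale-sensitive check false-flags them) and ignores
  all-zero columns, which occur legitimately when there are no spikes.
- The consensus threshold compares contrast *counts*
  (count ≥ fraction·N − 1e-9), keeping the 50 % boundary exact for even
  N; the tie rule is inclusive, so with N = 12 a voxel present in
  exactly 6 binarized maps is retained.
- Statistics accumulate in float64; volumes are float32 on disk. The
  fast engine (`ConnectomeEngine`) pre-centers and unit-normalizes every
  subject's in-mask series once so that a full network derivation is a
  few matrix products per subject; a test pins its output to the
  step-by-step module composition exactly.

## Order of operations

Preprocessing applies discard → motion exclusion → nuisance regression
(Friston-24, FD spikes, global/WM/CSF means, linear drift, intercept) →
band-pass → smoothing, and the connectivity stage runs on the result.
The regress-then-filter order and all settings are recorded in the
provenance sidecar. Registration, segmentation and slice timing are out
of scope: volumes are assumed aligned and motion traces are inputs.

## The synthetic cohort

Each subject's voxel v in planted network k follows
y_v(t) = β_k·s_k(t) + ε_v(t) with s_k i.i.d. standard normal shared
across the network within a subject (rank-1 block covariance, the
simplest structure satisfying the analysis's assumptions) and
ε ~ N(0, σ²) i.i.d.; background voxels are pure noise. Two same-network
voxels then have population correlation β²/(β²+σ²) — the calibration
the tests check (β = 1, σ = 1 gives r = 0.5). Latents are temporally
white by default since the pipeline's statistics are correlation-based
and do not model autocorrelation; an AR(1) option exists for the
latents. The default desk-scale grid is 20×24×20 voxels at 3 mm
(pseudo-MNI affine, origin at the grid center) with T = 175, the
volume count that remains after discarding 10 dummies from a 185-volume
acquisition; experiment cohorts are generated at T = 185 and the
pipeline discards 10.

Motion traces are per-axis Gaussian-smoothed white noise (σ = 8 TRs,
0.05 mm translations, 0.001 rad rotations) plus 2 % frame-to-frame
measurement jitter, with optional persistent step displacements so each
spike produces exactly one FD excursion of the configured size. The
jitter matters: perfectly smooth drift makes the Friston-24 expansion
numerically rank-deficient at short T, which real realignment estimates
never are. Two pure-noise tissue boxes stand in for white matter and
CSF so the nuisance design has its full column budget.

What the generator does *not* emulate: hemodynamic response and scanner
noise spectra, spatial autocorrelation of noise, anatomical geometry,
inter-subject spatial variability, and distance-dependent connectivity.
Passing tests therefore show that the mapping machinery is correct and
calibrated under its own statistical model — not that any particular
real-data result is right.

## Synthetic experiments and the smoothing choice

The recovery, null-network, type-I and radius experiments run with
`fwhm_mm = 0`. Planted voxels are spatially independent, so smoothing
can only blur the planted partition's boundary: a 6 mm kernel on 3 mm
voxels leaks ~20–30 % of the boundary signal into the adjacent
background shell, and the experiment would measure the kernel rather
than the mapping. On real data, smoothing compensates residual
registration error and is the default. This choice was fixed from the
generative model before the experiments were run.

Null contrasts (both the chance baseline and the type-I consensus
check) sample foci uniformly from brain-mask voxel centers with the same
per-contrast focus counts as the real contrasts — count-matching is an
assumption, flagged as such, since nothing pins down the sampling domain
of a chance seed. A hook on the permutation test accepts externally
generated null networks (e.g. from a surface-based spin test) in place
of the volumetric random-relocation null.

One behavior worth knowing: in synthetic cohorts the random-seed null
networks at a 50 % consensus over many contrasts are almost always
*empty* (random seeds share no voxels), which is exactly why the null
Dice baseline is near zero. The permutation test treats an all-empty
null as degenerate and raises; the pipeline driver catches this per
label and reports the permutation p as missing. The permutation-p
calibration therefore runs a two-contrast configuration, where the ≥50 %
rule keeps each contrast's own seed voxels and the null is non-trivial.

## Design decisions that were genuinely open

- **Talairach→MNI**: the Lancaster icbm2tal affine (inverted), not the
  Brett piecewise transform — a single invertible affine, widely
  adopted; the matrix lives in one place so an alternative can be
  swapped in. Nothing in the input convention forces either.
- **Voxel-level FWE = Bonferroni**, not random-field theory: RFT needs
  smoothness estimation machinery that buys little at voxel-level
  inference, and Bonferroni's conservatism is the transparent choice.
- **One-sided p**: with the t > 0 conjunction a two-sided variant
  differs only by the α split; the one-sided tail matches the
  positive-connectivity restriction. Config-exposed by swapping the
  correction's input.
- **Unweighted seed mean**, not the first eigenvariate: matches the
  common implementation of sphere-seed connectivity.
- **Duplicate foci** within a contrast collapse (sphere union is
  idempotent anyway); duplicates across contrasts are kept — each
  contrast votes once.
- **Dice** is 2|A∩B|/(|A|+|B|); permutation p uses the add-one
  estimator (1 + #{null ≥ obs})/(1 + n_perm), never exactly 0.

## Limitations

- The permutation null relocates foci uniformly in the volume; it is
  not a surface-based spin test and does not preserve spatial
  autocorrelation of the cortical sheet (use the null-network hook to
  supply such nulls).
- Bonferroni FWE is conservative relative to RFT-based FWE at matched α.
- The synthetic model's independence assumptions make some real-data
  failure modes (smoothness-inflated cluster sizes, global artifacts
  correlated with seeds) invisible to the test suite.
- Desk-scale problem sizes (30 subjects, ~10⁴ voxels, 100–1000 null
  replicates in the experiments) were chosen so the full study re-runs
  in minutes; all statistics are formulated identically at any scale.
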