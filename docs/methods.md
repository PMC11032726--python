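# Methods

## Trajectory model

A trajectory is a sequence of positions `x_i ∈ R^d` (d = 1, 2, 3) at
strictly increasing times `t_i`, `N ≥ 2`. Geometric descriptors
(straightness, efficiency, gyration shape, Katz dimension) accept any
time grid; lag-based descriptors (MSD by lag, VACF, Green–Kubo,
discrete Fourier transform, gaussianity) require uniform spacing and
raise `SpacingError` otherwise (tolerance 1e-9 relative on Δt), because
time-origin averaging at a fixed lag is ill-defined on irregular grids.
Missing values are rejected, never imputed, and coordinates are taken
as plain Cartesian — no periodic-image unwrapping is attempted on MD
dumps.

## Descriptor conventions and numerical choices

* **Maximum lag.** All lag-based averages stop at `n_max = ⌊N/4⌋`:
  beyond a quarter of the record each lag is estimated from too few
  displacement pairs and the statistical noise dominates. The
  anomalous-exponent fit uses ordinary least squares on
  (log τ, log MSD) over lags `1…n_max`.
* **Trappedness constants.** `P = 1 − exp(0.2048 − 0.25117·D₀T/r₀²)`,
  clamped to [0, 1], uses the constants published with the original
  single-particle-tracking feature family; they come from a logistic
  calibration of confinement detection and are kept verbatim for
  comparability. `D₀` is a through-origin least-squares slope over the
  first two MSD points divided by `2d`; `T = (N−1)Δt`; `r₀` is half
  the maximum pairwise extent.
* **Maximum extent.** Computed exactly by pairwise distances up to
  N = 1500; for longer trajectories the convex hull reduces the
  candidate set first. If the hull is degenerate (collinear points)
  the extent along the leading principal axis is used, which is exact
  in that case.
* **Katz degeneracy.** When `e/L = 1/n` the Katz denominator vanishes;
  `+inf` is returned as an explicit sentinel and logged. The
  classifier and projection impute such non-finite entries to the
  column's maximum finite training value so the row stays usable
  without inventing small values.
* **Green–Kubo cutoff.** The diffusivity integrates the unnormalized
  VACF by trapezoid up to its first zero crossing (located by linear
  interpolation between lag samples), or to `n_max·Δt` if it never
  crosses. The VACF tail beyond the first crossing is noise for the
  motion classes handled here, and integrating it only inflates the
  variance of the estimate. For white-noise (Brownian) velocity series
  the interpolated half-trapezoid recovers `D` exactly in expectation:
  `(1/d)·½·C(0)·Δt = D`.
* **Gaussianity reference lag** is 1 — the best-sampled lag; the
  Gaussian moment identity `⟨r⁴⟩ = (1+2/d)⟨r²⟩²` makes the statistic 0
  for normal diffusion in any dimension.
* **Fourier.** Mean subtraction per coordinate, rectangular window, no
  zero padding; per-coordinate power spectra are summed and the
  zero-frequency bin excluded. A relative power threshold of 1e-12
  maps numerically constant trajectories to frequency 0.
* **MSD ratio default pair** is `(1, ⌊n_max/2⌋)`; any valid pair can
  be passed explicitly.
* **Eigensystem reproducibility.** Gyration eigenvalues are sorted
  descending and each eigenvector's first nonzero component is made
  positive, so shape features and the kurtosis projection are
  deterministic across BLAS implementations.
* **Feature order** is alphabetical; it is the CSV column contract.

The three summary entries `msd_slope_diffusivity`, `vacf_first_lag`
and `msd_at_quarter_lag` complete the 17-descriptor vocabulary with
the short-lag diffusivity, the first-lag velocity correlation and a
mid-curve MSD value — quantities practitioners routinely read off the
MSD/VACF curves; they are this package's choice of curve summaries.

## Simulation engines

All four engines start at the origin, carry one master seed per spec,
and derive one deterministic sub-stream per spatial coordinate
(`numpy.random.SeedSequence.spawn`), so identical specs give
byte-identical trajectories.

* **normal** — increments i.i.d. `N(0, 2DΔt)` per dimension; ensemble
  MSD `2dDt`.
* **anomalous** — fractional Brownian motion with Hurst `H = α/2`,
  sampled *exactly* per coordinate by Cholesky factorization of the
  covariance `Cov(B_s, B_t) = D(s^α + t^α − |t−s|^α)`; ensemble MSD
  `2dDt^α`, reducing to the normal engine's law at α = 1. The exact
  generator was chosen over spectral approximations because at desk
  scale (N ≤ ~5000) the O(N³) factorization is cheap and the target
  law holds exactly, which makes the exponent-recovery tests sharp.
  A failed factorization is retried once with a tiny diagonal jitter.
* **confined** — Brownian proposal steps inside a reflecting sphere of
  radius R; a step leaving the sphere is reflected radially across the
  boundary (repeatedly if needed). Reflection rather than rejection
  preserves the step-length statistics and cannot loop forever. Every
  output point satisfies |x| ≤ R, so the MSD plateaus near the
  confinement scale.
* **directed** — Brownian motion plus constant drift `vΔt` per step;
  ballistic (α → 2) when the Péclet number `|v|²T/(2dD)` is large.

Mode → label mapping: confined → `subdiffusion`, normal → `normal`,
directed → `superdiffusion`, fBm (α ≠ 1) → `anomalous`. Confinement
and drift are the standard generators of the sub- and super-diffusive
signatures; the `anomalous` label is reserved for genuinely correlated
increments.

### Default study conditions

`make_training_specs` draws, per trajectory, deterministically from the
master seed: diffusivity log-uniform in [0.1, 10] (two decades, so the
classifier cannot key on absolute scale alone); fBm exponent uniform on
[0.3, 0.7] ∪ [1.3, 1.7], excluding the neighborhood of α = 1 where the
anomalous class is indistinguishable from normal diffusion by
construction; confinement radius with `R²` at 1–5 % of the free-diffusion
range `2dDNΔt` (strong confinement); drift speed `0.5–2 × √D` in a random
direction (Péclet well above 1). Defaults are N = 250 points, Δt = 1,
d = 2, 100 trajectories per class — trajectory lengths and class sizes
typical of particle-tracking experiments and sufficient for the
separability the feature space provides.

What the generator does **not** emulate: localization noise, frame
drop-out, drift of the microscope stage, heterogeneous or switching
motion within one trajectory, and finite-exposure blur. Passing tests
therefore demonstrate correctness of the estimators and separability of
the idealized regimes, not robustness to experimental artifacts.

## Classification and projection

Features are z-scored on the training table and fed to a random-forest
ensemble (300 trees, seeded) — a tree ensemble is the standard choice
for this feature family and is insensitive to the skewed, heavy-tailed
feature distributions. Held-out accuracy is estimated by stratified
5-fold cross-validation (seeded, single repetition) before refitting on
the full table. The model artifact stores the format version, feature
vocabulary, class list and imputation values, and refuses tables whose
feature names differ.

The 2-D projection z-scores the features and takes the top two
principal components with a deterministic sign convention (the
largest-magnitude loading of each component is positive). The
"four well-separated clusters" claim is operationalized as k-means
(k = 4, 10 restarts) on the projection recovering the true labels with
adjusted Rand index above 0.3 — a conservative above-chance threshold,
since no published separation metric exists for this figure.

Group comparison uses a two-sided Mann–Whitney U test by default:
feature distributions are skewed and a rank test needs no normality
assumption.

## Problem sizes

The test suite and the acceptance script use: 4 × 100 trajectories of
N = 250 for the clustering/classification checks; 50 trajectories of
N = 1000 per regime for exponent recovery; one N = 10⁴ Brownian
trajectory for the diffusivity cross-check; 100 random trajectories of
N ≤ 50 against the O(N²) brute-force MSD oracle. These sizes put every
Monte-Carlo check comfortably inside its stated tolerance while keeping
the whole suite around a minute on one CPU.

## Known limitations

* The exact fBm generator is O(N³)/O(N²) in time/memory per
  trajectory; for N beyond ~5000 a circulant-embedding generator would
  be the right replacement.
* `alpha` from a single short trajectory is noisy (sd ≈ 0.1 at
  N = 1000 for Brownian input); ensemble averaging or longer records
  are needed for precise exponents.
* Features are computed per whole trajectory; motion-state switching
  within a trajectory is averaged over, not segmented.
* The LAMMPS-style YAML reader covers the minimal
  `timestep/keywords/data` schema with an `id` column and `x/y/z`
  coordinates; other dump dialects and wrapped-coordinate unwrapping
  are out of scope.
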