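# Methods

This note records the models implemented, the defaults chosen where the
procedure admits genuine freedom, what the synthetic generators do and do
not emulate, and the numerical choices that matter for reproducing results.

## AFM contact mechanics

Curves are assumed pre-calibrated (force in N against piezo position in m);
photodiode-volt conversion and spring-constant calibration are out of scope.
All internal units are SI; readers accept nm/µm and nN/pN column dialects.

**Contact models.** The sphere model is the DMT limit of adhesive contact:
the Hertz sphere response minus a constant adhesion term `2πγR`. The work
of adhesion γ is a fitted parameter constrained to γ ≥ 0 (initial value 0);
whether to fit or fix γ is exposed because analysis conventions differ
between labs. The cone model is Sneddon's solution, `P ∝ E tanθ δ²`, with
no adhesion term. Poisson's ratio defaults to 0.5 (incompressible soft
matter). Finite-thickness (bottom-effect) corrections and the JKR model are
deliberately not implemented; the thin-sample regime is instead excluded by
QC (below).

**Contact-point detection.** The first 30% of the approach is treated as
baseline; a straight line removes offset and tilt, and contact is the first
run of 10 consecutive samples deviating from the baseline by more than
3 baseline standard deviations (with a tiny absolute floor so noiseless
curves work), backtracked along a 7-sample moving average to where the
excursion leaves the baseline. Detection is two-sided: adhesive snap-in
produces a negative excursion at contact, and catching it there is more
accurate than waiting for the force to rise. During fitting the contact
point is additionally refined by a bounded 1-D search (±5% of the z range)
minimizing the force residual, with the model coefficients re-solved in
closed form at each trial position — both models are linear in their
coefficients once the indentation origin is fixed, so the inner solve is a
plain least squares.

**Fit window and QC.** The window runs from the contact point to the
transition point (first sample at the trigger force). Samples with δ < 0
(snap-in region) are dropped. R² is computed on force residuals over the
window. When sample thickness is known, fits with max indentation above 20%
of thickness are flagged and excluded from force-map summaries, reflecting
the depth-independence limit of E estimates on thin samples. Force-map
summaries report mean/median/SD of E over accepted cells and enumerate
rejected cells with reasons; maps carry an optional acquisition time for
time-resolved series.

## Nanoneedle penetration analysis

Penetration events are local maxima of the smoothed force (5-sample moving
average) followed by a decline of at least `min_drop` before the force
rises back above the peak level; `min_drop` defaults to 5% of the trigger
force (10 nN default, the setting that achieves membrane penetration).
A half-`min_drop` hysteresis on "rises back above" and a 0.2 µm merge
radius keep noise from splitting one penetration into several detections.
Curves are accepted only when the event count matches the site: two peaks
over the nucleus (cell then nuclear membrane), one for cytoplasm, junction,
and edge/mid sites. Penetration depths beyond 2.3 µm are flagged as
implausible for the needle geometry.

Compartment stiffness is fitted with the cone model on the segment after
the last accepted peak, from the local force minimum following the peak
(at least one smoothing window past it, so the rupture transient is
excluded) to the transition point, with free indentation and force offsets
(`P = P0 + C(δ − d0)²`) because the needle has already traversed overlying
material. Whether published analyses fit pre- or post-penetration segments
is generally not stated; the post-penetration choice is an assumption of
this package and is what the generator's ground truth encodes. Site-ratio
confidence intervals are percentile bootstrap over cells (1,000 resamples).

## Permissive-zone (PZHR) statistic

Sites are encoded center → 0, inner third → 0.33, inner two-thirds → 0.67,
periphery → 1.0. Ordinary least squares fits `E(x) = ax² + bx + c` to all
observations (≥3 distinct x required). `X_15kPa` is the smallest root of
`E(x) = 15` in [0, 1]; if E(0) ≥ 15 it is 0, and if the profile stays below
15 across the axis it is 1. The area statistic squares the one-dimensional
fraction, `A = X²`, preserving the square-wound geometric convention of the
original definition; a circular-wound variant (πX²/4-normalized) exists but
is off by default. The 5 kPa floor is checked — a warning plus a
band-restricted area are emitted if the fitted profile dips below it inside
the zone — but never truncates the headline statistic. Default analysis
fits per animal and summarizes across animals; a pooled fit is available
because the original pooling convention is ambiguous.

## Traction force microscopy

**Green's tensor.** Infinite elastic half-space (Boussinesq) with traction
applied at the surface; in Fourier space

    G(k) = 2(1+ν)/(E k³) · [ (1−ν)k² + ν k_y²,  −ν k_x k_y ;
                             −ν k_x k_y,        (1−ν)k² + ν k_x² ]

No finite-gel-thickness correction is applied. The zero mode is undefined
(rigid translation) and set to zero on both forward and inverse paths,
which also enforces force balance of recovered tractions.

**Inversion.** G is symmetric positive definite for k ≠ 0, so both modes
go through its eigendecomposition: direct inversion applies 1/s per
eigenvalue (colony mode), Tikhonov applies `s/(s² + λ_abs²)` (single-cell
mode). λ is dimensionless: `λ_abs = λ · s_max` with `s_max` the largest
singular value of G on the grid, so a given λ has the same meaning across
grid sizes, spacings and substrate stiffnesses. A bare literature value of
λ is not transferable to this normalization; the default 1e-7 is a very
light filter whose noiseless solution is numerically indistinguishable from
the direct inverse. Real (non-periodic) fields should be inverted with
`taper=True` (mean subtraction + Hann window); oracle tests on periodic
synthetic fields use raw mode.

**PIV.** Multipass FFT cross-correlation at 64/32/16 px windows with 50%
overlap. Interrogation windows are mean-subtracted and Hann-weighted:
without the taper, bead images truncated at window edges bias the
correlation peak toward zero displacement by 10–20% of the shift. Each
pass pre-shifts the deformed window by the bilinearly interpolated, rounded
predictor from the previous pass, so only a sub-pixel residual must be
measured where the bias is negligible. Subpixel peaks use a 3-point
log-Gaussian fit after removing the correlation's median background
(falling back to a parabolic fit if a point is non-positive). Vectors whose
primary-to-secondary correlation peak ratio falls below 1.2 are replaced by
the 3×3 local median. Repeated final windows (e.g. 64/32/16/16) are
accepted as refinement iterations. Drift correction estimates a global
subpixel shift per frame against the first frame (upsampled cross-
correlation) and flags frames whose aligned correlation with the reference
is below 0.2.

**Strain energy.** `U = ½ Σ (T·u) · Δx²` with the per-node density map
returned. U is guaranteed nonnegative only for self-consistent (T, u)
pairs; measured pairs can carry noise of either sign.

## STORM chromatin analysis

Analysis starts at localization tables (x/y in nm per nucleus); raw-frame
fitting, drift correction of localizations and photophysics are out of
scope. Voronoi polygon areas are computed per localization; cells of
convex-hull points are unbounded and excluded from all threshold
statistics. Duplicate localizations are merged with a warning.

**Threshold calibration.** The polygon-area threshold is chosen by
bisection so that the mean over control nuclei of the fraction of interior
localizations with area below threshold equals the target (0.5) within
1e-3. The mean is across nuclei by default (each nucleus weighted equally);
a pooled-localizations mode exists because the original averaging
convention is ambiguous. The threshold is then reused unchanged for
treatment groups — only the control group ever sets it.

**Nanodomains.** DBSCAN on the heterochromatic fraction with
`eps = 5 × median nearest-neighbor distance` and `min_samples = 5`. The
factor self-scales to localization density; it must exceed the percolation
scale of a uniform-density domain (a factor of 3 fragments a 500-point
planted domain into several clusters). An exact Voronoi-adjacency
connected-components mode (Delaunay edges shorter than eps) is provided as
a cross-check and agrees with DBSCAN on well-separated synthetic domains.
Domain area is the convex hull of member points ("outer extent") and
`r = √(area/π)`.

**Nucleus geometry and periphery.** The boundary is the alpha shape
(triangles with circumradius below 5 × median NN distance), falling back to
the convex hull with a warning if the alpha shape degenerates or excludes
over 1% of localizations; `R = √(area/π)`. A domain is peripheral when the
minimum distance from its member points (not its centroid) to the boundary
ring is below 0.15·R. Peripheral thickness is sampled along inward normals
at points uniformly spaced on the boundary: heterochromatic localizations
within a lateral strip (half-width max(100 nm, 2 × median NN distance)) are
ordered by depth, a contiguous run tolerates gaps up to 150 nm, the run's
extent gets the (n+1)/n extreme-value correction for sparse uniform
samples, and the result is rounded up to the 20 nm radial bin.

## Track statistics

Input is a track table from an external tracker; tracking itself is out of
scope. Gaps of up to 2 missing frames are linearly interpolated, longer
gaps split the track (counts logged). Total distance is the summed step
lengths; mean speed is total distance over elapsed time; net displacement
is endpoint minus start. Population "displacement" means total path length
(net displacement is reported alongside). Skewness is the adjusted
Fisher–Pearson estimator `G1 = g1·√(n(n−1))/(n−2)` — the default printed by
mainstream statistics tools — so reported values are directly comparable to
published ones; zero-variance samples are flagged as undefined rather than
returned as 0. The leading edge is the 0.95 quantile (not the maximum, for
outlier resistance) of positions projected on the declared gradient axis,
and its displacement is last-frame edge minus first-frame edge.

## Synthetic generators

One `numpy.random.default_rng(seed)` per call; identical arguments give
bitwise-identical output. Noise is additive Gaussian unless stated.
No noise magnitudes are asserted as any study's; defaults are exposed
parameters chosen at plausible instrument levels (force noise a few tens of
pN; localization jitter 15 nm, typical SMLM precision).

- **Force curves** sample the contact model exactly, uniformly in
  indentation from the post-snap-in equilibrium (`kδ₀ = 2πγR − Aδ₀^{3/2}`)
  to the trigger force, with `z = z_c + δ + P/k`; a flat baseline precedes
  contact. The snap-in instability itself is not simulated as dynamics —
  the curve starts on the stable branch, as real approach curves do after
  the jump.
- **Nanoneedle curves** superpose membrane-loading bumps (smoothstep rise
  over 0.1 µm, incremental decline over 0.15 µm) on a continuous piecewise-
  cone backbone whose segments may differ in E; the bump amplitude
  compensates the backbone's rise across the decline so the observed force
  drop equals the requested one, and the post-peak branch obeys the offset
  cone law exactly.
- **Traction scenes** build balanced fields (snapped Fourier modes or
  mean-subtracted Gaussian spots) and compute displacement with the same
  forward operator the inversion targets — an internal-consistency oracle,
  not an independent elasticity solution. Bead images are Gaussian spots
  advected by the field.
- **Nucleus clouds** are uniform disks plus uniform-disk domains with
  optional peripheral placement inside the 0.15·R band; ground-truth labels
  and per-domain peripheral flags are retained. At the default 15 nm jitter
  the convex-hull radius of an 80 nm domain is genuinely ~95–105 nm
  (jitter widens the point cloud), so radius-recovery checks use 5 nm
  jitter, where planted and measured radii coincide.
- **Tracks** mix drifting leaders (seeded on the leading-edge strip) with
  Gaussian-random-walk followers; follower step lengths are Rayleigh
  (2-D diffusion), so raising follower mobility broadens the follower
  displacement mass toward the leaders' and pulls skewness toward zero.

What passing tests on these generators shows: the estimators invert their
own stated forward models at realistic noise levels. What it does not show:
robustness to model misspecification in real data — viscoelastic response,
non-DMT adhesion, gel thickness effects, localization blinking/multiple
emitters, or tracker errors are all outside the generated families.

## Problem sizes

Default validation sizes — 100-seed Monte Carlo for contact fits, 200
nanoneedle curves, 64×64 traction grids, 256² bead images, nuclei of
3–6k localizations with 50-seed peripheral-rule sweeps, 500-track fields —
were chosen so the full suite completes in a few minutes on one core while
keeping Monte Carlo standard errors well below the tolerances tested.
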