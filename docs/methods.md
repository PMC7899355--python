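# Methods

## Optical model

The cornea is a centred, rotationally symmetric two-surface system in a 2D
meridional plane (axis `z` in mm, radial coordinate `y`). Each surface is a
conic of revolution `z − z0 = (r²/R)/(1 + √(1 − (1+Q) r²/R²))` with central
radius `R > 0` (convex toward −z) and conic constant `Q`; eccentricity
exports convert as `Q = −e²`. The front apex sits at the origin, the back
apex at `z = CCT`. Refractive indices are the Liou–Brennan schematic-eye
values, cornea 1.376 and aqueous 1.336; object space is air (n = 1) with
the source at infinity (collimated input). Tilt, decentration, toricity
and dispersion are outside the model.

A note on the sag convention: some descriptions of this model print a sag
formula whose square-root argument mixes units (`1 − Q·R·r²`); the package
uses the standard conic sag above, which reproduces the central curvature
`1/R`, the exact sphere for `Q = 0` and the parabola `r²/2R` for `Q = −1`.

## Raytrace

Rays start on the plano reference plane `z = 0`, are intersected with each
conic by solving the quadratic in the travel parameter (stable "q"
formulation; smallest positive root on the apex branch), and refracted
with the vector form of Snell's law. Optical path length accumulates as
`Σ n·(segment length)` from `z = 0` to the back-surface exit point. The
kernel was validated against an independent 40-digit arbitrary-precision
trace using angle arithmetic; agreement is at machine precision.

The default fan has 1001 rays equally spaced across the pupil projection
`[−PUP/2, +PUP/2]` at the front apex plane. Because a meridional ray at
radius `r` represents an annulus of area ∝ `r dr`, rays are weighted by
`|r|` and normalised (`weighting="area_linear"`); the alternative
`"quadratic"` scheme (`w ∝ r²`) is provided as a pupil apodisation option.
The rim-inclusive uniform spacing makes the discrete `⟨r²⟩` exceed the
continuous disk value `PUP²/8` by the factor `(n+1)/n` (+0.1% at 1001
rays, +0.2% counted per half-fan); this is a property of the prescribed
sampling, not an error term worth correcting.

## Best-focus criteria

At a candidate plane `z` the ray heights are `y_i(z)` and the total
optical path to the on-axis point `(0, z)` is
`OPL_i(z) = OPL_i^exit + n_aq · dist(exit_i, (0,z))`. The four merit
functions are

* `WFE(z)` — weighted RMS of `OPL_i(z)` after removing the weighted mean
  (piston), in µm;
* `RMSS(z) = √(Σ w y² / Σ w)`, `MAS(z) = Σ w |y| / Σ w`,
  `TSD(z) = max y − min y`, in mm.

**Zone convention.** The three spot criteria are evaluated on the
pupil-limited fan. The wavefront criterion is evaluated on a fan spanning
the fixed central 6-mm corneal zone — the same zone the spherical
aberration coefficient refers to — and is therefore independent of pupil
size. This is a deliberate design choice: for an SA-positive cornea the
pupil-zone balanced-defocus plane sits at ~1/2 of the pupil's longitudinal
aberration, *behind* the three spot planes (~2/3, ~0.71, ~3/4 for RMS, MA
and TSD respectively, under any radial weighting), whereas the fixed-zone
wavefront plane reproduces the clinically reported ordering
`z_WF < z_TSD < z_RMS < z_MA` and the reported median power of 43.0 dpt
for the mean cornea. Passing `wf_zone_diameter=None` restores the
pupil-fan wavefront criterion.

A consequence worth knowing: because the fixed-zone wavefront plane does
not move with the pupil, the spot-metric penalty for focusing at the
wavefront plane grows rapidly as the pupil shrinks (the spot planes
migrate toward the paraxial focus). For pupils below ≈3 mm the ratio
`RMSS(z_WF)/RMSS(z_RMS)` exceeds 5 and can reach ~30 at a 1.5-mm pupil;
cross-criterion robustness statements bounded by ~5 hold for typical
photopic pupils, not in the small-pupil tail. The wavefront-side ratios
(`WFE` at spot planes over `WFE` at its own plane) stay below ~4 for all
corneas.

**Search.** A preset focus comes from a least-squares (Kasa) circle fit to
the exit wavefront (points of equal OPL along the exit rays); it is exact
for a stigmatic bundle and lands within 2 mm of every optimum in practice.
The default optimiser is deterministic bounded Brent minimisation in a
±2 mm bracket (`xatol = 1e−9` mm); the piecewise-smooth TSD merit first
takes a 1000-point scan to isolate the winning interval. A seeded
simulated-annealing option (`method="anneal"`, scipy `dual_annealing`)
matches the deterministic optimum to 1e−4 mm on smooth criteria and exists
for methodological comparability; the merit functions are unimodal within
the bracket, so determinism is preferred.

**Power and index.** `CP = 1000·n_aq/z_F` referenced to the front apex
(`CP·z_F = 1336` exactly); `n_K = 1 + CP·R_f/1000` inverts keratometry per
eye.

## Spherical aberration

The OPD map over the 6-mm zone is `OPD_i = ⟨OPL⟩_w − OPL_i` in µm
(piston-free, positive = phase-advanced marginal ray), referenced by
default to the best-wavefront plane; the choice of reference plane moves
Z40 by <0.01 µm. Weighted least squares fits the OSA-normalised radial
Zernike polynomials {Z00, Z20, Z40, Z60} on `ρ = r/3 mm`; under the `|r|`
area measure these are mutually orthogonal, so Z60 merely absorbs
higher-order leakage from the discrete sampling. 201 rays are the default
(Z40 changes <1e−4 µm vs 1001). The Table-mean cornea yields
Z40 = +0.103 µm; Z40 increases monotonically with `Q_f` and crosses zero
near the front-surface Cartesian condition `Q = −(1/1.376)² ≈ −0.53`.

## Keratometer index and power models

Two population definitions of `n_K` are provided: `least_squares`
minimises `Σ (CP_i − 1000(n_K−1)/R_f,i)²` in closed form (default);
`mean_zero` zeroes the mean deviation `CP − P_K`, which is the convention
under which deviation tables have exactly zero mean. Reported cohort
tables are internally consistent for medians but not for means under the
per-eye definition `n_K = 1 + CP·R_f/1000` (the implied covariance exceeds
the attainable bound); the per-eye definition is retained and both
population modes are surfaced in batch output.

`fit_power_model` regresses the offset residual
`y = CP − 1000(n_K−1)/R_f` on an intercept plus the six covariates
(ordinary least squares via statsmodels); RMS error and R² describe that
residual regression. The four published coefficient sets are stored
verbatim; note that evaluating a fitted linear model at the covariate
means differs from the mean prediction by the `1/R_f` curvature, which is
why the printed models at the mean covariates land within ~0.1 dpt of (not
exactly on) the cohort-mean powers.

## Synthetic populations

`sample_population` draws truncated multivariate-normal covariates with
the published marginal means, SDs and min/max bounds (rejection sampling;
CCT sampled in µm, stored in mm). The default correlation matrix is the
identity because only marginals are published; a user-supplied correlation
(e.g. the strong physiological `R_f`–`R_b` coupling) can be provided but
is never treated as ground truth. What passing population tests therefore
show: marginal calibration, keratometer-index recovery (which is driven by
the `1/R_f` structure and is insensitive to correlations) and model-form
recovery. What they cannot show: cohort dispersion statistics — deviation
SDs and refit model RMS/R² depend on the joint distribution. Under
identity correlations the refit spot-criterion models reach RMS ≈
0.13–0.16 dpt (R² ≈ 0.93), versus ≈ 0.04–0.07 dpt (R² ≈ 0.90–0.94)
reported on the real, correlated cohort; the wavefront-criterion refit,
being pupil-independent, reaches ≈ 0.06 dpt. The uncorrelated generator
explores covariate corners (large pupil with steep flat-Q corneas) that
amplify the nonlinear pupil×shape interactions a 7-parameter linear model
cannot absorb.

## Problem sizes and numerics

Defaults: 1001 rays per pupil fan, 201 per 6-mm SA fan, 2,000 eyes for
population-level checks (≈30 s on one core; a full eye — trace, four focus
searches, Z40 — costs ≈18 ms). Intersections are accepted at 1e−10 mm
residual on the conic; degenerate cases (collimated exit bundles, planes
inside the cornea, rays beyond a surface extent, total internal
reflection, rank-deficient fits, infeasible truncation) raise typed
exceptions with machine-readable reason codes that the batch pipeline
logs per eye.

## Known limitations

Meridional (2D) rays only — valid because the model is rotationally
symmetric by construction; no toric/biconic surfaces, no tilt or
decentration, no chromatic dispersion, no Strehl/MTF merit functions, no
finite object distances. Population realism is limited to marginals, as
discussed above. The printed-model reproduction inherits the coefficients'
printed precision.
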