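# Methods

This note records the model, the numerical choices, and the design
decisions behind `protherm`, in the spirit of a model-description document:
everything here is either implemented and tested in the package or an
explicitly stated limitation.  No empirical claim is made that the test
suite or `scripts/acceptance.py` does not itself compute.

## Physical model

A hydrated protein is idealized as a homogeneous body with thermal
diffusivity D = κV/C_p (C_p per molecule), relaxing toward an infinite,
well-stirred bath pinned at T_f.  Heat conduction obeys ∂T/∂t = DΔT with
the Robin (third-kind) interface condition −κ ∂T/∂n = G(T_s − T_f).  The
model therefore assumes:

* the protein's heat capacity and conductivity are uniform over its
  volume (no secondary-structure resolution);
* the bath carries heat away instantly (water conducts several times
  better than protein, and the measured Biot numbers ~4 say the interface
  and interior, not the solvent, are rate-limiting);
* one geometry direction dominates at a time.  The radial and
  longitudinal directions of a cylindrical protein are analyzed
  *independently*, each assuming all heat leaves through its own surface;
  a coupled two-direction solution is out of scope.  The optional
  flux-partition correction (below) compensates for the double counting.

Separation of variables gives the volume-averaged normalized temperature

    θ(Fo) = Σₙ Aₙ exp(−λₙ² Fo),   Fo = D t / l²,

where λₙ solves, branch by branch,

| geometry               | eigencondition           | l     | Dirichlet λ₁ |
|------------------------|--------------------------|-------|--------------|
| sphere                 | 1 − λ cot λ = Bi         | R     | π            |
| cylinder, radial       | λ J₁(λ)/J₀(λ) = Bi       | R     | j₀,₁ ≈ 2.4048|
| cylinder, longitudinal | λ tan λ = Bi             | H/2   | π/2          |

and the coefficients Aₙ are the volume-average projections of the
eigenmodes — exactly the printed single-term coefficient functions
evaluated at λₙ (for the sphere, A(λ) = 6(sin λ − λcos λ)²/(λ³(λ −
sin λ cos λ)), and analogously with Bessel/trigonometric forms for the
two cylinder directions).  The coefficients are positive and sum to 1, so
θ(0) → 1 as terms are added, while the single-term value A₁ < 1.  This
identification is cross-checked against an independent finite-difference
solution (below) rather than assumed: the two agree to better than 10⁻³
in normalized units for Bi ∈ {0.5, 4, 20} in all three geometries.

## Inverse chain

1. **Normalization.** θ(t) = (T(t) − T_f)/(T_i − T_f).  By default T_i is
   the mean protein temperature over the first 1 ps of the trace and T_f
   the bath set-point (300 K) or the time-average of a supplied bath
   trace; both can be overridden.
2. **Exponential fit.** θ ≈ A·exp(−Bt) by unweighted least squares
   (Levenberg–Marquardt, initial guesses A₀ = 1, B₀ = 1/span).  Both A
   and B are free: λ₁ comes from A, τ from B.
3. **Eigenvalue.** λ₁ solves A(λ₁) = A_fit on (0, Dirichlet limit), where
   A(·) is strictly decreasing from 1 to its Dirichlet-limit value
   (6/π² ≈ 0.6079, 4/j₀,₁² ≈ 0.6917, 8/π² ≈ 0.8106).  A fitted A outside
   that open interval means the single-mode model cannot explain the
   trace (e.g. A ≥ 1); this raises a no-root error naming the valid
   interval instead of returning a number.
4. **Transport.** τ = λ₁²/B, κ = (l²/τ)(C_p/V), Bi from the
   eigencondition, G = Bi·κ/l (reported in MW/K/m²).  With C_p in
   kJ/mol/K (converted per molecule via Avogadro's number), lengths in nm
   and times in ps, κ comes out in W/K/m.  The unit chain is pinned by a
   closed-form inversion: κ = 0.10 W/K/m for a 1.529 nm sphere with
   C_p = 27 kJ/mol/K implies τ ≈ 70 ps, the right order for a small
   protein.

### Fit window (burn-in)

The single-exponential model describes only the slowest eigenmode.  At
Bi ≈ 4 the n ≥ 2 modes carry ~10–15 % of the initial amplitude and decay
4–9× faster; including t = 0 in the fit biases A and B upward and
propagates into tens-of-percent errors in κ.  The default window therefore
discards a burn-in of one fitted e-folding time 1/B from the start of the
trace (capped at half the span), iterating fit → window → fit until the
window stabilizes.  One e-folding suppresses the contaminating modes to
the sub-percent level while retaining enough signal above the noise floor
for stable fits; an explicitly supplied window is always used verbatim.

## Protein size estimation

Gyration moments about the (mass-weighted, by default) center of mass:

* sphere: r_s = √(Σmᵢ|xᵢ−x̄|²/Σmᵢ);
* cylinder: positions are rotated to the principal axes of the covariance
  matrix; the symmetry axis is the direction of **largest** variance
  (sign fixed so the first nonzero component is positive), r_c² is the
  sum of the two transverse variances and h_c = 2√⟨w²⟩ along the axis,
  so a uniform solid cylinder (R, H) yields exactly r_c = R/√2 and
  h_c = H/√3.

Degenerate input handling: clouds with zero total extent are rejected;
perfectly collinear clouds are accepted and return r_c = 0 with the axis
along the line.  For an isotropic body all variances coincide and the
axis choice is arbitrary but deterministic.

"Filling-corrected" sizes are the dimensions of the uniform solid with
the same gyration moments: R_s = √(5/3)·r_s ≈ 1.29 r_s, R_c = √2·r_c,
H_c = √3·h_c.  At fixed fitted (A, B) the switch from gyration to filling
sizes rescales the outputs by closed-form factors:

| geometry               | κ factor        | G factor     |
|------------------------|-----------------|--------------|
| sphere                 | √(3/5) ≈ 0.77   | 3/5 = 0.60   |
| cylinder, radial       | 1/√3 ≈ 0.58     | 1/√6 ≈ 0.41  |
| cylinder, longitudinal | √3/2 ≈ 0.87     | 1/2 = 0.50   |

A related diagnostic, the ratio of the gyration-matched sphere volume to
the gyration-sized cylinder volume, uses r_s² = R_c²/2 + H_c²/12 for a
uniform cylinder.  Evaluating that formula, the ratio attains its minimum
√3 ≈ 1.732 at aspect ratio R_c/H_c = 1/√3 (verified against a dense
numerical scan); values reported elsewhere as "3 at 1/3" appear to have
lost the radicals in typesetting, and this package deliberately computes
the formula rather than reproducing those rounded strings.

### Flux partition (optional, off by default)

Analyzing each cylinder direction alone attributes the whole heat flux to
that direction.  If the two contributions scale with the lateral and
end-cap cross sections (2πRH : 2πR² = H : R), multiplying the radial
results by H/(H+R) and the longitudinal ones by R/(H+R) shares the flux
consistently.  It is exposed as `--flux-partition` and deliberately not
applied by default, matching the convention of the reported tables.

## Replicate statistics

Replicate κ or G values (per solvent-box size) are screened with the
two-sided Grubbs test at α = 0.05, applied iteratively: the single most
extreme value is tested against the critical value
G_crit = (n−1)/√n · √(t²/(n−2+t²)), t the upper α/(2n) Student-t quantile
with n−2 degrees of freedom, and removed if significant, until the set is
clean or only two values remain.  Reported numbers are the mean ± sample
SD (n−1 denominator) of the retained values pooled across the selected
box sizes with equal weight per value (not per box).

## Synthetic data generator

`SyntheticSpec` emulates the relaxation protocol the pipeline targets: a
protein at T_i = 400 K released into a T_f = 300 K bath, its
volume-averaged temperature sampled every 1 ps for 100 ps, repeated over
10 replicates.  Ground-truth κ and G fix Bi and D; the clean curve is the
eigenfunction series (200 terms by default, or the FD solver), and each
replicate adds i.i.d. Gaussian noise, 2 K by default — chosen to mimic
the visual scatter of published instantaneous-temperature traces; it is a
package choice, not a measured value.  All randomness flows from one seed
(bit-identical traces for a fixed spec).

What the generator deliberately does **not** emulate: correlated noise
from the finite protein heat bath (real kinetic-energy fluctuations are
autocorrelated over ~ps and scale like T/√N_dof), the initial 10 ps
dual-thermostat equilibration, force-field-specific heat capacities, or
any solvent structure.  Passing recovery tests therefore demonstrates the
*inverse machinery* is unbiased and stable at realistic noise amplitudes
— not that MD data will match the idealized model this well.

### Finite-difference oracle

The independent check solves ∂θ/∂Fo = (1/r^p)∂/∂r(r^p ∂θ/∂r) with p = 2,
1, 0 (sphere, cylinder radial, slab) on r ∈ [0, 1], θ(r, 0) = 1, a
symmetry condition at the center (Laplacian limit 2(p+1)(θ₁−θ₀)/h²) and
the Robin condition via a second-order ghost node θ_{N+1} = θ_{N−1} −
2hBi·θ_N.  Explicit Euler stepping with dt = 0.8/max|diag| (Gershgorin
bound; blow-ups are detected and raised as solver errors), second-order
central differences, r^p-weighted trapezoidal volume averaging.  Grid
refinement halving h reduces the error ~4×, confirming second-order
convergence; the default grid (150–200 nodes) keeps the FD/series
discrepancy near 10⁻⁵–10⁻⁴, well below the 10⁻³ acceptance band.

## Validation experiments and problem sizes

* Series vs FD: Bi ∈ {0.5, 4, 20} × 3 geometries, t/τ₁ ∈ [0, 5], 26 time
  points, grid 150 — runs in ~30 s total.
* Noiseless recovery (all geometries): κ within 2 %, G within 5 % of
  ground truth; the residual bias is the burn-in-truncation remnant.
* Noisy recovery: 2 K noise, 10 replicates, analyzed via the
  ensemble-averaged trace.  Per-replicate fits at this noise level are
  heavy-tailed (κ ∝ B/λ₁² diverges as the fitted A approaches 1), so
  averaging the replicate traces *before* fitting is the package's
  canonical ensemble estimate; per-replicate estimation + Grubbs + mean
  remains available (and appropriate) for box-size tables.  The averaged
  estimate carries a relative spread of roughly 8 % (κ) and 6 % (G)
  across noise realizations at these settings, so a single experiment
  recovers both within the documented 15 % band in the typical case but
  not with certainty — the κ/G inversion is intrinsically sensitive to
  the fitted prefactor, a known property of this analysis scheme.

## Numerical choices

* Eigenvalue roots: bracketed Brent iteration on analytically known
  branch intervals (between consecutive poles of cot, J₀ zeros, tan),
  xtol 10⁻¹⁴; never unguarded Newton.  A 10⁻⁸ margin excludes the poles.
* Coefficient functions near λ = 0 behave as 1 − λ⁴/c (c = 525, 192, 45);
  below λ = 0.01 that series replaces the closed forms, which lose ~8
  digits to cancellation there.
* Tolerances: eigenvalue round-trips to 10⁻¹⁰; Biot/eigenvalue mutual
  consistency to 10⁻⁹; series-vs-FD to 10⁻³ (normalized units).
* Heat capacities are interpreted per mole of protein molecules and
  converted per molecule by Avogadro's number; the τ ≈ 70 ps inversion
  above is the plausibility anchor for this convention.

## Known limitations

* No coupled radial+longitudinal solution; the flux-partition factor is a
  proportionality heuristic, not a solution of the 2-D problem.
* C_p is an input; the package does not estimate it from data.
* The bath is infinite: finite-box effects (the approach of κ/G to their
  large-box plateaus) can be *studied* with the aggregation tools but are
  not modeled by the generator.
* Single-exponential fitting with a burn-in is the supported estimator;
  no multi-exponential, stretched-exponential or Bayesian variants.
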