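# Methods

## Constitutive model

The material is a transversely isotropic hyperelastic solid with scalar
continuum damage. The strain energy density splits into a deviatoric part and
a volumetric penalty,

    psi = F1(I1~, I2~) + F2(lam~) + K/2 (ln J)^2,

with `I1~`, `I2~` the invariants of the deviatoric right Cauchy–Green tensor
`C~ = J^(-2/3) F^T F`, `lam~` the deviatoric fiber stretch and `J = det F`.
The ground substance is Veronda–Westmann,

    F1 = C1 (exp(C2 (I1~ - 3)) - 1) - C1 C2 / 2 (I2~ - 3),

and the fiber network is defined through its stretch-scaled derivative

    lam~ dF2/dlam~ = 0                                  lam~ <= 1
                   = C3 (exp(C4 (lam~ - 1)) - 1)        1 < lam~ < lam_m
                   = C5 lam~ + C6                       lam~ >= lam_m,

so fibers carry load only in tension; `C6 = C3 (e^{C4 (lam_m - 1)} - 1) -
C5 lam_m` makes the fiber stress continuous at the transition stretch
`lam_m`. The energy `F2` is reconstructed from the derivative with
`F2(1) = 0`; the toe branch integrates in closed form through the
exponential integral, and the constants are chosen so `F2` is C^1 at
`lam_m`. The undamaged Cauchy stress is the deviatoric push-forward of the
isochoric energy derivatives plus the volumetric pressure `K ln(J)/J`; the
implementation is verified against central-difference differentiation of
the energy (relative error below 1e-3 on random states, typically ~1e-9).

Damage is a scalar `D` driven by the history maximum of a criterion `Xi` —
the von Mises stress of the undamaged Cauchy stress, or the maximum
principal Lagrange strain — through a quintic smoothstep between the
thresholds `mu_min` and `mu_max`:

    D = D_max x^3 (6 x^2 - 15 x + 10),   x = clip((Xi - mu_min)/(mu_max - mu_min), 0, 1).

The quintic branch is scaled by `D_max`; without that scaling the law would
jump from 1 to `D_max` at `x = 1`, contradicting `D_max`'s role as the
damage cap. Damage is irreversible (the driver is the running maximum of
`Xi`) and degrades the full stress tensor, `sigma = (1 - D) sigma_0`,
including the volumetric term — the simplest reading of the stress-scaling
law; constituent-split damage is a known alternative but requires bookkeeping
the model description does not define. `D_max < 1` always; total failure is
never reached, which keeps the solvers stable and reproduces the
experimentally observed restabilization of transverse specimens after
localized softening.

Units everywhere: MPa, mm, N; stretches and strains dimensionless.
`K = 1000 MPa` enforces near-incompressibility (|J - 1| < ~1e-3 at working
stresses).

## Uniaxial material-point driver

`simulate_uniaxial` marches a prescribed axial stretch path and solves the
two lateral stretches for zero lateral Cauchy stress by Newton iteration
(residual tolerance 1e-8 MPa; the two lateral stretches are independent
because transverse fiber orientation breaks axisymmetry). Damage is frozen
during each equilibrium solve and updated once per converged step; a step
is subdivided whenever the damage increment would exceed 0.05, which
stabilizes softening branches. Loading orientations: longitudinal = fibers
along the load axis (y), transverse = fibers along the in-plane width axis
(x). Nominal stress is `sigma_yy * lat_x * lat_z`; force is nominal stress
times the reference cross-section. The driver treats grip-to-grip stretch
as homogeneous material stretch — an approximation used inside fitting
loops for speed; the finite element coupon is the reference for
coupon-level effects (shoulder compliance, necking, localization).

## Finite element model

The coupon is modeled as one octant of the dogbone (three symmetry planes),
meshed as a structured hex grid split into 6 tetrahedra per cell by a fixed
template. The grid is graded: width/thickness subdivision applies globally
and axial subdivision only inside a central band (default 2.5 mm full-coupon
height), which keeps the mesh conforming while concentrating resolution
where damage localizes. At the default four-fold refinement the longitudinal
mesh carries ~29k linear tets with 0.125 mm axial rows in the band.

Dogbone dimensions are package defaults chosen to be consistent with the
derived quantities the pipeline reports (quarter cross-sections of ~0.5 mm^2
longitudinal / 0.6 mm^2 transverse; two-element tear-ROI heights of 0.25 mm
longitudinal and 0.2 mm transverse at production refinement):

- longitudinal: 10 x 2 x 1 mm grip-to-grip x gauge width x thickness,
  grip width 4 mm, fillet radius 2 mm, straight gauge 4 mm;
- transverse: 8 x 2.4 x 1 mm, grip width 4.8 mm, fillet radius 1.6 mm,
  straight gauge 3.2 mm.

Boundary conditions idealize the rigid grip as a kinematic constraint:
grip-face nodes carry the prescribed axial displacement with lateral
translations free (the limiting case of a stiff frictionless sliding
contact); symmetry planes have zero normal displacement. The solve is total
Lagrangian displacement control: per load step, Newton iteration with a
numeric (forward-difference) consistent tangent assembled element-wise in
batch, an LU factorization that is reused while the residual contracts
(modified Newton), backtracking line search, and a linear predictor
extrapolated from the previous two converged states. Damage is explicit —
frozen during Newton, updated from the converged state — with adaptive step
cutback (halving, up to 6 times) on divergence or damage increments above
0.05. Equilibrium residuals at accepted steps are driven below 1e-8 of the
step's force scale; the patch test (affine boundary data) reproduces the
constitutive stress to machine precision because linear tets are
constant-strain.

Penalty incompressibility with pure displacement linear tets mildly locks;
this is accepted deliberately to stay with the element family the coupon
models use. Mesh convergence is therefore assessed on the reported
quantity: the tear-region surface strain.

## Tear metrics

All validation quantities live on the imaged surface (the z-max face of the
octant). The tear ROI is the element row with the greatest width-averaged
damage plus its neighbors, clipped at the mesh boundary; for a midplane
tear this is a two-row band (0.25 mm longitudinal / 0.2 mm transverse at
production refinement, matching the reported ROI heights). ROI strains are
area-weighted face averages of the in-plane Lagrange components; principal
values come from the 2x2 in-plane block and `gamma_max = E1 - E2` (the
in-plane Mohr-circle diameter — the convention planar DIC reports). The UTS
step is the converged step with maximum grip reaction.

Tear angle: surface damage is thresholded at 80% of its maximum and the
band orientation measured from the width axis (0 deg = straight across,
90 deg = parallel to the load), separately for each axial half of the
band's own extent so an angle change along the band is visible. For thin
bands (covariance anisotropy > 4) the angle is the damage-weighted
principal axis of the face centroids; for diffuse, cap-saturated fields the
band is first condensed to its damage-weighted ridge (weighted y-centroid
per width column) and the principal axis taken over the ridge points —
a raw principal axis over a blob would measure the blob's aspect ratio, not
the band. Synthetic oriented-band fixtures are recovered within 2 deg
across -90..90 deg.

Mesh convergence reports the surface `E_yy` averaged over a fixed-height
band (two refined-row heights of the coarsest mesh) centered on the finest
solution's damage-peak line, so every refinement level reports the same
physical region; the plateau flag requires the last increment below 25% of
the first across three levels.

## Sequential calibration

1. Yield = point of maximum smoothed slope (second-order Savitzky–Golay
   derivative on a uniformly resampled curve; default window 30% of the
   record, which places the detected yield inside the slope plateau rather
   than at its onset; ties break earliest and flat curves are flagged
   degenerate).
2. Ground substance (C1, C2) fit per transverse specimen up to yield,
   then fibers (C3, C4, C5, lam_m) per longitudinal specimen with the
   pooled ground substance frozen — bounded trust-region least squares with
   the model force evaluated by the uniaxial driver on a thinned grid
   (<= 32 points). A fit that lands on a bound has that extremum expanded
   by 30% (toward the hard floor for lower bounds: 0 for moduli, 1 for
   lam_m) and is re-run, up to 10 times. Failed forward runs contribute a
   large finite penalty residual, never an exception.
3. Damage triplet (mu_min, mu_max, D_max) per specimen and criterion by a
   deterministic multiplicative coordinate search (x/÷1.3 steps, halving on
   stagnation, 250-evaluation budget) seeded at the undamaged criterion
   values at the target's yield and ultimate points and D_max = 0.6, after
   a small coarse scan around the seed. The objective is force RMSE plus a
   penalty per unmet success criterion, mirroring a manual fit that tunes
   toward explicit acceptance rules: ultimate stress within 0.2 MPa
   (longitudinal) / 0.03 MPa (transverse), ultimate grip-to-grip strain
   within 3% (engineering, stretch - 1), and a post-ultimate stress drop of
   at least 1% / 0.5%. D_max is constrained below 1 (0.94 in the search).
4. Quality of fit: NRMSE normalized to mean target stress (percent) and
   R^2, both on the target's stretch grid.

Initial guesses and bounds follow the protocol of seeding from the cohort's
previously measured properties with roughly two-standard-deviation limits.
For the synthetic cohort that scale is the generator's (C1 ~ 0.026 MPa,
C5 ~ 9.5 MPa, lam_m ~ 1.02); the coupon-resolved cadaveric averages
(C1 = 0.78 MPa, C5 = 119.63 MPa, lam_m = 1.048) are kept available as
`TISSUE_SCALE_GUESSES` for experimental-scale curves. C2 starts at 1 with
half/double limits in both sets.

## Synthetic data

The model-based generator runs the damage material forward through the
uniaxial driver and adds seeded homoscedastic Gaussian force noise
(sd = 1% of the target ultimate force; the first sample stays exactly
zero). Default parameters are grip-to-grip-equivalent values calibrated
once so the forward model hits the experimental group means — ultimate
force 2.25 N at grip-to-grip stretch 1.155 longitudinal, 0.100 N at 1.493
transverse — under the study's damage caps (D_max 0.58 longitudinal von
Mises; 0.80 transverse max-normal-strain). They are deliberately smaller
than the coupon-resolved fitted averages because a single material point
conflates grip-to-grip and gauge stretch: the published moduli, pushed
through a homogeneous specimen at the published grip-to-grip ultimate
stretch, would overpredict the published ultimate force several-fold. The
fiber toe coefficient C3 is set for slope continuity into the linear
modulus at lam_m (as the cadaveric averages also imply), lam_m = 1.02
so a usable linear segment exists below damage onset, and the records end
at grip stretch 1.28 (longitudinal) / 1.55 (transverse), inside the
post-ultimate softening and before the capped-damage restabilization would
overtake the ultimate point. Specimen-to-specimen dispersion: a common
lognormal factor (5% CV) on all moduli (and on stress-valued damage
thresholds, keeping each specimen self-consistent), 5% CV on thresholds,
and +-0.03 (clipped to +-0.05) on D_max — well inside the experimental
standard deviations, so five-specimen groups exercise the fitting
tolerances meaningfully.

The phenomenological generator produces the observed curve shape directly:
backbone `F_u (e/e_u)^p exp(p (1 - e/e_u))` (convex toe to the inflection
at `e/e_u = 1 - 1/sqrt(p)`, approximately linear mid-section, maximum at
`e_u`, smooth softening), with optional seeded Gaussian stress peaks
between toe and 0.8 e_u emulating the localized pre-ultimate peaks of
transverse specimens.

What the generators do not emulate: coupon-level strain inhomogeneity
(shoulders, necking, localization), strain-rate effects, preconditioning
history, heteroscedastic or correlated measurement noise, and specimen
geometry variability. Passing the recovery and tolerance tests therefore
demonstrates that the calibration machinery is correct and well-posed under
the model's own assumptions, not that it resolves those tissue-level
effects.

## Known limitations and identifiability

- The transverse damage cap `D_max` is only weakly identified from a single
  force-stretch record because the recorded strains stop short of `mu_max`:
  (mu_max, D_max) trade off along a flat valley. Recovery errors of ~0.1-0.15
  on transverse D_max are intrinsic at the default noise level (the large
  published scatter on the transverse thresholds reflects the same valley).
  The longitudinal cap, which the record does traverse, recovers to ~0.02.
- The elastic fiber fit is ill-posed when the data end near the toe-linear
  transition; the wide yield-detection window and cohort-scale bounds keep
  the fit inside the identifiable regime.
- Without nonlocal regularization (deliberately absent), strain in the tear
  band localizes toward the smallest elements; the damage cap bounds this,
  and the convergence study measures a fixed physical region so the plateau
  is meaningful, but tear-band widths remain mesh-influenced.
- Tear-pattern runs use band refinement 2 and stop near the experimental
  ultimate stretch (1.20 grip-to-grip longitudinal, 1.50 transverse):
  beyond it the capped damage saturates across the gauge and the band
  structure washes out, consistent with the model's restabilization
  behavior.

## Problem sizes of the shipped studies

Five specimens per orientation for all fitting studies; dogbone solves at
band refinement 2 (4.6-4.9k tets) with 20-25 load steps; mesh convergence
on refinement levels 1/3/4 (1.0k/12.1k/24.6k tets; band-row heights
0.5/0.167/0.125 mm — a coarse reference plus two levels inside the
saturation regime) at 8 load steps with a relaxed Newton tolerance (1e-7)
and damage increments up to 0.1 per step.
These sizes were chosen so every study completes comfortably on a single
CPU while preserving the qualitative behavior of the full-resolution runs.
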