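# meniscus-cdm

Simulation and calibration pipeline for tensile failure of human meniscus
using continuum damage mechanics (CDM).

Meniscal tears disrupt either the circumferential collagen fibers (radial
and flap tears) or the ground substance between them (horizontal and
vertical tears). This package models both failure modes in a single
transversely isotropic hyperelastic damage material and asks whether a
continuum damage description can reproduce (i) the grip-to-grip
force–displacement behavior of dogbone tensile coupons pulled to failure
along or across the fiber direction, and (ii) the localized surface strains
and tear angles in the failure region — the quantities an optical (DIC)
system measures around a forming tear.

## Model

Strain energy (MPa, mm, N units throughout):

    psi = F1(I1~, I2~) + F2(lam~) + K/2 (ln J)^2
    F1  = C1 (e^{C2 (I1~ - 3)} - 1) - C1 C2/2 (I2~ - 3)          (ground substance)
    lam~ F2' = 0                        lam~ <= 1                 (fibers, tension only)
             = C3 (e^{C4 (lam~-1)} - 1)  1 < lam~ < lam_m
             = C5 lam~ + C6              lam~ >= lam_m

with C6 fixed by stress continuity at lam_m and K = 1000 MPa enforcing
near-incompressibility. Damage D in [0, D_max) follows the history maximum
of a criterion Xi — von Mises stress of the undamaged Cauchy stress
(fiber-type failure) or maximum normal Lagrange strain (ground-substance
failure) — through a quintic smoothstep CDF between mu_min and mu_max, and
degrades the stress as sigma = (1 - D) sigma_0.

Three model layers share this material:

- `material_point` — homogeneous uniaxial-stress driver (fast; used inside
  calibration loops),
- `fe_model` — total-Lagrangian quasi-static FE solve of the 1/8-symmetry
  dogbone coupon on linear tetrahedra, displacement-driven with an explicit
  damage update,
- `tear_metrics` — tear-region ROI extraction, ROI-averaged surface
  Lagrange strains at the ultimate step, tear angles, mesh-convergence
  reporting.

`curve_fitting` reproduces the sequential calibration (yield detection →
ground substance from transverse curves → fibers from longitudinal curves →
manual-style damage search against explicit success criteria), and
`synthetic_data` generates experiment-like tensile curves with known ground
truth — no public tensile data set exists for these cadaveric experiments,
so every stage is exercised on seeded synthetic stand-ins centered on the
published group means. See `docs/methods.md` for assumptions, numerical
choices, and known identifiability limits.

## Worked example

Generate the synthetic cohort and calibrate the material:

```
$ python analysis/01_synthesize_curves.py
longitudinal: ultimate force 2.280 N, ultimate stretch 1.150 (n=5; experimental
means 2.25 N / 1.155 longitudinal, 0.100 N / 1.493 transverse)
transverse: ultimate force 0.110 N, ultimate stretch 1.485 (...)
wrote 10 curves to .../results/curves

$ python analysis/02_fit_material.py
pooled elastic parameters:
  C1 = 0.03486
  C2 = 0.8229
  C3 = 0.09086
  C4 = 43.65
  C5 = 9.265
  lambda_m = 1.018
fiber modulus C5 recovered within 3.0% on average
                                NRMSE_pct      R2  success
orientation  criterion
longitudinal max_normal_strain     3.9526  0.9901        5
             von_mises             3.4332  0.9933        5
transverse   max_normal_strain     2.5583  0.9978        4
             von_mises             3.7797  0.9943        4
```

The ultimate-point statistics of the generated cohort sit on the
experimental group means; the sequential fit recovers the fiber modulus C5
to within 10% and meets the published success tolerances (ultimate stress
within 0.2 MPa longitudinal / 0.03 MPa transverse, ultimate strain within
3%, a post-ultimate stress drop) on at least 4 of 5 specimens per group,
with fit quality in the published regime (longitudinal R^2 > 0.99,
transverse R^2 > 0.93).

Solve the dogbone models with the fitted-average parameters and extract
tear patterns:

```
$ python analysis/03_tear_patterns.py
longitudinal/von_mises: full-coupon ultimate force 30.74 N, ROI E_yy 0.205,
tear angles [9.8, 31.8] deg
longitudinal/max_normal_strain: ... tear angles [-2.5] deg
transverse/von_mises: ... tear angles [0.4, 17.8] deg
transverse/max_normal_strain: ... tear angles [0.8, 33.4] deg
```

Transverse models and longitudinal max-normal-strain models tear straight
across the coupon (dominant angle ~0 deg), while longitudinal von Mises
models develop an oblique band near the fillet that flattens toward the
midline — the anisotropic tear-pattern signature that distinguishes the two
damage criteria. `analysis/04_mesh_convergence.py` reports the
tear-region strain across three band-refinement levels (monotone increase
with a plateau).

A CLI wraps the same stages: `meniscus-cdm synth|fit|solve|all`
(see `meniscus-cdm --help`).

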