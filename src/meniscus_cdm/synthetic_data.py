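"""Experiment-like synthetic tensile curves and damage-field fixtures.

No public tensile data set exists for these cadaveric experiments, so every
pipeline stage is exercised on synthetic stand-ins with known ground truth.
Two generators are provided:

- a model-based generator that runs the damage material forward through the
  uniaxial driver and adds seeded Gaussian force noise (for parameter
  recovery: the generating parameters are bundled with the curve), and
- a phenomenological generator producing the experimentally observed curve
  shape directly (exponential toe, linear region, smooth post-ultimate
  softening, and optional localized pre-ultimate stress peaks in transverse
  curves) without reference to the constitutive model.

Default generator specs are centered on the experimental group means
(ultimate force 2.25 N at grip-to-grip stretch 1.155 longitudinal; 0.100 N at
1.493 transverse) with specimen-to-specimen dispersion well inside the
experimental standard deviations, so five-specimen synthetic groups exercise
the fitting tolerances meaningfully.  The model-based defaults are
grip-to-grip-equivalent material parameters calibrated once so the forward
model hits those means; they are deliberately smaller than the
coupon-resolved fitted averages because the single material point conflates
grip-to-grip and gauge stretch.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .constitutive import Criterion, DamageParams, MaterialParams
from .fe_model import FEMesh
from .material_point import (Geometry, TensileCurve, curve_from_solution,
                             locate_uts, simulate_uniaxial)

__all__ = [
    "GeneratorSpec",
    "DEFAULT_MATERIAL",
    "DEFAULT_DAMAGE",
    "default_spec",
    "sample_ground_truth",
    "generate_curve_model_based",
    "generate_curve_phenomenological",
    "generate_damage_field_fixture",
]

# Grip-to-grip-equivalent default material shared by both orientations
# (ground substance identical; fibers only load longitudinally).  C3 is set
# so the fiber toe slope runs continuously into the linear modulus C5 at
# lambda_m, as the coupon-resolved fitted averages also do.
DEFAULT_MATERIAL = MaterialParams(C1=0.0272, C2=1.0, C3=0.1032, C4=40.83,
                                  C5=9.534, lambda_m=1.02, K=1000.0)

DEFAULT_DAMAGE = {
    "longitudinal": DamageParams(Criterion.VON_MISES, 1.100, 2.200, 0.58),
    "transverse": DamageParams(Criterion.MAX_NORMAL_STRAIN, 0.12, 1.00, 0.80),
}

_GEOMETRY = {
    "longitudinal": Geometry(gauge_length=10.0, cross_section_area=2.0),
    "transverse": Geometry(gauge_length=8.0, cross_section_area=2.4),
}

_GRID_END = {"longitudinal": 1.28, "transverse": 1.55}


@dataclass(frozen=True)
class GeneratorSpec:
    """Specification of one synthetic tensile curve."""

    orientation: str
    target_ultimate_force: float       # N
    target_ultimate_stretch: float     # grip-to-grip
    toe_extent: float                  # engineering strain of the toe region
    softening_sharpness: float         # shape exponent of the softening bump
    peak_count: int = 0                # localized pre-ultimate stress peaks
    peak_amplitude: float = 0.0        # N
    noise_sd: float = 0.0              # N, additive Gaussian
    seed: int = 0
    n_points: int = 120

    def __post_init__(self) -> None:
        if self.target_ultimate_force <= 0 or self.target_ultimate_stretch <= 1:
            raise ValueError("targets must be positive (stretch > 1)")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        if self.target_ultimate_stretch - 1.0 <= self.toe_extent:
            raise ValueError("ultimate stretch must exceed the toe extent")


def default_spec(orientation: str, seed: int = 0) -> GeneratorSpec:
    """Default spec centered on the experimental group means."""
    if orientation == "longitudinal":
        return GeneratorSpec(orientation, 2.25, 1.155, toe_extent=0.05,
                             softening_sharpness=4.0,
                             noise_sd=0.01 * 2.25, seed=seed)
    if orientation == "transverse":
        return GeneratorSpec(orientation, 0.100, 1.493, toe_extent=0.15,
                             softening_sharpness=3.0, peak_count=2,
                             peak_amplitude=0.004,
                             noise_sd=0.01 * 0.100, seed=seed)
    raise ValueError(f"unknown orientation {orientation!r}")


def sample_ground_truth(orientation: str, rng: np.random.Generator,
                        stiffness_cv: float = 0.05,
                        threshold_cv: float = 0.05,
                        dmax_sd: float = 0.03):
    """Draw one specimen's true parameters around the defaults.

    Stress-like quantities (moduli and, for the von Mises criterion, the
    damage thresholds) share a common lognormal factor so each specimen is a
    self-consistent rescaling; dispersions are small multiples of the
    defaults, well inside the experimental standard deviations.
    """
    s = float(np.exp(rng.normal(0.0, stiffness_cv)))
    t = float(np.exp(rng.normal(0.0, threshold_cv)))
    m = DEFAULT_MATERIAL
    params = replace(m, C1=m.C1 * s, C3=m.C3 * s, C5=m.C5 * s)
    dp0 = DEFAULT_DAMAGE[orientation]
    thr = t * (s if dp0.criterion is Criterion.VON_MISES else 1.0)
    dmax = float(np.clip(dp0.D_max + rng.normal(0.0, dmax_sd),
                         dp0.D_max - 0.05, min(dp0.D_max + 0.05, 0.94)))
    dp = DamageParams(dp0.criterion, dp0.mu_min * thr, dp0.mu_max * thr, dmax)
    return params, dp


def generate_curve_model_based(params: MaterialParams, dp: DamageParams,
                               spec: GeneratorSpec):
    """Forward-simulate a tensile curve and add seeded force noise.

    Returns ``(curve, truth)`` where ``truth`` records the generating
    parameters, the noise-free ultimate point and the seed.  If the forward
    run terminates before the target stretch the run is regenerated with a
    reduced end stretch (recorded in the truth dict).
    """
    geom = _GEOMETRY[spec.orientation]
    end = _GRID_END[spec.orientation]
    rng = np.random.default_rng(spec.seed)
    for _ in range(6):
        grid = np.linspace(1.0, end, spec.n_points)
        sol = simulate_uniaxial(params, dp, spec.orientation, grid)
        if not sol.terminated_early:
            break
        end = 1.0 + 0.8 * (sol.converged_through - 1.0)
    else:
        raise RuntimeError("forward model keeps terminating early")
    clean = curve_from_solution(sol, geom)
    uts = locate_uts(clean)
    noise = rng.normal(0.0, spec.noise_sd, size=len(clean.force))
    noise[0] = 0.0  # force starts at zero by construction
    curve = TensileCurve(stretch=clean.stretch,
                         force=clean.force + noise,
                         orientation=spec.orientation,
                         gauge_length=geom.gauge_length,
                         cross_section_area=geom.cross_section_area,
                         meta={"seed": spec.seed, "generator": "model_based",
                               "grid_end": end})
    truth = {
        "params": params, "damage_params": dp, "spec": spec,
        "ultimate_force": uts.force, "ultimate_stretch": uts.stretch,
        "seed": spec.seed, "grid_end": end,
    }
    return curve, truth


def _bump_shape(s: np.ndarray, p: float) -> np.ndarray:
    """Unit-peak curve s^p exp(p(1-s)): convex toe, linear rise, smooth
    softening past the maximum at s = 1."""
    return s ** p * np.exp(p * (1.0 - s))


def generate_curve_phenomenological(spec: GeneratorSpec) -> TensileCurve:
    """Parametric experiment-shaped curve without the constitutive model.

    The backbone is ``F_u * (e/e_u)^p exp(p (1 - e/e_u))`` in engineering
    strain e, which has a strictly convex toe up to its inflection (the yield
    point), an approximately linear mid-section, the maximum F_u at e_u, and
    smooth softening beyond.  Transverse specs superpose ``peak_count``
    seeded, localized Gaussian stress peaks between toe and ultimate.
    """
    rng = np.random.default_rng(spec.seed)
    geom = _GEOMETRY[spec.orientation]
    e_u = spec.target_ultimate_stretch - 1.0
    e_end = 1.25 * e_u
    e = np.linspace(0.0, e_end, spec.n_points)
    p = spec.softening_sharpness
    f = spec.target_ultimate_force * _bump_shape(e / e_u, p)
    if spec.peak_count > 0:
        lo, hi = max(spec.toe_extent, 0.4 * e_u), 0.9 * e_u
        centers = rng.uniform(lo, hi, size=spec.peak_count)
        widths = rng.uniform(0.02, 0.04, size=spec.peak_count) * e_u
        for c0, w0 in zip(centers, widths):
            f = f + spec.peak_amplitude * np.exp(-0.5 * ((e - c0) / w0) ** 2)
    if spec.noise_sd > 0:
        noise = rng.normal(0.0, spec.noise_sd, size=len(e))
        noise[0] = 0.0
        f = f + noise
    f[0] = 0.0
    return TensileCurve(stretch=1.0 + e, force=f,
                        orientation=spec.orientation,
                        gauge_length=geom.gauge_length,
                        cross_section_area=geom.cross_section_area,
                        meta={"seed": spec.seed, "generator": "phenomenological"})


def generate_damage_field_fixture(band_angle_deg: float, band_width: float,
                                  mesh: FEMesh,
                                  damage_in: float = 0.9,
                                  damage_out: float = 0.01) -> np.ndarray:
    """Element damage map with an oriented band through the surface center.

    The band runs at ``band_angle_deg`` from the width axis (x) in the x-y
    plane, centered on the mesh centroid; elements whose centroids fall
    within ``band_width`` of the band line get ``damage_in``, the rest
    ``damage_out``.  Used to test tear-angle and ROI extraction with a known
    answer.
    """
    if not -90.0 <= band_angle_deg <= 90.0:
        raise ValueError("band angle must lie in [-90, 90] degrees")
    cents = mesh.centroids()
    lo, hi = mesh.nodes.min(axis=0), mesh.nodes.max(axis=0)
    center = 0.5 * (lo + hi)
    th = np.radians(band_angle_deg)
    # signed distance to the band line in the x-y plane
    n = np.array([-np.sin(th), np.cos(th)])
    d = (cents[:, :2] - center[:2]) @ n
    inside = np.abs(d) <= 0.5 * band_width
    if not np.any(inside):
        raise ValueError("band does not intersect the mesh")
    out = np.full(mesh.n_elems, damage_out)
    out[inside] = damage_in
    return out
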