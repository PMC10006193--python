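"""Homogeneous uniaxial-stress tensile test of the damage material.

Drives the constitutive model along a prescribed axial stretch path (loading
along y), solving for the two lateral stretches that null the lateral Cauchy
stresses at every step.  The two lateral stretches are independent because the
fiber direction breaks transverse isotropy about the load axis when loading
transverse to the fibers.  Damage is updated once per converged equilibrium
step from the history maximum of the criterion; a step is sub-divided when the
damage increment exceeds ``max_dD_per_step`` to stabilize softening.

The driver approximates the grip-to-grip response of a dogbone coupon by a
single material point; the finite element model in :mod:`meniscus_cdm.fe_model`
is the reference for coupon-level effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .constitutive import (
    Criterion,
    DamageParams,
    DamageState,
    DeformationState,
    MaterialParams,
    apply_damage,
    cauchy_stress_undamaged,
    damage_criterion,
    update_damage_state,
)

__all__ = [
    "Geometry",
    "TensileCurve",
    "UniaxialSolution",
    "simulate_uniaxial",
    "curve_from_solution",
    "locate_uts",
    "fiber_direction",
]

LOAD_AXIS = 1  # y


def fiber_direction(orientation: str) -> tuple[float, float, float]:
    """Reference fiber direction for a loading orientation.

    Longitudinal coupons are punched along the preferred fiber direction
    (fibers along the load axis y); transverse coupons normal to it (fibers
    along the in-plane width axis x).
    """
    if orientation == "longitudinal":
        return (0.0, 1.0, 0.0)
    if orientation == "transverse":
        return (1.0, 0.0, 0.0)
    raise ValueError(f"unknown orientation {orientation!r}")


@dataclass(frozen=True)
class Geometry:
    """Reference coupon geometry entering force/stress conversions."""

    gauge_length: float  # mm, grip-to-grip
    cross_section_area: float  # mm^2


@dataclass
class TensileCurve:
    """Grip-to-grip stretch vs. axial force with geometry metadata."""

    stretch: np.ndarray
    force: np.ndarray
    orientation: str
    gauge_length: float
    cross_section_area: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.stretch = np.asarray(self.stretch, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.stretch.shape != self.force.shape or self.stretch.ndim != 1:
            raise ValueError("stretch and force must be equal-length 1-D arrays")
        if np.any(np.diff(self.stretch) <= 0.0):
            raise ValueError("stretch must be strictly increasing")
        if abs(self.force[0]) > 1e-6 + 1e-3 * np.max(np.abs(self.force)):
            raise ValueError("force must start at zero")

    @property
    def stress(self) -> np.ndarray:
        """Nominal stress (MPa): force over reference cross-section."""
        return self.force / self.cross_section_area

    @property
    def strain(self) -> np.ndarray:
        """Grip-to-grip engineering strain (stretch - 1)."""
        return self.stretch - 1.0


@dataclass
class UniaxialSolution:
    """Per-step state of a uniaxial-stress simulation."""

    stretch: np.ndarray           # axial stretch
    lateral: np.ndarray           # (n, 2) lateral stretches (x, z)
    cauchy_stress: np.ndarray     # damaged axial Cauchy stress (MPa)
    nominal_stress: np.ndarray    # damaged axial nominal stress (MPa)
    damage: np.ndarray            # D
    xi: np.ndarray                # criterion trace
    J: np.ndarray                 # volume ratio
    orientation: str
    terminated_early: bool = False

    @property
    def converged_through(self) -> float:
        return float(self.stretch[-1])


def _uniaxial_F(lam_y: float, lat: np.ndarray) -> np.ndarray:
    return np.diag([lat[0], lam_y, lat[1]])


def _solve_laterals(lam_y, lat0, a0, params, tol=1e-8, max_iter=60):
    """Newton solve of the zero-lateral-Cauchy-stress conditions.

    The residual and its central-difference Jacobian come from one batched
    stress evaluation of five diagonal deformation gradients per iteration.
    """
    from .constitutive import stress_batch  # local import avoids cycle at init

    lat = np.asarray(lat0, dtype=float).copy()
    a0b = np.tile(a0, (5, 1))
    st = s = None
    for _ in range(max_iter):
        hx = 1e-7 * max(1.0, abs(lat[0]))
        hz = 1e-7 * max(1.0, abs(lat[1]))
        F = np.zeros((5, 3, 3))
        F[:, 0, 0] = lat[0] + np.array([0.0, hx, -hx, 0.0, 0.0])
        F[:, 1, 1] = lam_y
        F[:, 2, 2] = lat[1] + np.array([0.0, 0.0, 0.0, hz, -hz])
        sig = stress_batch(F, a0b, params)
        s = sig[0]
        r = np.array([s[0, 0], s[2, 2]])
        if np.max(np.abs(r)) < tol:
            st = DeformationState.from_F(F[0], a0)
            return lat, st, s, True
        Jm = np.array([
            [(sig[1, 0, 0] - sig[2, 0, 0]) / (2 * hx),
             (sig[3, 0, 0] - sig[4, 0, 0]) / (2 * hz)],
            [(sig[1, 2, 2] - sig[2, 2, 2]) / (2 * hx),
             (sig[3, 2, 2] - sig[4, 2, 2]) / (2 * hz)],
        ])
        try:
            step = np.linalg.solve(Jm, r)
        except np.linalg.LinAlgError:
            break
        # damped update, keep stretches positive
        scale = 1.0
        while np.any(lat - scale * step <= 0.05):
            scale *= 0.5
            if scale < 1e-6:
                break
        lat = lat - scale * step
    st = DeformationState.from_F(_uniaxial_F(lam_y, lat), a0)
    s = cauchy_stress_undamaged(st, params)
    r = np.array([s[0, 0], s[2, 2]])
    return lat, st, s, bool(np.max(np.abs(r)) < tol)


def simulate_uniaxial(params: MaterialParams, dp: DamageParams | None,
                      orientation: str, stretch_grid: Sequence[float],
                      max_dD_per_step: float = 0.05) -> UniaxialSolution:
    """Simulate a displacement-driven uniaxial-stress test.

    ``dp=None`` disables damage.  Returns a partial solution with
    ``terminated_early=True`` if the lateral Newton solve fails after step
    cutbacks (the analogue of premature model termination in the FE solver).
    """
    grid = np.asarray(stretch_grid, dtype=float)
    if grid[0] < 1.0 - 1e-12 or np.any(np.diff(grid) <= 0):
        raise ValueError("stretch_grid must increase from 1")
    a0 = np.asarray(fiber_direction(orientation), dtype=float)
    params = params.with_fiber(a0)

    rows = {k: [] for k in ("stretch", "lat", "cauchy", "nominal", "D", "xi", "J")}
    dstate = DamageState()
    lat = np.array([1.0, 1.0])
    terminated = False

    def record(lam_y, lat, st, s0, dstate):
        s = apply_damage(s0, dstate.D)
        rows["stretch"].append(lam_y)
        rows["lat"].append(lat.copy())
        rows["cauchy"].append(s[LOAD_AXIS, LOAD_AXIS])
        # nominal = J sigma F^{-T} along load axis = sigma_yy * lat_x * lat_z
        rows["nominal"].append(s[LOAD_AXIS, LOAD_AXIS] * lat[0] * lat[1])
        rows["D"].append(dstate.D)
        rows["xi"].append(dstate.xi_max)
        rows["J"].append(st.J)

    prev_lam = grid[0]
    if abs(prev_lam - 1.0) < 1e-12:
        st = DeformationState.from_F(np.eye(3), a0)
        record(1.0, lat, st, np.zeros((3, 3)), dstate)
        targets = grid[1:]
    else:
        targets = grid

    for lam_target in targets:
        if terminated:
            break
        lam = prev_lam
        dlam = lam_target - prev_lam
        cutbacks = 0
        while lam < lam_target - 1e-14:
            lam_try = min(lam + dlam, lam_target)
            lat_try, st, s0, ok = _solve_laterals(lam_try, lat, a0, params)
            if ok and dp is not None:
                xi = damage_criterion(st, s0, dp.criterion)
                d_new = update_damage_state(dstate, xi, dp)
                if d_new.D - dstate.D > max_dD_per_step and dlam > 1e-6:
                    ok = False  # force a cutback to limit the damage increment
            if not ok:
                dlam *= 0.5
                cutbacks += 1
                if cutbacks > 25:
                    terminated = True
                    break
                continue
            lam = lam_try
            lat = lat_try
            if dp is not None:
                dstate = d_new
            last = (lam, lat, st, s0)
        if not terminated:
            record(*last, dstate)
            prev_lam = lam_target

    return UniaxialSolution(
        stretch=np.array(rows["stretch"]),
        lateral=np.array(rows["lat"]),
        cauchy_stress=np.array(rows["cauchy"]),
        nominal_stress=np.array(rows["nominal"]),
        damage=np.array(rows["D"]),
        xi=np.array(rows["xi"]),
        J=np.array(rows["J"]),
        orientation=orientation,
        terminated_early=terminated,
    )


def curve_from_solution(sol: UniaxialSolution, geometry: Geometry) -> TensileCurve:
    """Convert a uniaxial solution to a force-stretch curve.

    Force is the nominal axial stress times the reference cross-section area;
    stretch is copied from the simulation grid.
    """
    return TensileCurve(
        stretch=sol.stretch.copy(),
        force=sol.nominal_stress * geometry.cross_section_area,
        orientation=sol.orientation,
        gauge_length=geometry.gauge_length,
        cross_section_area=geometry.cross_section_area,
    )


class UTSPoint(NamedTuple):
    force: float
    stretch: float
    index: int
    at_end: bool  # True when the curve is monotone with no interior maximum


def locate_uts(curve: TensileCurve) -> UTSPoint:
    """Ultimate tensile point: global force maximum, earliest on ties."""
    if len(curve.force) < 3:
        raise ValueError("curve needs at least 3 points")
    i = int(np.argmax(curve.force))  # argmax returns the first maximum
    return UTSPoint(force=float(curve.force[i]), stretch=float(curve.stretch[i]),
                    index=i, at_end=i == len(curve.force) - 1)
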