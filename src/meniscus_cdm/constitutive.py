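"""Transversely isotropic hyperelastic material with scalar continuum damage.

The strain energy density is uncoupled into a deviatoric part and a volumetric
penalty,

    psi = F1(I1~, I2~) + F2(lam~) + K/2 (ln J)^2,

where I1~, I2~ are invariants of the deviatoric right Cauchy-Green tensor
C~ = J^(-2/3) F^T F, lam~ is the deviatoric stretch along the reference fiber
direction and J = det F.  The ground substance follows a Veronda-Westmann
form,

    F1 = C1 (exp(C2 (I1~ - 3)) - 1) - C1 C2 / 2 (I2~ - 3),

and the fiber network a piecewise exponential-linear law specified through its
stretch-scaled derivative,

    lam~ dF2/dlam~ = 0                               lam~ <= 1
                   = C3 (exp(C4 (lam~ - 1)) - 1)     1 < lam~ < lam_m
                   = C5 lam~ + C6                    lam~ >= lam_m,

with C6 fixed by stress continuity at the toe-to-linear transition stretch
lam_m.  Fibers carry load in tension only.

Damage is an isotropic scalar D in [0, D_max) driven by the historical maximum
of a damage criterion Xi (von Mises stress of the undamaged Cauchy stress, or
the maximum principal Lagrange strain) through a quintic smoothstep cumulative
distribution between the thresholds mu_min and mu_max.  The damaged Cauchy
stress is sigma = (1 - D) sigma_0.

Units are fixed package-wide: MPa for stress and moduli, mm for length, N for
force; stretches and strains are dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
from scipy.special import expi

__all__ = [
    "Criterion",
    "MaterialParams",
    "DamageParams",
    "DeformationState",
    "DamageState",
    "compute_C6",
    "strain_energy",
    "cauchy_stress_undamaged",
    "damage_criterion",
    "damage_cdf",
    "apply_damage",
    "update_damage_state",
]

_I3 = np.eye(3)


class Criterion(str, Enum):
    """Damage criterion choice."""

    VON_MISES = "von_mises"
    MAX_NORMAL_STRAIN = "max_normal_strain"


def compute_C6(C3: float, C4: float, C5: float, lambda_m: float) -> float:
    """Linear-branch offset making the fiber stress continuous at ``lambda_m``.

    Equates the exponential toe branch and the linear branch of the fiber law
    at the transition stretch:

        C6 = C3 (exp(C4 (lam_m - 1)) - 1) - C5 lam_m
    """
    if lambda_m <= 1.0:
        raise ValueError(f"lambda_m must exceed 1, got {lambda_m}")
    return C3 * (np.exp(C4 * (lambda_m - 1.0)) - 1.0) - C5 * lambda_m


@dataclass(frozen=True)
class MaterialParams:
    """Elastic constants of the transversely isotropic hyperelastic material.

    Attributes
    ----------
    C1, C2 : Veronda-Westmann ground-substance coefficients (C1 in MPa).
    C3, C4 : fiber toe-region coefficients (C3 in MPa).
    C5 : fiber modulus in the linear region (MPa).
    lambda_m : toe-to-linear transition fiber stretch (> 1).
    K : bulk modulus penalty enforcing near-incompressibility (MPa).
    fiber_dir : unit reference fiber direction.

    ``C6`` is always derived from stress continuity at ``lambda_m`` and never
    supplied by the user.
    """

    C1: float
    C2: float
    C3: float
    C4: float
    C5: float
    lambda_m: float
    K: float = 1000.0
    fiber_dir: tuple[float, float, float] = (0.0, 1.0, 0.0)

    def __post_init__(self) -> None:
        for name in ("C1", "C3", "C5", "K"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be non-negative")
        if self.C4 < 0.0:
            raise ValueError("C4 must be non-negative")
        if self.lambda_m <= 1.0:
            raise ValueError("lambda_m must exceed 1")
        a = np.asarray(self.fiber_dir, dtype=float)
        n = float(np.linalg.norm(a))
        if not np.isfinite(n) or n == 0.0:
            raise ValueError("fiber_dir must be a nonzero vector")
        object.__setattr__(self, "fiber_dir", tuple(a / n))

    @property
    def C6(self) -> float:
        return compute_C6(self.C3, self.C4, self.C5, self.lambda_m)

    def with_fiber(self, fiber_dir) -> "MaterialParams":
        return replace(self, fiber_dir=tuple(np.asarray(fiber_dir, float)))


@dataclass(frozen=True)
class DamageParams:
    """Damage evolution parameters for one constituent-orientation group.

    ``mu_min``/``mu_max`` carry the units of the criterion: MPa for the von
    Mises stress criterion, dimensionless strain for maximum normal strain.
    """

    criterion: Criterion
    mu_min: float
    mu_max: float
    D_max: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "criterion", Criterion(self.criterion))
        if self.mu_min < 0.0:
            raise ValueError("mu_min must be non-negative")
        if self.mu_max <= self.mu_min:
            raise ValueError("mu_max must exceed mu_min")
        if not (0.0 <= self.D_max < 1.0):
            raise ValueError("D_max must lie in [0, 1)")


@dataclass(frozen=True)
class DeformationState:
    """Deformation gradient with the derived kinematic quantities.

    ``C_tilde`` is the deviatoric right Cauchy-Green tensor (unit
    determinant), ``lambda_tilde`` the deviatoric fiber stretch and ``E`` the
    (total) Lagrange strain (F^T F - I)/2.
    """

    F: np.ndarray
    J: float
    C_tilde: np.ndarray
    I1_tilde: float
    I2_tilde: float
    lambda_tilde: float
    E: np.ndarray
    fiber_dir: np.ndarray

    @classmethod
    def from_F(cls, F, fiber_dir) -> "DeformationState":
        F = np.asarray(F, dtype=float)
        if F.shape != (3, 3):
            raise ValueError("F must be 3x3")
        J = float(np.linalg.det(F))
        if J <= 0.0:
            raise ValueError(f"non-positive volume ratio J={J}")
        a0 = np.asarray(fiber_dir, dtype=float)
        a0 = a0 / np.linalg.norm(a0)
        C = F.T @ F
        Ct = J ** (-2.0 / 3.0) * C
        I1 = float(np.trace(Ct))
        I2 = 0.5 * (I1 * I1 - float(np.trace(Ct @ Ct)))
        lam = float(np.sqrt(a0 @ Ct @ a0))
        E = 0.5 * (C - _I3)
        return cls(F=F, J=J, C_tilde=Ct, I1_tilde=I1, I2_tilde=I2,
                   lambda_tilde=lam, E=E, fiber_dir=a0)


@dataclass(frozen=True)
class DamageState:
    """History variable: running maximum of the criterion and current damage."""

    xi_max: float = 0.0
    D: float = 0.0


# ---------------------------------------------------------------------------
# batched kernels (used by the scalar API, the uniaxial driver and the FE
# assembly; all accept F of shape (n, 3, 3) and a0 of shape (n, 3))
# ---------------------------------------------------------------------------

def fiber_tension_batch(lam: np.ndarray, p: MaterialParams) -> np.ndarray:
    """lam~ dF2/dlam~ of the piecewise fiber law (tension only)."""
    lam = np.asarray(lam, dtype=float)
    out = np.zeros_like(lam)
    toe = (lam > 1.0) & (lam < p.lambda_m)
    lin = lam >= p.lambda_m
    if np.any(toe):
        out[toe] = p.C3 * (np.exp(p.C4 * (lam[toe] - 1.0)) - 1.0)
    if np.any(lin):
        out[lin] = p.C5 * lam[lin] + p.C6
    return out


def fiber_energy_batch(lam: np.ndarray, p: MaterialParams) -> np.ndarray:
    """F2(lam~): antiderivative of the fiber law with F2(1) = 0, C1 at lam_m.

    The toe branch integrates in closed form through the exponential integral:
    int C3 (e^{C4 (t-1)} - 1) / t dt = C3 [e^{-C4} Ei(C4 t) - ln t].
    """
    lam = np.asarray(lam, dtype=float)
    out = np.zeros_like(lam)
    if p.C3 == 0.0 and p.C5 == 0.0:
        return out

    def toe_int(x):
        # antiderivative of the toe branch over stretch, from 1 to x
        return p.C3 * (np.exp(-p.C4) * (expi(p.C4 * x) - expi(p.C4)) - np.log(x))

    toe = (lam > 1.0) & (lam < p.lambda_m)
    lin = lam >= p.lambda_m
    if np.any(toe):
        out[toe] = toe_int(lam[toe])
    if np.any(lin):
        F2m = toe_int(p.lambda_m)
        x = lam[lin]
        out[lin] = F2m + p.C5 * (x - p.lambda_m) + p.C6 * np.log(x / p.lambda_m)
    return out


def energy_batch(F: np.ndarray, a0: np.ndarray, p: MaterialParams) -> np.ndarray:
    """Strain energy density (MPa) for a batch of deformation gradients."""
    F = np.asarray(F, dtype=float)
    J = np.linalg.det(F)
    if np.any(J <= 0.0):
        raise ValueError("non-positive volume ratio in batch")
    C = np.einsum("nji,njk->nik", F, F)
    Ct = J[:, None, None] ** (-2.0 / 3.0) * C
    I1 = np.trace(Ct, axis1=1, axis2=2)
    I2 = 0.5 * (I1 * I1 - np.einsum("nij,nji->n", Ct, Ct))
    lam = np.sqrt(np.einsum("ni,nij,nj->n", a0, Ct, a0))
    F1 = p.C1 * (np.exp(p.C2 * (I1 - 3.0)) - 1.0) - 0.5 * p.C1 * p.C2 * (I2 - 3.0)
    return F1 + fiber_energy_batch(lam, p) + 0.5 * p.K * np.log(J) ** 2


def stress_batch(F: np.ndarray, a0: np.ndarray, p: MaterialParams) -> np.ndarray:
    """Undamaged Cauchy stress (n,3,3) for a batch of deformation gradients.

    Deviatoric push-forward of the isochoric energy derivatives plus the
    volumetric pressure K ln(J)/J.
    """
    F = np.asarray(F, dtype=float)
    n = F.shape[0]
    J = np.linalg.det(F)
    if np.any(J <= 0.0):
        raise ValueError("non-positive volume ratio in batch")
    Jm13 = J ** (-1.0 / 3.0)
    Fb = Jm13[:, None, None] * F
    bb = np.einsum("nij,nkj->nik", Fb, Fb)          # deviatoric left CG
    I1 = np.trace(bb, axis1=1, axis2=2)
    # ground substance: W1 = dF1/dI1, W2 = dF1/dI2
    W1 = p.C1 * p.C2 * np.exp(p.C2 * (I1 - 3.0))
    W2 = np.full(n, -0.5 * p.C1 * p.C2)
    bb2 = np.einsum("nij,njk->nik", bb, bb)
    iso = 2.0 * ((W1 + I1 * W2)[:, None, None] * bb - W2[:, None, None] * bb2)
    # fiber: lam~ dF2/dlam~ along the deformed (unit) fiber direction
    fa = np.einsum("nij,nj->ni", Fb, a0)            # F~ a0, magnitude lam~
    lam = np.linalg.norm(fa, axis=1)
    w = fiber_tension_batch(lam, p)
    with np.errstate(invalid="ignore", divide="ignore"):
        ahat = fa / lam[:, None]
    ahat = np.where(lam[:, None] > 0, ahat, 0.0)
    iso = iso + w[:, None, None] * np.einsum("ni,nj->nij", ahat, ahat)
    # deviatoric projection and volumetric pressure
    tr = np.trace(iso, axis1=1, axis2=2)
    sig = (iso - (tr / 3.0)[:, None, None] * _I3) / J[:, None, None]
    sig = sig + (p.K * np.log(J) / J)[:, None, None] * _I3
    return sig


# ---------------------------------------------------------------------------
# scalar operations
# ---------------------------------------------------------------------------

def strain_energy(state: DeformationState, params: MaterialParams) -> float:
    """Strain energy density psi (MPa) at a deformation state."""
    return float(energy_batch(state.F[None], state.fiber_dir[None], params)[0])


def cauchy_stress_undamaged(state: DeformationState,
                            params: MaterialParams) -> np.ndarray:
    """Effective undamaged Cauchy stress sigma_0 (3x3 symmetric, MPa)."""
    return stress_batch(state.F[None], state.fiber_dir[None], params)[0]


def von_mises(sigma: np.ndarray) -> float:
    """von Mises equivalent stress sqrt(3/2 s:s) of the deviator s."""
    s = sigma - np.trace(sigma) / 3.0 * _I3
    return float(np.sqrt(1.5 * np.sum(s * s)))


def damage_criterion(state: DeformationState, sigma0: np.ndarray,
                     which: Criterion | str) -> float:
    """Evaluate the damage criterion Xi.

    ``von_mises``: equivalent stress of the deviator of the undamaged Cauchy
    stress (MPa).  ``max_normal_strain``: largest principal value of the total
    Lagrange strain (dimensionless).
    """
    which = Criterion(which)
    if which is Criterion.VON_MISES:
        return von_mises(np.asarray(sigma0, float))
    return float(np.max(np.linalg.eigvalsh(state.E)))


def damage_cdf(xi_max: float, dp: DamageParams):
    """Damage D as a quintic-smoothstep CDF of the criterion maximum.

    D = 0 below ``mu_min``, ``D_max`` above ``mu_max``, and in between
    D = D_max x^3 (6 x^2 - 15 x + 10) with x the normalized exceedance,
    which is continuous with zero slope at both thresholds.
    """
    xi = np.asarray(xi_max, dtype=float)
    x = np.clip((xi - dp.mu_min) / (dp.mu_max - dp.mu_min), 0.0, 1.0)
    D = dp.D_max * x ** 3 * (6.0 * x * x - 15.0 * x + 10.0)
    return float(D) if np.isscalar(xi_max) else D


def apply_damage(sigma0: np.ndarray, D: float) -> np.ndarray:
    """Damaged Cauchy stress sigma = (1 - D) sigma_0."""
    if not (0.0 <= D < 1.0):
        raise ValueError(f"damage D={D} outside [0, 1)")
    return (1.0 - D) * np.asarray(sigma0, float)


def update_damage_state(prev: DamageState, xi_now: float,
                        dp: DamageParams) -> DamageState:
    """Irreversible update: damage follows the history maximum of Xi."""
    xi = max(prev.xi_max, float(xi_now))
    return DamageState(xi_max=xi, D=damage_cdf(xi, dp))


# Fitted elastic parameter averages (MPa where dimensional) used as default
# initial guesses and for the reference tear-pattern simulations.
AVERAGE_ELASTIC = MaterialParams(C1=0.78, C2=1.20, C3=0.43, C4=40.83,
                                 C5=119.63, lambda_m=1.048, K=1000.0)

# Average damage parameters per orientation and criterion (von Mises values
# in MPa, max-normal-strain values dimensionless).
AVERAGE_DAMAGE: dict[tuple[str, str], DamageParams] = {
    ("longitudinal", "von_mises"): DamageParams(Criterion.VON_MISES, 8.83, 43.66, 0.58),
    ("longitudinal", "max_normal_strain"): DamageParams(Criterion.MAX_NORMAL_STRAIN, 0.18, 0.48, 0.61),
    ("transverse", "von_mises"): DamageParams(Criterion.VON_MISES, 0.19, 2.20, 0.65),
    ("transverse", "max_normal_strain"): DamageParams(Criterion.MAX_NORMAL_STRAIN, 0.12, 1.18, 0.73),
}
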