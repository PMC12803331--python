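"""Constitutive models for the vessel wall, patch and crimping tube.

The right ventricular outflow tract (RVOT) wall is modeled with the uncoupled
Holzapfel--Gasser--Ogden (HGO) law: an isotropic neo-Hookean ground matrix
reinforced by two symmetric families of dispersed collagen fibers, plus a
volumetric penalty.  All stresses are Cauchy stresses in kPa; lengths are mm
and densities kg/mm^3 throughout the package.

The local material frame is (circumferential, axial, radial).  Fiber family
reference directions are ``a0 = (cos g, +/- sin g, 0)`` where ``g`` is the
mean fiber angle measured from the circumferential direction in the tangent
plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HGOParams",
    "IsotropicElastic",
    "KinematicState",
    "RVOT_BASELINE",
    "TUBE_MATERIAL",
    "PATCH_STIFFNESS_CONDITIONS",
    "STENT_BEAM_METADATA",
    "kinematics",
    "strain_energy",
    "cauchy_stress",
    "isotropic_strain_energy",
    "isotropic_stress",
    "plane_strain_dev_stress",
]

_I3 = np.eye(3)


class InvalidDeformationError(ValueError):
    """Raised when det F <= 0 or a material precondition is violated."""


class EnergyOverflowError(FloatingPointError):
    """Raised when the fiber exponential overflows; names the offending strain."""


@dataclass(frozen=True)
class HGOParams:
    """The five uncertain HGO coefficients plus bulk modulus and density.

    Parameters
    ----------
    c : float
        Ground-matrix shear modulus (kPa).
    k1 : float
        Fiber modulus (kPa).
    k2 : float
        Dimensionless fiber exponential coefficient.
    gamma_deg : float
        Mean fiber orientation angle from the circumferential direction (deg).
    kappa : float
        Fiber dispersion, 0 (perfectly aligned) to 1/3 (isotropic).
    k_bulk : float
        Bulk modulus of the volumetric penalty (kPa).
    rho : float
        Mass density (kg/mm^3); carried for provenance, inertia is not modeled.
    """

    c: float
    k1: float
    k2: float
    gamma_deg: float
    kappa: float
    k_bulk: float = 1500.0
    rho: float = 1.02e-6

    def __post_init__(self) -> None:
        if not self.c > 0:
            raise ValueError(f"ground-matrix shear modulus c must be > 0, got {self.c}")
        if self.k1 < 0:
            raise ValueError(f"fiber modulus k1 must be >= 0, got {self.k1}")
        if not self.k2 > 0:
            raise ValueError(f"fiber exponential coefficient k2 must be > 0, got {self.k2}")
        if not 0.0 <= self.kappa <= 1.0 / 3.0 + 1e-12:
            raise ValueError(f"fiber dispersion kappa must lie in [0, 1/3], got {self.kappa}")
        if not 0.0 <= self.gamma_deg <= 90.0:
            raise ValueError(f"fiber angle must lie in [0, 90] deg, got {self.gamma_deg}")
        if not self.k_bulk > 0:
            raise ValueError(f"bulk modulus must be > 0, got {self.k_bulk}")

    def replace(self, **kw) -> "HGOParams":
        from dataclasses import replace as _replace

        return _replace(self, **kw)


@dataclass(frozen=True)
class IsotropicElastic:
    """Isotropic comparator material (patch, crimping tube).

    Realized as a compressible neo-Hookean solid matched to (E, nu) in the
    small-strain limit; a small-strain Hooke law would not be objective at
    deployment strains.
    """

    E: float
    nu: float
    rho: float = 1.41e-6

    def __post_init__(self) -> None:
        if not self.E > 0:
            raise ValueError(f"Young's modulus must be > 0, got {self.E}")
        if not -1.0 < self.nu < 0.5:
            raise ValueError(f"Poisson ratio must lie in (-1, 0.5), got {self.nu}")

    @property
    def mu(self) -> float:
        """Shear modulus E / (2(1+nu)) in kPa."""
        return self.E / (2.0 * (1.0 + self.nu))

    @property
    def bulk(self) -> float:
        """Bulk modulus E / (3(1-2nu)) in kPa."""
        return self.E / (3.0 * (1.0 - 2.0 * self.nu))


#: RVOT wall baseline (uncoupled HGO).
RVOT_BASELINE = HGOParams(
    c=200.0, k1=13480.0, k2=1.06, gamma_deg=18.85, kappa=0.33, k_bulk=1500.0, rho=1.02e-6
)

#: Crimping-tube neo-Hookean material (recorded; the tube itself is out of the
#: reduced-order model's scope).
TUBE_MATERIAL = IsotropicElastic(E=4.0e7, nu=0.33, rho=6.5e-6)

#: The four transannular-patch stiffness conditions (kPa); nu and rho shared.
PATCH_STIFFNESS_CONDITIONS = (1.1e3, 2.2e3, 4.4e3, 8.8e3)


def make_patch_material(E: float) -> IsotropicElastic:
    """Patch material for a given Young's modulus (nu = 0.495, rho = 1.41e-6)."""
    return IsotropicElastic(E=E, nu=0.495, rho=1.41e-6)


#: Nitinol beam-element constants of the TPV25 device, recorded verbatim as
#: metadata.  Never used in computation: the device enters the reduced-order
#: model only through its free radius profile and radial stiffness.  Note the
#: recorded cross-section area (0.111045 mm^2) differs slightly from pi*r^2 at
#: r = 0.1875 mm (0.110447 mm^2); it is kept as recorded.
STENT_BEAM_METADATA = {
    "beam_diameter_mm": 0.375,
    "E_kPa": 4.0e7,
    "G_kPa": 1.5e7,
    "A_mm2": 0.111045,
    "I_mm4": 0.000970722,
    "rho_kg_per_mm3": 6.5e-6,
}


@dataclass(frozen=True)
class KinematicState:
    """Deviatoric kinematics entering the HGO energy.

    ``C_bar = J^(-2/3) F^T F`` is the deviatoric right Cauchy-Green tensor,
    ``I1_bar = tr C_bar``, ``I4_bar[a] = a0[a] . C_bar . a0[a]`` and the fiber
    strain is ``E_fiber[a] = kappa (I1_bar - 3) + (1 - 3 kappa)(I4_bar[a] - 1)``
    (the kappa-weighting is applied lazily by the energy/stress routines since
    kappa is a material parameter, not a kinematic one; this class stores the
    two building blocks).
    """

    F: np.ndarray
    J: float
    C_bar: np.ndarray
    I1_bar: float
    a0: np.ndarray  # (2, 3) fiber reference directions
    I4_bar: np.ndarray  # (2,)

    def fiber_strain(self, kappa: float) -> np.ndarray:
        """E_fiber for both families at dispersion kappa."""
        return kappa * (self.I1_bar - 3.0) + (1.0 - 3.0 * kappa) * (self.I4_bar - 1.0)


def fiber_directions(gamma_deg: float) -> np.ndarray:
    """Two fiber families at +/- gamma from circumferential, in-plane.

    Rows are unit vectors in the (circumferential, axial, radial) frame.
    """
    g = math.radians(gamma_deg)
    return np.array(
        [
            [math.cos(g), math.sin(g), 0.0],
            [math.cos(g), -math.sin(g), 0.0],
        ]
    )


def kinematics(F: np.ndarray, gamma_deg: float) -> KinematicState:
    """Compute the deviatoric invariants of a deformation gradient.

    Raises
    ------
    InvalidDeformationError
        If det F <= 0.
    """
    F = np.asarray(F, dtype=float)
    if F.shape != (3, 3):
        raise ValueError(f"F must be 3x3, got shape {F.shape}")
    J = float(np.linalg.det(F))
    if J <= 0.0:
        raise InvalidDeformationError(f"det F = {J:g} <= 0: not a valid deformation")
    C = F.T @ F
    C_bar = J ** (-2.0 / 3.0) * C
    a0 = fiber_directions(gamma_deg)
    I4 = np.einsum("ai,ij,aj->a", a0, C_bar, a0)
    return KinematicState(
        F=F, J=J, C_bar=C_bar, I1_bar=float(np.trace(C_bar)), a0=a0, I4_bar=I4
    )


def _volumetric_energy(J: float, k_bulk: float) -> float:
    # U(J) = (k/2)[(J^2-1)/2 - ln J]; U(1)=0, U'(1)=0, U''(1)=k.
    return 0.5 * k_bulk * (0.5 * (J * J - 1.0) - math.log(J))


def _volumetric_pressure(J: float, k_bulk: float) -> float:
    # U'(J) = (k/2)(J - 1/J)
    return 0.5 * k_bulk * (J - 1.0 / J)


_EXP_ARG_MAX = 700.0  # beyond this exp() overflows a float64


def strain_energy(state: KinematicState, p: HGOParams, tension_only: bool = True) -> float:
    """HGO strain-energy density (kPa).

    ``Psi = (c/2)(I1_bar - 3) + (k1/(2 k2)) sum_a [exp(k2 <E_a>^2) - 1] + U(J)``
    where ``<.>`` keeps only tensile fiber strains when ``tension_only`` (the
    standard HGO convention: compressed fibers carry no load).
    """
    psi = 0.5 * p.c * (state.I1_bar - 3.0) + _volumetric_energy(state.J, p.k_bulk)
    if p.k1 > 0.0:
        E = state.fiber_strain(p.kappa)
        for a, Ea in enumerate(E):
            if tension_only and Ea <= 0.0:
                continue
            arg = p.k2 * Ea * Ea
            if arg > _EXP_ARG_MAX:
                raise EnergyOverflowError(
                    f"fiber family {a + 1}: exp overflow at fiber strain E={Ea:g}"
                )
            psi += p.k1 / (2.0 * p.k2) * (math.exp(arg) - 1.0)
    return psi


def _dev(sig: np.ndarray) -> np.ndarray:
    return sig - np.trace(sig) / 3.0 * _I3


def cauchy_stress(state: KinematicState, p: HGOParams, tension_only: bool = True) -> np.ndarray:
    """Cauchy stress (kPa) of the uncoupled HGO law.

    Standard uncoupled push-forward: with ``S_bar = 2 dPsi_dev/dC_bar`` and
    ``F_bar = J^(-1/3) F``,

        sigma = dev(F_bar S_bar F_bar^T) / J + U'(J) I.
    """
    # S_bar = c I + sum_a 2 k1 E_a exp(k2 E_a^2) (kappa I + (1-3kappa) a0 x a0)
    S_bar = p.c * _I3.copy()
    if p.k1 > 0.0:
        E = state.fiber_strain(p.kappa)
        for a, Ea in enumerate(E):
            if tension_only and Ea <= 0.0:
                continue
            arg = p.k2 * Ea * Ea
            if arg > _EXP_ARG_MAX:
                raise EnergyOverflowError(
                    f"fiber family {a + 1}: exp overflow at fiber strain E={Ea:g}"
                )
            w = 2.0 * p.k1 * Ea * math.exp(arg)
            S_bar += w * (
                p.kappa * _I3 + (1.0 - 3.0 * p.kappa) * np.outer(state.a0[a], state.a0[a])
            )
    F_bar = state.J ** (-1.0 / 3.0) * state.F
    tau_bar = F_bar @ S_bar @ F_bar.T
    sig = _dev(tau_bar) / state.J + _volumetric_pressure(state.J, p.k_bulk) * _I3
    return 0.5 * (sig + sig.T)  # symmetrize away roundoff


def isotropic_strain_energy(F: np.ndarray, m: IsotropicElastic) -> float:
    """Compressible neo-Hookean energy density matched to (E, nu) (kPa)."""
    st = kinematics(F, 0.0)
    return 0.5 * m.mu * (st.I1_bar - 3.0) + _volumetric_energy(st.J, m.bulk)


def isotropic_stress(F: np.ndarray, m: IsotropicElastic) -> np.ndarray:
    """Cauchy stress of the compressible neo-Hookean comparator (kPa).

    Reduces to linear elasticity with modulus E and Poisson ratio nu for
    infinitesimal strains.
    """
    F = np.asarray(F, dtype=float)
    J = float(np.linalg.det(F))
    if J <= 0.0:
        raise InvalidDeformationError(f"det F = {J:g} <= 0")
    B_bar = J ** (-2.0 / 3.0) * (F @ F.T)
    sig = m.mu / J * _dev(B_bar) + _volumetric_pressure(J, m.bulk) * _I3
    return 0.5 * (sig + sig.T)


# ---------------------------------------------------------------------------
# Fast diagonal plane-strain path used by the ring solver.
# ---------------------------------------------------------------------------

def plane_strain_dev_stress(
    material, lam_theta: np.ndarray, tension_only: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deviatoric Cauchy stress differences on the incompressible plane-strain path.

    For ``F = diag(lam_theta, 1, 1/lam_theta)`` in the (circumferential, axial,
    radial) frame with J = 1, returns the three deviatoric diagonal components
    ``(sigma_tt_dev, sigma_zz_dev, sigma_rr_dev)`` as arrays over the input
    stretches.  Pressure-free: differences such as ``sigma_tt - sigma_rr`` are
    complete Cauchy-stress differences.

    Vectorized closed form; the general-tensor :func:`cauchy_stress` is the
    cross-check in the tests.
    """
    lt = np.asarray(lam_theta, dtype=float)
    lt2 = lt * lt
    inv_lt2 = 1.0 / lt2
    I1 = lt2 + 1.0 + inv_lt2

    if isinstance(material, IsotropicElastic):
        mu = material.mu
        # sigma_dev = mu * dev(B), B = diag(lt2, 1, 1/lt2)
        tr = I1 / 3.0
        return mu * (lt2 - tr), mu * (1.0 - tr), mu * (inv_lt2 - tr)

    p: HGOParams = material
    # tau_bar = F S_bar F^T is diagonal for diagonal F and in-plane fibers.
    tau_t = p.c * lt2
    tau_z = p.c * np.ones_like(lt)
    tau_r = p.c * inv_lt2
    if p.k1 > 0.0:
        g = math.radians(p.gamma_deg)
        cg2, sg2 = math.cos(g) ** 2, math.sin(g) ** 2
        I4 = lt2 * cg2 + sg2  # same for both +/- gamma families
        E = p.kappa * (I1 - 3.0) + (1.0 - 3.0 * p.kappa) * (I4 - 1.0)
        act = E > 0.0 if tension_only else np.ones_like(E, dtype=bool)
        arg = p.k2 * E * E
        if np.any(arg[act] > _EXP_ARG_MAX):
            raise EnergyOverflowError("fiber exp overflow on plane-strain path")
        w = np.where(act, 2.0 * p.k1 * E * np.exp(np.minimum(arg, _EXP_ARG_MAX)), 0.0)
        # both families contribute identically to the diagonal
        tau_t = tau_t + 2.0 * w * (p.kappa + (1.0 - 3.0 * p.kappa) * cg2) * lt2
        tau_z = tau_z + 2.0 * w * (p.kappa + (1.0 - 3.0 * p.kappa) * sg2)
        tau_r = tau_r + 2.0 * w * p.kappa * inv_lt2
    tr = (tau_t + tau_z + tau_r) / 3.0
    return tau_t - tr, tau_z - tr, tau_r - tr
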