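"""Fibril-reinforced poroviscoelastic swelling material model for cartilage.

Material-point implementation of the constitutive model used by the impact
solver: a compressible Neo-Hookean non-fibrillar matrix, tension-only
viscoelastic collagen fibrils (primary Benninghoff arcades + an isotropic
secondary set), strain-dependent Darcy permeability, Donnan osmotic swelling
driven by the fixed charge density (FCD) of the proteoglycans, and a chemical
expansion stress from charge repulsion.

All quantities are SI internally: Pa, m, s, mol m^-3, K.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "InvalidDeformationError",
    "MaterialParams",
    "DepthProfile",
    "KinematicState",
    "FibrilHistory",
    "neo_hookean_stress",
    "fibril_stress_update",
    "fibril_network_stress",
    "permeability",
    "fcd_current",
    "anion_concentration",
    "donnan_pressure",
    "chemical_expansion",
    "total_stress",
    "secondary_fibril_directions",
    "primary_fibril_angle",
]

_I3 = np.eye(3)


class InvalidDeformationError(ValueError):
    """Non-physical kinematics: det(F) <= 0 or pore collapse."""


@dataclass(frozen=True)
class MaterialParams:
    """Constitutive parameters ("mature bovine" preset defaults).

    The preset values follow the fibril-reinforced poroviscoelastic swelling
    literature for mature bovine cartilage; every acceptance-relevant path is
    written against configurable inputs, not this preset.
    """

    E_nf: float = 0.9e6        # non-fibrillar matrix Young's modulus (Pa)
    nu_nf: float = 0.15        # non-fibrillar Poisson ratio (-)
    E0: float = 4.3e6          # initial fibril network modulus (Pa)
    E_eps: float = 1.5e9       # strain-dependent fibril network modulus (Pa)
    eta: float = 1.06e9        # fibril damping coefficient (Pa s)
    C: float = 3.009           # primary/secondary fibril density ratio (-)
    k0: float = 3.0e-16        # initial permeability (m^4 N^-1 s^-1)
    M: float = 5.0             # permeability strain-dependence exponent (-)
    a0: float = 4.0e2          # chemical expansion constant (Pa m^3 mol^-1)
    kappa: float = 5.0e-3      # chemical expansion exponent constant (m^3 mol^-1)
    gamma_ext: float = 0.92    # external activity coefficient (-)
    gamma_int: float = 0.90    # internal activity coefficient (-)
    phi_ext: float = 0.93      # external osmotic coefficient (-)
    phi_int: float = 0.90      # internal osmotic coefficient (-)
    R: float = 8.314           # molar gas constant (J mol^-1 K^-1)
    T: float = 310.0           # absolute temperature (K)
    c_ext: float = 150.0       # external salt concentration (mol m^-3)

    def __post_init__(self):
        if self.E_nf <= 0:
            raise ValueError("E_nf must be positive")
        if not (-1.0 < self.nu_nf < 0.5):
            raise ValueError("nu_nf must lie in (-1, 0.5)")
        if self.k0 <= 0:
            raise ValueError("k0 must be positive")
        if self.eta < 0:
            raise ValueError("eta must be nonnegative")
        if self.T <= 0 or self.c_ext <= 0:
            raise ValueError("T and c_ext must be positive")
        for name in ("gamma_ext", "gamma_int", "phi_ext", "phi_int"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1]")

    def with_(self, **kw) -> "MaterialParams":
        return replace(self, **kw)


def _interp(z, zs, vs):
    return np.interp(np.asarray(z, dtype=float), zs, vs)


@dataclass(frozen=True)
class DepthProfile:
    """Depth-varying composition on a normalized depth grid.

    ``z = 0`` is the articular surface, ``z = 1`` the deep (bone-side) limit.
    Primary fibril orientation follows the Benninghoff arcades: parallel to
    the surface at ``z = 0``, perpendicular to it (depth-aligned) at ``z = 1``.
    """

    z: np.ndarray                   # normalized depth grid in [0, 1]
    c_FCD0: np.ndarray              # initial FCD (mol m^-3 of fluid)
    n_fl0: np.ndarray               # initial fluid fraction (-)
    rho_z: np.ndarray               # collagen density fraction (-)
    arcade_surface_frac: float = 0.15   # superficial-zone fraction (surface-parallel)
    arcade_deep_frac: float = 0.45      # deep-zone fraction (depth-aligned)

    def __post_init__(self):
        z = np.asarray(self.z, float)
        for name in ("z", "c_FCD0", "n_fl0", "rho_z"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        if np.any((self.n_fl0 <= 0) | (self.n_fl0 >= 1)):
            raise ValueError("n_fl0 must lie in (0, 1) everywhere")
        if np.any(self.c_FCD0 < 0):
            raise ValueError("c_FCD0 must be nonnegative")
        if np.any(np.diff(z) <= 0) or z[0] < 0 or z[-1] > 1:
            raise ValueError("z grid must be strictly increasing within [0, 1]")

    def fcd0_at(self, z):
        return _interp(z, self.z, self.c_FCD0)

    def n_fl0_at(self, z):
        return _interp(z, self.z, self.n_fl0)

    def rho_at(self, z):
        return _interp(z, self.z, self.rho_z)


def primary_fibril_angle(z, profile: DepthProfile | None = None) -> np.ndarray:
    """Angle (rad) of the primary fibril from the surface plane at depth z.

    0 at the surface (fibrils surface-parallel) rising linearly through the
    middle zone to pi/2 (depth-aligned) in the deep zone.  The superficial /
    deep plateau fractions are taken from the profile when given.
    """
    sf = profile.arcade_surface_frac if profile is not None else 0.15
    df = profile.arcade_deep_frac if profile is not None else 0.45
    z = np.asarray(z, float)
    t = np.clip((z - sf) / max(1e-12, (1.0 - df) - sf), 0.0, 1.0)
    return t * (np.pi / 2.0)


def secondary_fibril_directions() -> np.ndarray:
    """Fixed 13-direction near-isotropic set of unit vectors (3D).

    Axes (3), face diagonals (6), and body diagonals (4): half of the
    26-neighborhood up to sign symmetry.
    """
    dirs = []
    for v in [(1, 0, 0), (0, 1, 0), (0, 0, 1),
              (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
              (1, 1, 1), (1, 1, -1), (1, -1, 1), (-1, 1, 1)]:
        a = np.array(v, float)
        dirs.append(a / np.linalg.norm(a))
    return np.array(dirs)


@dataclass
class FibrilHistory:
    """Per-fibril internal state for the viscoelastic update."""

    sigma_f: float = 0.0   # fibril stress (Pa)
    eps_f: float = 0.0     # fibril strain at the last converged step (-)


@dataclass
class KinematicState:
    """Kinematic and compositional state at a material point."""

    F: np.ndarray = field(default_factory=lambda: _I3.copy())
    c_FCD0: float = 180.0
    n_fl0: float = 0.8

    @property
    def J(self) -> float:
        J = float(np.linalg.det(self.F))
        if J <= 0:
            raise InvalidDeformationError(f"det(F) = {J} <= 0")
        return J

    @property
    def E_GL(self) -> np.ndarray:
        F = self.F
        return 0.5 * (F.T @ F - _I3)

    @property
    def e0(self) -> float:
        return self.n_fl0 / (1.0 - self.n_fl0)


def neo_hookean_stress(F: np.ndarray, params: MaterialParams) -> np.ndarray:
    """Cauchy stress of the compressible Neo-Hookean non-fibrillar matrix.

    sigma_nf = E/(3(1-2nu)) * ln(J)/J * I + E/(2(1+nu)) * (F F^T - J^(2/3) I)/J

    This is the stress derived from the stored energy
    W = K/2 (ln J)^2 + G/2 (I1 - 3 J^(2/3)) with K = E/(3(1-2nu)) and
    G = E/(2(1+nu)), which the verification tests differentiate numerically.
    """
    F = np.asarray(F, float)
    J = float(np.linalg.det(F))
    if J <= 0:
        raise InvalidDeformationError(f"det(F) = {J} <= 0")
    K = params.E_nf / (3.0 * (1.0 - 2.0 * params.nu_nf))
    G = params.E_nf / (2.0 * (1.0 + params.nu_nf))
    B = F @ F.T
    return K * np.log(J) / J * _I3 + G / J * (B - J ** (2.0 / 3.0) * _I3)


def fibril_stress_update(
    eps_f: float,
    eps_f_rate: float,
    history: FibrilHistory,
    params: MaterialParams,
    dt: float,
) -> FibrilHistory:
    """Implicit (backward-Euler) update of the viscoelastic fibril stress.

    The fibril is a linear spring E0 in parallel with a Maxwell branch whose
    spring is quadratic (sigma_s = E_eps * eps_s^2) and whose dashpot has
    viscosity eta; the branch overstress s = sigma_f - E0*eps_f then obeys

        s + eta * s_dot / (2 sqrt(E_eps s)) = eta * eps_f_rate.

    Fibrils carry no compression: eps_f < 0 gives sigma_f = 0.  The radicand
    is clamped at 1e-12 * E_eps * E0 near the elastic limit (the printed law
    is singular at s = 0).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if eps_f < 0.0:
        return FibrilHistory(sigma_f=0.0, eps_f=eps_f)
    if params.eta == 0.0:
        # purely elastic limit of the network: Maxwell branch relaxes instantly
        return FibrilHistory(sigma_f=params.E0 * eps_f, eps_f=eps_f)

    E0, E_eps, eta = params.E0, params.E_eps, params.eta
    floor = 1e-12 * E_eps * E0
    s_old = max(history.sigma_f - E0 * history.eps_f, 0.0)

    def residual(s: float) -> float:
        x = np.sqrt(max(E_eps * s, floor))
        return s + eta * (s - s_old) / (2.0 * x * dt) - eta * eps_f_rate

    # bracket the root: residual(0-) < 0 only if eps_f_rate drives loading
    lo, hi = 0.0, max(abs(eta * eps_f_rate), s_old, floor / E_eps) * 4.0 + floor
    r_lo = residual(lo)
    if r_lo >= 0.0:
        s_new = 0.0  # unloading / relaxation has reached the elastic limit
    else:
        while residual(hi) < 0.0:
            hi *= 4.0
            if hi > 1e30:
                raise RuntimeError("fibril stress update failed to bracket root")
        from scipy.optimize import brentq

        s_new = brentq(residual, lo, hi, xtol=1e-12 * max(1.0, hi), rtol=1e-12)
    return FibrilHistory(sigma_f=E0 * eps_f + s_new, eps_f=eps_f)


def fibril_network_stress(
    fibril_stresses: np.ndarray,
    directions: np.ndarray,
    rho_z: float,
    params: MaterialParams,
    n_primary: int,
) -> np.ndarray:
    """Total fibril Cauchy stress: sum of rho_z*C*sigma_f e(x)e over the first
    ``n_primary`` fibrils plus rho_z*sigma_f e(x)e over the remaining
    (secondary) ones.  Tension-only behaviour is enforced upstream (negative
    fibril strains give zero sigma_f)."""
    fibril_stresses = np.asarray(fibril_stresses, float)
    directions = np.asarray(directions, float)
    sig = np.zeros((3, 3))
    for i, (s_f, e) in enumerate(zip(fibril_stresses, directions)):
        if s_f == 0.0:
            continue
        w = params.C if i < n_primary else 1.0
        sig += rho_z * w * s_f * np.outer(e, e)
    return sig


def permeability(J: float, params: MaterialParams) -> float:
    """Deformation-dependent permeability k = k0 * J^M."""
    if J <= 0:
        raise InvalidDeformationError(f"J = {J} <= 0")
    return params.k0 * J ** params.M


def fcd_current(J: float, c_FCD0: float, n_fl0: float):
    """Current fixed charge density under volumetric deformation J.

    c_FCD = c_FCD0 * n_fl0 / (n_fl0 - 1 + J): the fixed charges are conserved
    while the fluid volume fraction changes with J.
    """
    denom = n_fl0 - 1.0 + np.asarray(J, float)
    if np.any(denom <= 0):
        raise InvalidDeformationError("pore collapse: n_fl0 - 1 + J <= 0")
    return np.asarray(c_FCD0, float) * n_fl0 / denom


def anion_concentration(c_FCD, params: MaterialParams):
    """Mobile anion concentration inside the tissue from ideal Donnan
    equilibrium: c- = (-c_FCD + sqrt(c_FCD^2 + 4 (g_ext/g_int)^2 c_ext^2))/2."""
    c = np.asarray(c_FCD, float)
    g = params.gamma_ext / params.gamma_int
    return 0.5 * (-c + np.sqrt(c * c + 4.0 * g * g * params.c_ext ** 2))


def donnan_pressure(c_FCD, params: MaterialParams):
    """Donnan osmotic swelling pressure (Pa).

    dpi = phi_int R T sqrt(c_FCD^2 + 4 (g_ext/g_int)^2 c_ext^2)
          - 2 phi_ext R T c_ext
    """
    c = np.asarray(c_FCD, float)
    if np.any(c < 0):
        raise ValueError("c_FCD must be nonnegative")
    g = params.gamma_ext / params.gamma_int
    RT = params.R * params.T
    return (params.phi_int * RT * np.sqrt(c * c + 4.0 * g * g * params.c_ext ** 2)
            - 2.0 * params.phi_ext * RT * params.c_ext)


def chemical_expansion(c_FCD, c_minus, params: MaterialParams):
    """Chemical expansion stress T_c (Pa) from fixed-charge repulsion.

    T_c = a0 c_FCD exp(-kappa (g_ext/g_int) sqrt(c-(c- + c_FCD)))
    """
    c = np.asarray(c_FCD, float)
    cm = np.asarray(c_minus, float)
    if np.any(c < 0) or np.any(cm < 0):
        raise ValueError("concentrations must be nonnegative")
    g = params.gamma_ext / params.gamma_int
    return params.a0 * c * np.exp(-params.kappa * g * np.sqrt(cm * (cm + c)))


def total_stress(
    state: KinematicState,
    params: MaterialParams,
    fibril_stress_tensor: np.ndarray | None = None,
    p_eff: float = 0.0,
) -> np.ndarray:
    """Total Cauchy stress.

    sigma_tot = sigma_nf + sum_k sigma_f^k - T_c I - dpi I - p_eff I

    ``p_eff`` is the effective fluid pressure term: the water chemical
    potential is folded together with the pore pressure into a single
    effective-pressure contribution (only total boundary tractions are
    observable).
    """
    J = state.J
    c_FCD = float(fcd_current(J, state.c_FCD0, state.n_fl0))
    c_m = float(anion_concentration(c_FCD, params))
    sig = neo_hookean_stress(state.F, params)
    if fibril_stress_tensor is not None:
        sig = sig + fibril_stress_tensor
    dpi = float(donnan_pressure(c_FCD, params))
    T_c = float(chemical_expansion(c_FCD, c_m, params))
    return sig - (T_c + dpi + p_eff) * _I3
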