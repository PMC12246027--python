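"""Synthetic inputs: strain fields and depth profiles.

These generators make every downstream module testable without running the
finite-element impact stage.  The "paper-like" strain preset encodes the
reference impact outcome — a superficial impacted-zone damaged-cell fraction
of 0.56 at the (0.40, 1.50) thresholds, i.e. a plateau maximum shear strain
of 0.679 under the indenter — rather than any particular material-parameter
set, so the biology stages are decoupled from the mechanical preset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .biokinetics import KineticsGrid
from .cell_damage import DamageThresholds
from .constitutive import DepthProfile
from .impact_solver import StrainField, export_strain_field

__all__ = [
    "FixtureSpec",
    "make_strain_fixture",
    "paper_like_strain_field",
    "make_depth_profile_fixture",
    "invert_damage_fraction",
]

PAPER_LIKE_PEAK_GAMMA = 0.679  # plateau strain giving 0.56 damage at (0.40, 1.50)


def invert_damage_fraction(f: float, thresholds: DamageThresholds = DamageThresholds()) -> float:
    """Strain at which the damage function equals ``f`` (0 < f < 1).

    Solves f = (em/eps)(eps-ei)/(em-ei) for eps:
    eps = em*ei / (em - f*(em - ei)).
    """
    if not (0.0 < f < 1.0):
        raise ValueError("f must lie strictly between 0 and 1")
    ei, em = thresholds.eps_init, thresholds.eps_max
    return em * ei / (em - f * (em - ei))


@dataclass(frozen=True)
class FixtureSpec:
    """Synthetic strain-field specification."""

    grid: KineticsGrid = KineticsGrid()
    pattern: str = "radial-gaussian"    # uniform | radial-gaussian | depth-profile
    peak_gamma: float = PAPER_LIKE_PEAK_GAMMA
    plateau_radius: float = 2.5e-3      # m, flat-top under the indenter
    pattern_width: float = 2.5e-3       # m, Gaussian half-width of radial decay
    noise_sd: float = 0.0               # relative perturbation, 0 = deterministic
    seed: int = 0

    def __post_init__(self):
        if self.peak_gamma < 0:
            raise ValueError("peak_gamma must be nonnegative")
        if self.pattern not in ("uniform", "radial-gaussian", "depth-profile"):
            raise ValueError(f"unknown pattern {self.pattern!r}")


def _pattern_values(spec: FixtureSpec, r: np.ndarray, z: np.ndarray) -> np.ndarray:
    if spec.pattern == "uniform":
        return np.full_like(r, spec.peak_gamma)
    if spec.pattern == "radial-gaussian":
        d = np.maximum(r - spec.plateau_radius, 0.0)
        return spec.peak_gamma * np.exp(-0.5 * (d / spec.pattern_width) ** 2)
    # depth-profile: plateau radially, linear attenuation by 30% to the deep side
    d = np.maximum(r - spec.plateau_radius, 0.0)
    radial = np.exp(-0.5 * (d / spec.pattern_width) ** 2)
    depth = 1.0 - 0.3 * (z / z.max() if z.max() > 0 else z)
    return spec.peak_gamma * radial * depth


def paper_like_strain_field(spec: FixtureSpec = FixtureSpec()) -> StrainField:
    """Deterministic synthetic strain field on the kinetics grid."""
    r, z = spec.grid.points()
    gam = _pattern_values(spec, r, z)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        gam = np.clip(gam * (1.0 + spec.noise_sd * rng.standard_normal(gam.shape)), 0.0, None)
    # a plausible impact pore-pressure pattern: scales with local strain
    pp = 2.0e6 * gam / max(spec.peak_gamma, 1e-12)
    return StrainField(r=r, z=z, gamma_max=gam, pore_pressure=pp,
                       meta={"fixture": spec.pattern, "seed": spec.seed,
                             "peak_gamma": spec.peak_gamma,
                             "synthetic": True})


def make_strain_fixture(spec: FixtureSpec, path) -> StrainField:
    """Generate the synthetic field and write it as a strain-field CSV."""
    fieldf = paper_like_strain_field(spec)
    export_strain_field(fieldf, path)
    return fieldf


def make_depth_profile_fixture(n: int = 21) -> DepthProfile:
    """Smooth, physiological depth profiles for mature bovine cartilage.

    Fixed charge density rises with depth (proteoglycan-rich deep zone),
    fluid fraction falls with depth, collagen density is highest at the
    surface and in the deep zone (classic U-like pattern flattened here to a
    monotone decrease for simplicity of the fibril weighting).
    """
    z = np.linspace(0.0, 1.0, n)
    c_FCD0 = 120.0 + 130.0 * z ** 1.2          # 120 -> 250 mol m^-3
    n_fl0 = 0.85 - 0.15 * z                    # 0.85 -> 0.70
    rho_z = 0.25 - 0.08 * z                    # 0.25 -> 0.17
    return DepthProfile(z=z, c_FCD0=c_FCD0, n_fl0=n_fl0, rho_z=rho_z)
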