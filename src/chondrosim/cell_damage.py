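"""Strain-thresholded chondrocyte damage and the initial cell populations.

The peak maximum-shear-strain field from the impact stage is mapped to a
damaged-cell fraction with a nonlinear two-threshold function: no damage
below the initiation threshold (40% shear strain by default), all cells
damaged above the saturation threshold (150% by default), and a smooth
hyperbolic ramp in between.  The damaged fraction seeds the healthy /
damaged / dead cell populations whose total is conserved throughout the
downstream kinetics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DamageThresholds",
    "CellField",
    "ZoneSpec",
    "SUPERFICIAL_IMPACTED_ZONE",
    "INTACT_ZONE",
    "damage_fraction",
    "seed_cell_field",
    "zone_average",
]

C_INIT_DEFAULT = 0.5e14  # initial chondrocyte density (cells m^-3), homogeneous


@dataclass(frozen=True)
class DamageThresholds:
    """Shear-strain thresholds of the cellular damage function."""

    eps_init: float = 0.40   # damage initiation max shear strain (-)
    eps_max: float = 1.50    # full-damage max shear strain (-)

    def __post_init__(self):
        if not (0.0 < self.eps_init < self.eps_max):
            raise ValueError("require 0 < eps_init < eps_max")


def damage_fraction(gamma_max, thresholds: DamageThresholds = DamageThresholds()):
    """Fraction of initially healthy cells damaged at max shear strain eps.

    f = 0                                                 for eps < eps_init
    f = (eps_max/eps) (eps-eps_init)/(eps_max-eps_init)   in between
    f = 1                                                 for eps > eps_max

    Continuous and nondecreasing in eps; nonincreasing in eps_max for fixed
    eps above the initiation threshold.
    """
    eps = np.asarray(gamma_max, float)
    if np.any(eps < 0):
        raise ValueError("gamma_max must be nonnegative")
    ei, em = thresholds.eps_init, thresholds.eps_max
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        mid = (em / np.where(eps > 0, eps, 1.0)) * (eps - ei) / (em - ei)
    f = np.where(eps < ei, 0.0, np.where(eps > em, 1.0, mid))
    return f if f.ndim else float(f)


@dataclass
class CellField:
    """Healthy / damaged / dead chondrocyte concentrations on a point set.

    The total C_h + C_dmg + C_dead equals C_init at every point and time
    (no proliferation; conservation is asserted by the kinetics stepper).
    """

    r: np.ndarray
    z: np.ndarray
    C_h: np.ndarray
    C_dmg: np.ndarray
    C_dead: np.ndarray
    C_init: float = C_INIT_DEFAULT
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("r", "z", "C_h", "C_dmg", "C_dead"):
            setattr(self, name, np.asarray(getattr(self, name), float).ravel())
        if np.any(self.C_h < 0) or np.any(self.C_dmg < 0) or np.any(self.C_dead < 0):
            raise ValueError("cell concentrations must be nonnegative")

    @property
    def total(self) -> np.ndarray:
        return self.C_h + self.C_dmg + self.C_dead

    @property
    def viability(self) -> np.ndarray:
        """Viable (healthy + damaged) fraction of the initial density."""
        return (self.C_h + self.C_dmg) / self.C_init

    def conservation_error(self) -> float:
        return float(np.max(np.abs(self.total - self.C_init)) / self.C_init)


def seed_cell_field(strain_field, thresholds: DamageThresholds = DamageThresholds(),
                    C_init: float = C_INIT_DEFAULT) -> CellField:
    """Initial cell populations from the peak strain field.

    C_dmg = f_dmg(gamma_max) * C_init, C_h = (1 - f_dmg) * C_init, C_dead = 0.
    """
    gam = np.asarray(strain_field.gamma_max, float)
    if np.any(gam < 0):
        raise ValueError("strain field contains negative gamma_max")
    f = np.asarray(damage_fraction(gam, thresholds), float)
    return CellField(
        r=strain_field.r, z=strain_field.z,
        C_h=(1.0 - f) * C_init, C_dmg=f * C_init,
        C_dead=np.zeros_like(f), C_init=C_init,
        meta={"thresholds": (thresholds.eps_init, thresholds.eps_max)},
    )


@dataclass(frozen=True)
class ZoneSpec:
    """Axisymmetric reporting zone: an (r, z) box, z = depth below surface."""

    r_min: float = 0.0
    r_max: float = np.inf
    z_min: float = 0.0
    z_max: float = np.inf
    name: str = ""

    def mask(self, r: np.ndarray, z: np.ndarray) -> np.ndarray:
        return ((r >= self.r_min) & (r <= self.r_max)
                & (z >= self.z_min) & (z <= self.z_max))


# Reporting zones mirroring the source experiments: the impacted superficial
# zone is the top 200 um within the 4-mm-wide impacted core; the intact
# reference is a full-depth annulus away from the impact site.
SUPERFICIAL_IMPACTED_ZONE = ZoneSpec(0.0, 2.0e-3, 0.0, 200e-6, "superficial_impacted")
INTACT_ZONE = ZoneSpec(8.0e-3, 10.0e-3, 0.0, np.inf, "intact")


def zone_average(values, r, z, zone: ZoneSpec, weights=None) -> float:
    """Volume-weighted (2*pi*r) mean of a field quantity over a zone.

    ``weights`` may carry per-point cell volumes; otherwise points are
    weighted by radius alone (valid for uniform point spacing).
    """
    values = np.asarray(values, float).ravel()
    r = np.asarray(r, float).ravel()
    z = np.asarray(z, float).ravel()
    m = zone.mask(r, z)
    if not np.any(m):
        raise ValueError(f"zone {zone.name or zone} does not intersect the grid")
    w = (np.asarray(weights, float).ravel() if weights is not None else 2.0 * np.pi * r)
    w = w[m]
    if w.sum() <= 0:
        # on-axis single column: fall back to plain mean
        return float(values[m].mean())
    return float(np.sum(values[m] * w) / np.sum(w))
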