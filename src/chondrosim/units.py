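"""Minimal unit-tag handling for configuration files.

Every dimensional quantity in a config may be written either as a bare number
(assumed SI) or as a string ``"<number> <unit>"`` with a recognized unit tag,
e.g. ``"6.9e-5 1/s"``, ``"0.2484 1/h"``, ``"2 mM"``, ``"0.9 MPa"``.
Only multiplicative conversions are supported (no offset units).
"""

from __future__ import annotations

# unit tag -> factor to SI
_FACTORS: dict[str, float] = {
    # pressure / modulus
    "Pa": 1.0, "kPa": 1e3, "MPa": 1e6, "GPa": 1e9,
    # length
    "m": 1.0, "mm": 1e-3, "um": 1e-6, "µm": 1e-6, "nm": 1e-9,
    # time
    "s": 1.0, "min": 60.0, "h": 3600.0, "hr": 3600.0, "day": 86400.0, "d": 86400.0,
    # rates
    "1/s": 1.0, "1/min": 1.0 / 60.0, "1/h": 1.0 / 3600.0, "1/day": 1.0 / 86400.0,
    # concentration (SI internal: mol/m^3)
    "mol/m^3": 1.0, "mM": 1.0, "M": 1e3, "umol/l": 1e-3, "mmol/l": 1.0,
    # diffusivity
    "m^2/s": 1.0, "mm^2/s": 1e-6, "um^2/s": 1e-12, "cm^2/s": 1e-4,
    # force
    "N": 1.0, "kN": 1e3,
    # permeability
    "m^4/(N*s)": 1.0, "m^4/Ns": 1.0,
    # second-order rate (protection rate)
    "m^3/(mol*s)": 1.0, "m^3/mol/s": 1.0,
    # chemical expansion constants
    "Pa*m^3/mol": 1.0, "MPa*m^3/mol": 1e6, "m^3/mol": 1.0,
    # cell density
    "cells/m^3": 1.0, "1/m^3": 1.0,
    # energy, temperature, dimensionless
    "J": 1.0, "K": 1.0, "-": 1.0, "1": 1.0,
    # viscosity-like damping
    "Pa*s": 1.0, "MPa*s": 1e6,
    # molar gas constant convention
    "J/(mol*K)": 1.0,
    # PG synthesis rate
    "mol/(m^3*s)": 1.0,
}


class UnitError(ValueError):
    """Raised for unknown unit tags or malformed tagged values."""


def to_si(value) -> float:
    """Convert a possibly unit-tagged value to SI.

    Accepts a plain number (returned as float, assumed SI), a string
    ``"<number> <unit>"``, or a mapping ``{"value": x, "unit": u}``.
    """
    if isinstance(value, (int, float)):
        return float(value)
    if isinstance(value, dict):
        try:
            num, unit = value["value"], value["unit"]
        except KeyError as exc:
            raise UnitError(f"tagged value needs 'value' and 'unit': {value!r}") from exc
        return float(num) * _factor(str(unit))
    if isinstance(value, str):
        parts = value.split()
        if len(parts) == 1:
            try:
                return float(parts[0])
            except ValueError as exc:
                raise UnitError(f"cannot parse quantity {value!r}") from exc
        if len(parts) != 2:
            raise UnitError(f"cannot parse quantity {value!r}; expected '<number> <unit>'")
        try:
            num = float(parts[0])
        except ValueError as exc:
            raise UnitError(f"bad number in quantity {value!r}") from exc
        return num * _factor(parts[1])
    raise UnitError(f"unsupported quantity type: {value!r}")


def _factor(unit: str) -> float:
    try:
        return _FACTORS[unit]
    except KeyError:
        raise UnitError(f"unknown unit tag {unit!r}") from None
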