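"""Yield and unit arithmetic for fermentation endpoints.

All quantities are mass-based (g/L, g/g) unless explicitly molar.  The
biomass Cmol mass is computed from the assumed elemental composition
CH1.8O0.5N0.2, never hard-coded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict

from .model import ATOMIC_MASS

#: Assumed biomass elemental composition (per Cmol).
BIOMASS_COMPOSITION: Dict[str, float] = {"C": 1.0, "H": 1.8, "O": 0.5, "N": 0.2}


def formula_mass(formula: Dict[str, float]) -> float:
    """Molar mass (g/mol) of an elemental composition map."""
    return sum(ATOMIC_MASS[el] * n for el, n in formula.items())


@dataclass(frozen=True)
class UnitConstants:
    mw_3hp: float = 90.08          # g/mol, C3H6O3
    mw_glucose: float = 180.16     # g/mol, C6H12O6
    od_to_dcw_factor: float = 0.7  # g DCW/L per OD600 unit
    biomass_composition: Dict[str, float] = field(
        default_factory=lambda: dict(BIOMASS_COMPOSITION))

    @property
    def m_biomass(self) -> float:
        """Biomass mass per Cmol, ~24.63 g/Cmol for CH1.8O0.5N0.2."""
        return formula_mass(self.biomass_composition)


CONSTANTS = UnitConstants()


def mass_yield(titre: float, substrate_consumed: float) -> float:
    """Product mass yield (g/g) from endpoint titre and substrate consumed."""
    if substrate_consumed <= 0:
        raise ValueError("substrate consumed must be positive")
    if titre < 0:
        raise ValueError("titre must be non-negative")
    return titre / substrate_consumed


def molar_to_mass_yield(y: float, mw_product: float, mw_substrate: float) -> float:
    """Convert mol product/mol substrate to g/g."""
    if mw_product <= 0 or mw_substrate <= 0:
        raise ValueError("molar masses must be positive")
    return y * mw_product / mw_substrate


def mass_to_molar_yield(y: float, mw_product: float, mw_substrate: float) -> float:
    """Convert g/g to mol product/mol substrate."""
    if mw_product <= 0 or mw_substrate <= 0:
        raise ValueError("molar masses must be positive")
    return y * mw_substrate / mw_product


def percent_of_theoretical(y: float, y_max: float) -> float:
    """Observed yield as a percentage of a theoretical maximum."""
    if y_max <= 0:
        raise ValueError("theoretical maximum must be positive")
    if y > y_max:
        warnings.warn(
            f"yield {y} exceeds theoretical maximum {y_max}; "
            "reporting >100% (measurement noise?)",
            stacklevel=2,
        )
    return 100.0 * y / y_max


def percent_improvement(new: float, old: float) -> float:
    """Relative improvement of ``new`` over ``old`` in percent."""
    if old <= 0:
        raise ValueError("reference value must be positive")
    return 100.0 * (new - old) / old


def od_to_dcw(od600: float, factor: float = CONSTANTS.od_to_dcw_factor) -> float:
    """Dry cell weight (g/L) estimated from OD600 (DCW = 0.7 x OD600)."""
    if od600 < 0:
        raise ValueError("OD600 must be non-negative")
    return factor * od600
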