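"""Inorganic-carbon (carbonate system) equilibrium speciation.

Dissolved inorganic carbon distributes over CO2(aq) (lumped with H2CO3),
HCO3- and CO3^2- according to the two apparent acid dissociation constants;
the CO2(aq) pool in equilibrium with a gas phase follows Henry's law.  At
near-neutral cytosolic pH the bicarbonate fraction dominates — the
quantitative basis for treating HCO3-, not CO2, as the carboxylation
substrate pool.

Constants are *apparent* (no activity/ionic-strength corrections).  Defaults:
pKa1 = 6.06 and pKa2 = 10.33 (freshwater apparent constants near 20 degC),
kH = 0.039 mol/(L atm) at 20 degC, atmospheric pCO2 = 4.0e-4 atm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple


@dataclass
class CarbonateParams:
    ph: float = 7.4
    temperature_c: float = 20.0
    pka1: float = 6.06     # CO2(aq) + H2O <=> HCO3- + H+
    pka2: float = 10.33    # HCO3- <=> CO3^2- + H+
    kh: float = 0.039      # mol/(L atm), Henry constant for CO2
    pco2: float = 4.0e-4   # atm

    def __post_init__(self) -> None:
        if not self.pka1 < self.pka2:
            raise ValueError("pKa1 must be smaller than pKa2")
        if self.kh <= 0 or self.pco2 < 0:
            raise ValueError("Henry constant must be positive, pCO2 >= 0")


@dataclass
class CarbonateState:
    co2_mM: float
    hco3_mM: float
    co3_mM: float

    @property
    def dic_mM(self) -> float:
        return self.co2_mM + self.hco3_mM + self.co3_mM

    @property
    def fractions(self) -> Tuple[float, float, float]:
        total = self.dic_mM
        if total == 0:
            return (0.0, 0.0, 0.0)
        return (self.co2_mM / total, self.hco3_mM / total, self.co3_mM / total)


def species_fractions(ph: float, pka1: float, pka2: float) -> Tuple[float, float, float]:
    """Diprotic speciation fractions (fCO2, fHCO3, fCO3) at a given pH."""
    a1 = 10.0 ** (ph - pka1)          # [HCO3]/[CO2]
    a2 = 10.0 ** (2 * ph - pka1 - pka2)  # [CO3]/[CO2]
    denom = 1.0 + a1 + a2
    return (1.0 / denom, a1 / denom, a2 / denom)


def dissolved_co2(pco2: float, kh: float) -> float:
    """CO2(aq) concentration (mM) in equilibrium with a gas phase, kH*pCO2."""
    if pco2 < 0 or kh < 0:
        raise ValueError("inputs must be non-negative")
    return kh * pco2 * 1000.0


def bicarbonate_from_co2(co2_mM: float, ph: float, pka1: float) -> float:
    """HCO3- (mM) in equilibrium with a given CO2(aq) pool."""
    if co2_mM < 0:
        raise ValueError("CO2 concentration must be non-negative")
    return co2_mM * 10.0 ** (ph - pka1)


def speciate(params: CarbonateParams, dic_mM: float | None = None) -> CarbonateState:
    """Full carbonate state, either for a stated total DIC or (default) for
    the CO2 pool in Henry equilibrium with ``params.pco2``."""
    f_co2, f_hco3, f_co3 = species_fractions(params.ph, params.pka1, params.pka2)
    if dic_mM is not None:
        if dic_mM < 0:
            raise ValueError("DIC must be non-negative")
        return CarbonateState(dic_mM * f_co2, dic_mM * f_hco3, dic_mM * f_co3)
    co2 = dissolved_co2(params.pco2, params.kh)
    hco3 = bicarbonate_from_co2(co2, params.ph, params.pka1)
    co3 = hco3 * 10.0 ** (params.ph - params.pka2)
    return CarbonateState(co2, hco3, co3)
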