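"""Synthetic inputs: a curated yeast central-carbon core model, analytic toy
models with closed-form envelopes, and noisy strain endpoint tables.

The core model is a ~45-reaction lumped representation of S. cerevisiae
central carbon metabolism built so that every flux the bicarbonate analysis
reasons about is an individually boundable reaction: glycolysis, the
oxidative pentose-phosphate branch (NADPH source, CO2 release), the optional
phosphoketolase bypass (acetyl-CoA without CO2 loss), the pyruvate node
(PDH, the PDH bypass via acetaldehyde/acetate, ethanol fermentation,
pyruvate carboxylase consuming HCO3-), a lumped TCA cycle, oxidative
phosphorylation with a parameterisable P/O ratio, carbonic anhydrase
CO2 <-> HCO3-, Acc1 carboxylation (acetyl-CoA + HCO3- + ATP -> malonyl-CoA),
an ATP-dissipation reaction, and a biomass pseudo-reaction of composition
CH1.8O0.5N0.2.

Formula conventions (so every internal reaction balances in C,H,O,N,P,S
without an explicit proton species): redox carriers absorb the proton
(NADH = NAD + H2, NADPH = NADP + H2, FADH2 = FAD + H2), bicarbonate is
carried as the carbonic-acid lump CH2O3, ATP = ADP + HPO3 and Pi = H3PO4.

It is a curated fixture, not a reduction of a genome-scale reconstruction;
numbers that depend on the full yeast network (e.g. its theoretical 3-HP
yield) are not claimed of it.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import INF_BOUND, MetabolicModel, Metabolite, Reaction
from .units import BIOMASS_COMPOSITION, formula_mass

# ---------------------------------------------------------------------------
# Core model
# ---------------------------------------------------------------------------


@dataclass
class CoreModelConfig:
    """Tunable parameters of the core model.

    po_ratio:
        ATP per NADH (and per FADH2) at the respiratory chain; ~1 in yeast.
    gam:
        Growth-associated maintenance, mmol ATP per gDCW, embedded in the
        biomass reaction.
    ngam:
        Non-growth maintenance flux (mmol ATP/gDCW/h), the lower bound of the
        ATP-dissipation reaction.
    """

    po_ratio: float = 1.0
    include_pk_pathway: bool = True
    ngam: float = 0.0
    gam: float = 30.0
    ethanol_branch: bool = True
    biomass_composition: Dict[str, float] = field(
        default_factory=lambda: dict(BIOMASS_COMPOSITION))

    def __post_init__(self) -> None:
        if self.po_ratio <= 0:
            raise ValueError("P/O ratio must be positive")
        if self.gam < 0 or self.ngam < 0:
            raise ValueError("maintenance parameters must be non-negative")


_F = {
    "glc": {"C": 6, "H": 12, "O": 6},
    "g6p": {"C": 6, "H": 13, "O": 9, "P": 1},
    "f6p": {"C": 6, "H": 13, "O": 9, "P": 1},
    "x5p": {"C": 5, "H": 11, "O": 8, "P": 1},
    "gap": {"C": 3, "H": 7, "O": 6, "P": 1},
    "acp": {"C": 2, "H": 5, "O": 5, "P": 1},
    "pyr": {"C": 3, "H": 4, "O": 3},
    "acald": {"C": 2, "H": 4, "O": 1},
    "etoh": {"C": 2, "H": 6, "O": 1},
    "ac": {"C": 2, "H": 4, "O": 2},
    "oaa": {"C": 4, "H": 4, "O": 5},
    "glyc": {"C": 3, "H": 8, "O": 3},
    "co2": {"C": 1, "O": 2},
    "hco3": {"C": 1, "H": 2, "O": 3},   # carbonic-acid lump, see module docstring
    "h2o": {"H": 2, "O": 1},
    "o2": {"O": 2},
    "nh3": {"N": 1, "H": 3},
    "atp": {"C": 10, "H": 16, "N": 5, "O": 13, "P": 3},
    "adp": {"C": 10, "H": 15, "N": 5, "O": 10, "P": 2},
    "pi": {"H": 3, "O": 4, "P": 1},
    "nad": {"C": 21, "H": 26, "N": 7, "O": 14, "P": 2},
    "nadh": {"C": 21, "H": 28, "N": 7, "O": 14, "P": 2},
    "nadp": {"C": 21, "H": 27, "N": 7, "O": 17, "P": 3},
    "nadph": {"C": 21, "H": 29, "N": 7, "O": 17, "P": 3},
    "fad": {"C": 27, "H": 33, "N": 9, "O": 15, "P": 2},
    "fadh2": {"C": 27, "H": 35, "N": 9, "O": 15, "P": 2},
    "coa": {"C": 21, "H": 36, "N": 7, "O": 16, "P": 3, "S": 1},
    "accoa": {"C": 23, "H": 38, "N": 7, "O": 17, "P": 3, "S": 1},
    "malcoa": {"C": 24, "H": 38, "N": 7, "O": 19, "P": 3, "S": 1},
}

_NAMES = {
    "glc": "D-glucose", "g6p": "glucose 6-phosphate", "f6p": "fructose 6-phosphate",
    "x5p": "xylulose 5-phosphate", "gap": "glyceraldehyde 3-phosphate",
    "acp": "acetyl phosphate", "pyr": "pyruvate", "acald": "acetaldehyde",
    "etoh": "ethanol", "ac": "acetate", "oaa": "oxaloacetate",
    "glyc": "glycerol",
    "co2": "carbon dioxide", "hco3": "bicarbonate", "h2o": "water",
    "o2": "oxygen", "nh3": "ammonia", "coa": "coenzyme A",
    "accoa": "acetyl-CoA", "malcoa": "malonyl-CoA",
}


def build_core_model(config: CoreModelConfig | None = None) -> MetabolicModel:
    """Construct the curated yeast central-carbon core model.

    Every internal reaction is elementally balanced; the biomass
    pseudo-reaction is carbon-balanced against the declared composition
    (1.5 Cmol substrate in per Cmol biomass, 0.5 Cmol respired).
    """
    cfg = config or CoreModelConfig()
    p = cfg.po_ratio
    m_biomass = formula_mass(cfg.biomass_composition)

    model = MetabolicModel(
        provenance=f"bicarbenv core model (P/O={p}, PK={cfg.include_pk_pathway}, "
                   f"GAM={cfg.gam}, NGAM={cfg.ngam}, ethanol={cfg.ethanol_branch})",
        mu_per_biomass_flux=m_biomass / 1000.0,
    )

    extracellular = ["glc", "co2", "hco3", "etoh", "ac", "glyc", "o2", "nh3", "h2o"]
    for mid, formula in _F.items():
        model.add_metabolite(Metabolite(mid, _NAMES.get(mid, mid), dict(formula), 0, "c"))
    for mid in extracellular:
        model.add_metabolite(
            Metabolite(mid + "_e", _NAMES.get(mid, mid) + " (extracellular)",
                       dict(_F[mid]), 0, "e"))
    model.add_metabolite(
        Metabolite("biomass", "biomass (per Cmol)", dict(cfg.biomass_composition), 0, "c"))

    def rxn(rid, name, stoich, lb=0.0, ub=INF_BOUND, exchange=False):
        model.add_reaction(Reaction(rid, name, stoich, lb, ub, exchange))

    # exchanges: negative flux = uptake
    rxn("EX_glc", "glucose exchange", {"glc_e": -1}, -1.0, 0.0, True)
    rxn("EX_o2", "oxygen exchange", {"o2_e": -1}, -INF_BOUND, INF_BOUND, True)
    rxn("EX_co2", "CO2 exchange", {"co2_e": -1}, -INF_BOUND, INF_BOUND, True)
    rxn("EX_hco3", "bicarbonate exchange", {"hco3_e": -1}, 0.0, INF_BOUND, True)
    rxn("EX_etoh", "ethanol exchange", {"etoh_e": -1}, 0.0, INF_BOUND, True)
    rxn("EX_ac", "acetate exchange", {"ac_e": -1}, 0.0, INF_BOUND, True)
    rxn("EX_glyc", "glycerol exchange", {"glyc_e": -1}, 0.0, INF_BOUND, True)
    rxn("EX_nh3", "ammonia exchange", {"nh3_e": -1}, -INF_BOUND, INF_BOUND, True)
    rxn("EX_h2o", "water exchange", {"h2o_e": -1}, -INF_BOUND, INF_BOUND, True)
    rxn("EX_biomass", "biomass drain", {"biomass": -1}, 0.0, INF_BOUND, True)

    # transport
    rxn("GLCt", "glucose transport", {"glc_e": -1, "glc": 1})
    rxn("O2t", "oxygen diffusion", {"o2_e": -1, "o2": 1}, -INF_BOUND)
    rxn("CO2t", "CO2 diffusion", {"co2": -1, "co2_e": 1}, -INF_BOUND)
    rxn("HCO3t", "bicarbonate import (Sul1-like influx)",
        {"hco3_e": -1, "hco3": 1})
    rxn("ETOHt", "ethanol export", {"etoh": -1, "etoh_e": 1})
    rxn("ACt", "acetate export", {"ac": -1, "ac_e": 1})
    rxn("GLYCt", "glycerol export", {"glyc": -1, "glyc_e": 1})
    rxn("NH3t", "ammonia uptake", {"nh3_e": -1, "nh3": 1})
    rxn("H2Ot", "water diffusion", {"h2o": -1, "h2o_e": 1}, -INF_BOUND)

    # glycolysis (lumped; net 2 ATP + 2 NADH per glucose)
    rxn("HXK", "hexokinase", {"glc": -1, "atp": -1, "g6p": 1, "adp": 1})
    rxn("PGI", "phosphoglucose isomerase", {"g6p": -1, "f6p": 1}, -INF_BOUND)
    rxn("PFK_FBA", "phosphofructokinase + aldolase + TPI",
        {"f6p": -1, "atp": -1, "gap": 2, "adp": 1})
    rxn("GAPD_PYK", "lower glycolysis (GAP -> pyruvate)",
        {"gap": -1, "nad": -1, "adp": -2, "pi": -1,
         "pyr": 1, "nadh": 1, "atp": 2, "h2o": 1})

    # glycerol branch: the anaerobic NADH sink of yeast
    rxn("G3PD", "glycerol formation (GAP + NADH -> glycerol + Pi)",
        {"gap": -1, "nadh": -1, "h2o": -1, "glyc": 1, "nad": 1, "pi": 1})

    # pentose phosphate pathway
    rxn("OXPPP", "oxidative PP pathway (G6P -> X5P + CO2 + 2 NADPH)",
        {"g6p": -1, "h2o": -1, "nadp": -2, "x5p": 1, "co2": 1, "nadph": 2})
    rxn("TKT", "non-oxidative PP rearrangement (3 X5P <-> 2 F6P + GAP)",
        {"x5p": -3, "f6p": 2, "gap": 1}, -INF_BOUND)

    # phosphoketolase bypass: acetyl-CoA without CO2 release
    if cfg.include_pk_pathway:
        rxn("XPK", "phosphoketolase (X5P -> AcP + GAP)",
            {"x5p": -1, "pi": -1, "acp": 1, "gap": 1, "h2o": 1})
        rxn("PTA", "phosphotransacetylase",
            {"acp": -1, "coa": -1, "accoa": 1, "pi": 1})

    # pyruvate node
    rxn("PDC", "pyruvate decarboxylase", {"pyr": -1, "acald": 1, "co2": 1})
    if cfg.ethanol_branch:
        rxn("ADH", "alcohol dehydrogenase", {"acald": -1, "nadh": -1, "etoh": 1, "nad": 1})
    rxn("ALD6", "NADP aldehyde dehydrogenase",
        {"acald": -1, "nadp": -1, "h2o": -1, "ac": 1, "nadph": 1})
    rxn("ACS", "acetyl-CoA synthetase (2 ATP equivalents)",
        {"ac": -1, "coa": -1, "atp": -2, "h2o": -1, "accoa": 1, "adp": 2, "pi": 2})
    rxn("PDH", "pyruvate dehydrogenase",
        {"pyr": -1, "coa": -1, "nad": -1, "accoa": 1, "co2": 1, "nadh": 1})
    rxn("PYC", "pyruvate carboxylase (HCO3- consuming)",
        {"pyr": -1, "hco3": -1, "atp": -1, "oaa": 1, "adp": 1, "pi": 1})

    # TCA (lumped per acetyl-CoA: 1 ATP-equivalent + 3 NADH + 1 FADH2)
    rxn("TCA", "TCA cycle (lumped)",
        {"accoa": -1, "nad": -3, "fad": -1, "adp": -1, "pi": -1, "h2o": -2,
         "coa": 1, "co2": 2, "nadh": 3, "fadh2": 1, "atp": 1})

    # oxidative phosphorylation at the configured P/O ratio
    rxn("NADH_OXPHOS", f"NADH respiration (P/O={p})",
        {"nadh": -1, "o2": -0.5, "adp": -p, "pi": -p,
         "nad": 1, "atp": p, "h2o": 1 + p})
    rxn("FADH2_OXPHOS", f"FADH2 respiration (P/O={p})",
        {"fadh2": -1, "o2": -0.5, "adp": -p, "pi": -p,
         "fad": 1, "atp": p, "h2o": 1 + p})

    # inorganic carbon and carboxylation
    rxn("CA", "carbonic anhydrase (CO2 + H2O <-> HCO3-)",
        {"co2": -1, "h2o": -1, "hco3": 1}, -INF_BOUND)
    rxn("ACC1", "acetyl-CoA carboxylase",
        {"accoa": -1, "hco3": -1, "atp": -1, "malcoa": 1, "adp": 1, "pi": 1})

    # maintenance + biomass
    rxn("ATPM", "ATP dissipation (maintenance)",
        {"atp": -1, "h2o": -1, "adp": 1, "pi": 1}, cfg.ngam)
    gam_cmol = cfg.gam * m_biomass / 1000.0  # mol ATP per Cmol biomass
    # 1.5 Cmol precursor carbon in per Cmol biomass, 0.5 Cmol respired; the
    # sugar phosphate's Pi is returned (biomass carries no phosphorus)
    rxn("BIOMASS", "biomass pseudo-reaction (per Cmol)",
        {"g6p": -0.2, "oaa": -0.075, "nh3": -0.2, "nadph": -0.3,
         "atp": -gam_cmol, "h2o": -gam_cmol,
         "biomass": 1, "co2": 0.5, "nadp": 0.3,
         "adp": gam_cmol, "pi": gam_cmol + 0.2})

    model.set_role("glucose_exchange", "EX_glc")
    model.set_role("biomass", "BIOMASS")
    model.set_role("bicarbonate_formation", "CA")
    model.set_role("bicarbonate_exchange", "EX_hco3")
    model.set_role("atp_dissipation", "ATPM")
    return model


# ---------------------------------------------------------------------------
# Analytic toy models
# ---------------------------------------------------------------------------

_CMOL = {"C": 1, "H": 2, "O": 1}  # CH2O, 30.025 g/mol


def build_toy_linear_model() -> MetabolicModel:
    """Linear chain A_ext -> A -> B -> B_ext with uptake bound 1.

    Closed form: maximal B export equals the uptake bound.
    """
    model = MetabolicModel(provenance="toy linear chain")
    for mid, comp in (("A_e", "e"), ("A", "c"), ("B", "c"), ("B_e", "e")):
        model.add_metabolite(Metabolite(mid, mid, dict(_CMOL), 0, comp))
    model.add_reaction(Reaction("EX_A", "A exchange", {"A_e": -1}, -1.0, 0.0, True))
    model.add_reaction(Reaction("At", "A uptake", {"A_e": -1, "A": 1}, 0.0, INF_BOUND))
    model.add_reaction(Reaction("AB", "A -> B", {"A": -1, "B": 1}, 0.0, INF_BOUND))
    model.add_reaction(Reaction("Bt", "B export", {"B": -1, "B_e": 1}, 0.0, INF_BOUND))
    model.add_reaction(Reaction("EX_B", "B exchange", {"B_e": -1}, 0.0, INF_BOUND, True))
    model.set_role("glucose_exchange", "EX_A")
    model.set_role("product_exchange", "EX_B")
    return model


def build_toy_branch_model() -> MetabolicModel:
    """Branch model: substrate S converts 1:1 to product P or biomass X.

    All species are CH2O Cmol units, so the envelope is the exact line
    yield_product = Ymax * (1 - growth_fraction) with Ymax = 1 g/g.
    """
    model = MetabolicModel(provenance="toy branch model",
                           mu_per_biomass_flux=formula_mass(_CMOL) / 1000.0)
    for mid, comp in (("S_e", "e"), ("S", "c"), ("P", "c"), ("P_e", "e"), ("X", "c")):
        model.add_metabolite(Metabolite(mid, mid, dict(_CMOL), 0, comp))
    model.add_reaction(Reaction("EX_S", "S exchange", {"S_e": -1}, -1.0, 0.0, True))
    model.add_reaction(Reaction("St", "S uptake", {"S_e": -1, "S": 1}, 0.0, INF_BOUND))
    model.add_reaction(Reaction("SP", "S -> P", {"S": -1, "P": 1}, 0.0, INF_BOUND))
    model.add_reaction(Reaction("SX", "S -> biomass", {"S": -1, "X": 1}, 0.0, INF_BOUND))
    model.add_reaction(Reaction("Pt", "P export", {"P": -1, "P_e": 1}, 0.0, INF_BOUND))
    model.add_reaction(Reaction("EX_P", "P exchange", {"P_e": -1}, 0.0, INF_BOUND, True))
    model.add_reaction(Reaction("EX_X", "biomass drain", {"X": -1}, 0.0, INF_BOUND, True))
    model.set_role("glucose_exchange", "EX_S")
    model.set_role("product_exchange", "EX_P")
    model.set_role("biomass", "SX")
    return model


@dataclass
class AnalyticEnvelope:
    """Closed-form envelope of the toy branch model."""

    uptake: float = 1.0
    yield_max: float = 1.0  # g/g, equal Cmol masses

    @property
    def mu_max(self) -> float:
        return self.uptake * formula_mass(_CMOL) / 1000.0

    def product_max_flux(self, mu: float) -> float:
        """Maximal product flux at growth rate mu (1/h)."""
        return max(0.0, self.uptake * (1.0 - mu / self.mu_max))

    def yield_product(self, growth_fraction: float) -> float:
        """Maximal product mass yield (g/g) at a growth fraction in [0, 1]."""
        return self.yield_max * (1.0 - growth_fraction)


def analytic_envelope_toy(uptake: float = 1.0) -> AnalyticEnvelope:
    """Exact envelope of :func:`build_toy_branch_model` for a given uptake."""
    return AnalyticEnvelope(uptake=uptake)


# ---------------------------------------------------------------------------
# Strain endpoint tables
# ---------------------------------------------------------------------------


@dataclass
class StrainTable:
    """Fermentation endpoints, one row per strain, with ground truth when
    synthetic."""

    data: pd.DataFrame
    seed: int | None = None

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False, float_format="%.6g")

    def csv_bytes(self) -> bytes:
        buf = io.StringIO()
        self.data.to_csv(buf, index=False, float_format="%.6g")
        return buf.getvalue().encode()


def generate_strain_table(
    truth: Sequence[Tuple[float, float]],
    glucose: float = 20.0,
    noise_cv: float = 0.05,
    seed: int = 0,
) -> StrainTable:
    """Noisy strain endpoints from known ground-truth yields.

    Each (yield_product, yield_biomass) pair produces one strain with
    titre = yield_product * glucose * (1 + eps) and
    DCW = yield_biomass * glucose * (1 + eps'), eps ~ Normal(0, noise_cv).
    Negative draws are clipped at zero with a warning.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    if any(yp < 0 or yb < 0 for yp, yb in truth):
        raise ValueError("truth yields must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    clipped = 0
    for i, (yp, yb) in enumerate(truth):
        titre = yp * glucose * (1.0 + rng.normal(0.0, noise_cv))
        dcw = yb * glucose * (1.0 + rng.normal(0.0, noise_cv))
        if titre < 0 or dcw < 0:
            clipped += 1
            titre, dcw = max(titre, 0.0), max(dcw, 0.0)
        rows.append({
            "strain": f"SYN{i + 1:03d}",
            "titre_g_l": titre,
            "glucose_g_l": glucose,
            "dcw_g_l": dcw,
            "true_yield_product": yp,
            "true_yield_biomass": yb,
        })
    if clipped:
        warnings.warn(f"{clipped} negative synthetic endpoint(s) clipped at 0",
                      stacklevel=2)
    return StrainTable(pd.DataFrame(rows), seed=seed)


def load_strain_endpoints() -> pd.DataFrame:
    """Published shake-flask endpoints of the engineered 3-HP strains
    (20 g/L glucose throughout; OD600 where reported)."""
    path = resources.files("bicarbenv.data").joinpath("strain_endpoints.csv")
    return pd.read_csv(io.StringIO(path.read_text()))
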