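"""Model edits for 3-HP production and bicarbonate availability.

Three edits are provided, all pure (they return modified copies and log the
edit in the model provenance):

* :func:`add_3hp_pathway` grafts the malonyl-CoA reductase route onto a model:
  malonyl-CoA -> malonic semialdehyde (MSA) -> 3-hydroxypropionic acid (3-HP),
  each reduction consuming one NAD(P)H, plus a secretion-only 3-HP exchange.
* :func:`cap_bicarbonate_formation` bounds the carbonic-anhydrase-type
  CO2 -> HCO3- conversion at a chosen multiple of the glucose uptake rate —
  the native-supply constraint of the envelope analysis.
* :func:`enable_bicarbonate_uptake` opens the bicarbonate exchange to uptake
  at a chosen multiple of glucose uptake — external supplementation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .model import MetabolicModel, Metabolite, ModelValidationError, Reaction, INF_BOUND

#: Sentinel accepted wherever a bicarbonate ratio may be unbounded.
UNBOUNDED = math.inf


@dataclass
class PathwaySpec:
    """Configuration of the heterologous 3-HP route.

    cofactor:
        NAD(P)H used by both reduction steps.  Default NADPH: the reductase's
        two domains are NADPH-dependent in the source organism; configurable
        because either cofactor pair may be present in a host model.
    """

    cofactor: str = "NADPH"
    compartment: str = "c"
    product_exchange_id: str = "EX_3hp"
    malonyl_coa_id: str = "malcoa"
    coa_id: str = "coa"


_COFACTORS = {
    "NADPH": ("nadph", "nadp"),
    "NADH": ("nadh", "nad"),
}


def add_3hp_pathway(model: MetabolicModel, spec: PathwaySpec | None = None) -> MetabolicModel:
    """Add the two reduction reactions and the 3-HP secretion exchange.

    Adds exactly three reactions and two metabolites (MSA and 3-HP); all
    internal additions are elementally balanced.  The ``product_exchange``
    role is set on the new exchange.  Raises if the pathway is already
    present or a required species is missing.
    """
    spec = spec or PathwaySpec()
    if spec.cofactor not in _COFACTORS:
        raise ModelValidationError(f"unknown cofactor {spec.cofactor!r}")
    red, ox = _COFACTORS[spec.cofactor]
    for needed in (spec.malonyl_coa_id, spec.coa_id, red, ox):
        if needed not in model.metabolites:
            raise ModelValidationError(f"model lacks required species {needed!r}")
    if "3hp" in model.metabolites or "msa" in model.metabolites:
        raise ModelValidationError("3-HP pathway already present in model")
    if spec.compartment not in {m.compartment for m in model.metabolites.values()}:
        raise ModelValidationError(f"compartment {spec.compartment!r} not in model")

    out = model.copy()
    out.add_metabolite(Metabolite("msa", "malonic semialdehyde",
                                  {"C": 3, "H": 4, "O": 3}, -1, spec.compartment))
    out.add_metabolite(Metabolite("3hp", "3-hydroxypropionic acid",
                                  {"C": 3, "H": 6, "O": 3}, -1, spec.compartment))
    # malonyl-CoA + NAD(P)H -> MSA + CoA + NAD(P)+   (reductase C-domain)
    out.add_reaction(Reaction(
        "MCR_C", "malonyl-CoA reductase (C domain)",
        {spec.malonyl_coa_id: -1, red: -1, "msa": 1, spec.coa_id: 1, ox: 1},
        0.0, INF_BOUND))
    # MSA + NAD(P)H -> 3-HP + NAD(P)+   (reductase N-domain)
    out.add_reaction(Reaction(
        "MCR_N", "malonyl-CoA reductase (N domain)",
        {"msa": -1, red: -1, "3hp": 1, ox: 1},
        0.0, INF_BOUND))
    # secretion only by default: no re-uptake of product
    out.add_reaction(Reaction(
        spec.product_exchange_id, "3-HP exchange",
        {"3hp": -1}, 0.0, INF_BOUND, is_exchange=True))
    out.set_role("product_exchange", spec.product_exchange_id)
    out.log(f"added 3-HP pathway (cofactor {spec.cofactor})")
    return out


def _glucose_magnitude(model: MetabolicModel, glucose_uptake: float | None) -> float:
    if glucose_uptake is not None:
        return abs(glucose_uptake)
    glc = model.role_reaction("glucose_exchange")
    return abs(glc.lower_bound)


def cap_bicarbonate_formation(
    model: MetabolicModel, ratio: float, glucose_uptake: float | None = None
) -> MetabolicModel:
    """Set the upper bound of the bicarbonate-formation reaction to
    ``ratio * |glucose_uptake|``; the unbounded sentinel restores +inf."""
    if ratio < 0:
        raise ModelValidationError("bicarbonate ratio must be >= 0")
    rxn = model.role_reaction("bicarbonate_formation")
    out = model.copy()
    target = out.reactions[rxn.id]
    if math.isinf(ratio):
        target.upper_bound = INF_BOUND
        out.log("bicarbonate formation unbounded")
    else:
        target.upper_bound = ratio * _glucose_magnitude(model, glucose_uptake)
        out.log(f"bicarbonate formation capped at ratio {ratio}")
    return out


def enable_bicarbonate_uptake(
    model: MetabolicModel, ratio: float, glucose_uptake: float | None = None
) -> MetabolicModel:
    """Allow bicarbonate uptake through the exchange at up to
    ``ratio * |glucose_uptake|`` (external supplementation)."""
    if ratio < 0:
        raise ModelValidationError("bicarbonate ratio must be >= 0")
    rxn = model.role_reaction("bicarbonate_exchange")
    out = model.copy()
    target = out.reactions[rxn.id]
    if math.isinf(ratio):
        target.lower_bound = -INF_BOUND
        out.log("bicarbonate uptake unbounded")
    else:
        target.lower_bound = -ratio * _glucose_magnitude(model, glucose_uptake)
        out.log(f"bicarbonate uptake allowed at ratio {ratio}")
    return out
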