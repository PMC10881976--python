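"""Read-only SBML Level 3 + FBC import.

Only the constructs the envelope analysis needs are mapped: species (id,
name, formula, charge, compartment), reactions (stoichiometry, flux bounds)
and boundary/exchange status.  Anything else in the file is ignored with one
log line per ignored construct class.

Semantic roles (glucose exchange, biomass, ...) in third-party models are
resolved by ordered matching: exact reaction id from the supplied config,
then SBO/annotation hints, then a case-insensitive name regex.  A role that
matches nothing is left unset rather than guessed.
"""

from __future__ import annotations

import logging
import re
from typing import Dict, Mapping, Optional

import libsbml

from .model import (
    ATOMIC_MASS,
    INF_BOUND,
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
    ROLE_NAMES,
)

log = logging.getLogger(__name__)


class SBMLParseError(ValueError):
    """Malformed SBML; message carries the libsbml line number."""


#: Default name-regex fallbacks for role resolution in genome-scale models
#: (the Yeast8 naming style).  Exact ids always take precedence via config.
DEFAULT_ROLE_PATTERNS: Dict[str, str] = {
    "glucose_exchange": r"d-?glucose exchange",
    "biomass": r"growth|biomass",
    "bicarbonate_formation": r"carbonic anhydrase|bicarbonate formation",
    "bicarbonate_exchange": r"bicarbonate exchange",
    "atp_dissipation": r"non-?growth.*maintenance|atp maintenance",
}

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*\.?\d*)")


def parse_formula(text: str) -> Dict[str, float]:
    """Parse a Hill-style formula string like ``C6H12O6`` into a dict."""
    out: Dict[str, float] = {}
    for el, num in _FORMULA_RE.findall(text or ""):
        if el not in ATOMIC_MASS:
            # extension elements are carried through untouched
            pass
        out[el] = out.get(el, 0.0) + (float(num) if num else 1.0)
    return out


def _bound_value(sb_model, fbc_rxn, which: str, rid: str) -> float:
    pid = (
        fbc_rxn.getLowerFluxBound()
        if which == "lower"
        else fbc_rxn.getUpperFluxBound()
    )
    if not pid:
        raise ModelValidationError(f"reaction {rid!r}: missing {which} flux bound")
    param = sb_model.getParameter(pid)
    if param is None or not param.isSetValue():
        raise ModelValidationError(
            f"reaction {rid!r}: {which} bound parameter {pid!r} has no value"
        )
    return float(param.getValue())


def read_sbml(path, role_config: Optional[Mapping[str, str]] = None) -> MetabolicModel:
    """Load an SBML Level 3 + FBC model file.

    Parameters
    ----------
    path:
        SBML file path.
    role_config:
        Optional map of role name -> exact reaction id, taking precedence
        over the built-in annotation/name-pattern matching.
    """
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise SBMLParseError(
            f"SBML parse error at line {err.getLine()}: {err.getMessage().strip()}"
        )
    sb_model = doc.getModel()
    if sb_model is None:
        raise SBMLParseError("SBML file contains no model element")

    model = MetabolicModel(provenance=f"sbml:{sb_model.getId() or path}")

    ignored = set()
    for plugin_name in ("groups", "layout", "comp"):
        if doc.getPlugin(plugin_name) is not None:
            ignored.add(plugin_name)
    for construct in ignored:
        log.warning("ignoring SBML construct: %s", construct)
    if sb_model.getNumRules() or sb_model.getNumEvents():
        log.warning("ignoring SBML construct: rules/events")

    for i in range(sb_model.getNumSpecies()):
        sp = sb_model.getSpecies(i)
        fbc_sp = sp.getPlugin("fbc")
        formula = {}
        charge = 0
        if fbc_sp is not None:
            if fbc_sp.isSetChemicalFormula():
                formula = parse_formula(fbc_sp.getChemicalFormula())
            if fbc_sp.isSetCharge():
                charge = fbc_sp.getCharge()
        model.add_metabolite(
            Metabolite(
                id=sp.getId(),
                name=sp.getName() or sp.getId(),
                formula=formula,
                charge=charge,
                compartment=sp.getCompartment() or "c",
            )
        )

    boundary = {
        sb_model.getSpecies(i).getId()
        for i in range(sb_model.getNumSpecies())
        if sb_model.getSpecies(i).getBoundaryCondition()
    }

    for i in range(sb_model.getNumReactions()):
        rx = sb_model.getReaction(i)
        rid = rx.getId()
        fbc_rxn = rx.getPlugin("fbc")
        if fbc_rxn is None:
            raise ModelValidationError(f"reaction {rid!r}: no FBC flux bounds")
        stoich: Dict[str, float] = {}
        for j in range(rx.getNumReactants()):
            sr = rx.getReactant(j)
            if sr.getSpecies() in boundary:
                continue
            stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) - sr.getStoichiometry()
        for j in range(rx.getNumProducts()):
            sr = rx.getProduct(j)
            if sr.getSpecies() in boundary:
                continue
            stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) + sr.getStoichiometry()
        lb = _bound_value(sb_model, fbc_rxn, "lower", rid)
        ub = _bound_value(sb_model, fbc_rxn, "upper", rid)
        model.add_reaction(
            Reaction(
                id=rid,
                name=rx.getName() or rid,
                stoichiometry=stoich,
                lower_bound=max(lb, -INF_BOUND) if lb != float("-inf") else -INF_BOUND,
                upper_bound=min(ub, INF_BOUND) if ub != float("inf") else INF_BOUND,
                is_exchange=len(stoich) == 1,
            )
        )

    _resolve_roles(model, role_config or {})
    return model


def _resolve_roles(model: MetabolicModel, role_config: Mapping[str, str]) -> None:
    for role in ROLE_NAMES:
        rid = role_config.get(role)
        if rid is not None:
            if rid not in model.reactions:
                raise ModelValidationError(
                    f"configured id {rid!r} for role {role!r} not in model"
                )
            model.set_role(role, rid)
            continue
        pattern = DEFAULT_ROLE_PATTERNS.get(role)
        if pattern is None:
            continue
        rx = re.compile(pattern, re.IGNORECASE)
        hits = [r.id for r in model.reactions.values() if rx.search(r.name or "")]
        if len(hits) == 1:
            model.set_role(role, hits[0])
        elif len(hits) > 1:
            log.warning("role %s: ambiguous name matches %s; left unset", role, hits[:5])
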