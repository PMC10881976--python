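"""Stoichiometric model data structures, native JSON I/O and balance checks.

A :class:`MetabolicModel` is the object flux balance analysis acts on: a set
of metabolites with elemental formulas, a set of bounded reactions, and a
``roles`` map that names the handful of reactions the envelope analysis needs
to find by meaning rather than by id (glucose exchange, biomass, product
exchange, bicarbonate formation, bicarbonate exchange, ATP dissipation).

Sign convention: for exchange reactions, negative flux is uptake and positive
flux is secretion.  Units are mmol/gDCW/h throughout; no unit inference is
performed on file input.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional

import numpy as np
from scipy import sparse

#: Standard atomic masses (g/mol) for the supported element set.
ATOMIC_MASS = {
    "C": 12.011,
    "H": 1.008,
    "O": 15.999,
    "N": 14.007,
    "P": 30.974,
    "S": 32.06,
}

ROLE_NAMES = (
    "glucose_exchange",
    "biomass",
    "product_exchange",
    "bicarbonate_formation",
    "bicarbonate_exchange",
    "atp_dissipation",
)

#: Effectively-unbounded flux used for open bounds.
INF_BOUND = 1000.0


class ModelValidationError(ValueError):
    """Raised when a model or model file violates a structural invariant."""


class SchemaError(ModelValidationError):
    """Raised when a native JSON model file violates the documented schema."""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    formula: Dict[str, float] = field(default_factory=dict)
    charge: int = 0
    compartment: str = "c"

    def molar_mass(self) -> float:
        """Molar mass in g/mol computed from the elemental formula."""
        return sum(ATOMIC_MASS[el] * n for el, n in self.formula.items())

    def carbon(self) -> float:
        return float(self.formula.get("C", 0.0))


@dataclass
class Reaction:
    id: str
    name: str = ""
    stoichiometry: Dict[str, float] = field(default_factory=dict)
    lower_bound: float = -INF_BOUND
    upper_bound: float = INF_BOUND
    is_exchange: bool = False

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )


@dataclass
class MetabolicModel:
    metabolites: Dict[str, Metabolite] = field(default_factory=dict)
    reactions: Dict[str, Reaction] = field(default_factory=dict)
    roles: Dict[str, str] = field(default_factory=dict)
    provenance: str = ""
    #: Growth rate (1/h) per unit flux of the biomass reaction.  1.0 means the
    #: biomass flux *is* the growth rate (genome-scale convention); the bundled
    #: core model produces one Cmol of biomass per flux unit and sets this to
    #: M_biomass/1000.
    mu_per_biomass_flux: float = 1.0

    # -- construction ----------------------------------------------------
    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise ModelValidationError(f"duplicate metabolite id {met.id!r}")
        if not met.compartment:
            raise ModelValidationError(f"metabolite {met.id!r}: empty compartment")
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self.reactions:
            raise ModelValidationError(f"duplicate reaction id {rxn.id!r}")
        if not rxn.stoichiometry:
            raise ModelValidationError(f"reaction {rxn.id!r}: empty stoichiometry")
        for mid in rxn.stoichiometry:
            if mid not in self.metabolites:
                raise ModelValidationError(
                    f"reaction {rxn.id!r} references unknown metabolite {mid!r}"
                )
        if rxn.is_exchange and len(rxn.stoichiometry) != 1:
            raise ModelValidationError(
                f"exchange reaction {rxn.id!r} must touch exactly one metabolite"
            )
        self.reactions[rxn.id] = rxn

    def set_role(self, role: str, reaction_id: str) -> None:
        if role not in ROLE_NAMES:
            raise ModelValidationError(f"unknown role {role!r}")
        if reaction_id not in self.reactions:
            raise ModelValidationError(
                f"role {role!r} points at unknown reaction {reaction_id!r}"
            )
        self.roles[role] = reaction_id

    def role_reaction(self, role: str) -> Reaction:
        try:
            rid = self.roles[role]
        except KeyError:
            raise ModelValidationError(f"role {role!r} is not set on this model")
        return self.reactions[rid]

    def copy(self) -> "MetabolicModel":
        return copy.deepcopy(self)

    def log(self, message: str) -> None:
        """Append an edit note to the provenance tag."""
        self.provenance = (self.provenance + "; " if self.provenance else "") + message

    # -- views ------------------------------------------------------------
    @property
    def reaction_ids(self) -> List[str]:
        return list(self.reactions)

    @property
    def metabolite_ids(self) -> List[str]:
        return list(self.metabolites)

    def exchanges(self) -> List[Reaction]:
        return [r for r in self.reactions.values() if r.is_exchange]


@dataclass
class BalanceReport:
    """Element-wise balance audit of all internal (non-exchange) reactions."""

    imbalances: Dict[str, Dict[str, float]]
    unbalanced: List[str]
    passed: bool

    def __bool__(self) -> bool:
        return self.passed


def stoichiometric_matrix(model: MetabolicModel) -> sparse.csr_matrix:
    """The S matrix (metabolites x reactions) with S[i, j] = coefficient of
    metabolite i in reaction j; column order follows reaction order."""
    met_index = {m: i for i, m in enumerate(model.metabolite_ids)}
    rows, cols, vals = [], [], []
    for j, rxn in enumerate(model.reactions.values()):
        for mid, coeff in rxn.stoichiometry.items():
            rows.append(met_index[mid])
            cols.append(j)
            vals.append(float(coeff))
    return sparse.csr_matrix(
        (vals, (rows, cols)),
        shape=(len(model.metabolites), len(model.reactions)),
    )


def validate_elemental_balance(
    model: MetabolicModel, tol: float = 1e-6
) -> BalanceReport:
    """Check every internal reaction element-by-element.

    The biomass pseudo-reaction (identified through the ``biomass`` role) is
    exempt from the full check but still audited for carbon, since the carbon
    bookkeeping is what the envelope analysis relies on.  A metabolite without
    a formula inside an internal reaction yields a report entry rather than an
    exception.
    """
    imbalances: Dict[str, Dict[str, float]] = {}
    unbalanced: List[str] = []
    biomass_id = model.roles.get("biomass")
    for rxn in model.reactions.values():
        if rxn.is_exchange:
            continue
        elements = ["C"] if rxn.id == biomass_id else list(ATOMIC_MASS)
        totals = {el: 0.0 for el in elements}
        missing = False
        for mid, coeff in rxn.stoichiometry.items():
            met = model.metabolites[mid]
            if not met.formula:
                imbalances[rxn.id] = {"missing_formula": math.nan}
                missing = True
                break
            for el in elements:
                totals[el] += coeff * met.formula.get(el, 0.0)
        if missing:
            unbalanced.append(rxn.id)
            continue
        bad = {el: v for el, v in totals.items() if abs(v) > tol}
        if bad:
            imbalances[rxn.id] = bad
            unbalanced.append(rxn.id)
    return BalanceReport(imbalances=imbalances, unbalanced=unbalanced,
                         passed=not unbalanced)


def exchange_carbon_flux(model: MetabolicModel, fluxes: Mapping[str, float]) -> float:
    """Net carbon leaving the system (mmol C/gDCW/h) for a flux vector.

    Zero (to solver tolerance) for any steady-state solution of a
    carbon-balanced model.
    """
    total = 0.0
    for rxn in model.exchanges():
        (mid, coeff), = rxn.stoichiometry.items()
        # positive exchange flux removes the metabolite (secretion)
        total += fluxes.get(rxn.id, 0.0) * (-coeff) * model.metabolites[mid].carbon()
    return total


# ---------------------------------------------------------------------------
# Native JSON dialect
# ---------------------------------------------------------------------------

def _model_to_dict(model: MetabolicModel) -> dict:
    return {
        "provenance": model.provenance,
        "mu_per_biomass_flux": model.mu_per_biomass_flux,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "formula": m.formula,
                "charge": m.charge,
                "compartment": m.compartment,
            }
            for m in model.metabolites.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": r.stoichiometry,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "is_exchange": r.is_exchange,
            }
            for r in model.reactions.values()
        ],
        "roles": dict(model.roles),
    }


def write_native_model(model: MetabolicModel, path) -> None:
    """Serialize to the native JSON dialect (deterministic field ordering)."""
    with open(path, "w") as fh:
        json.dump(_model_to_dict(model), fh, indent=1)
        fh.write("\n")


def read_native_model(path) -> MetabolicModel:
    with open(path) as fh:
        data = json.load(fh)
    for key in ("metabolites", "reactions"):
        if key not in data:
            raise SchemaError(f"native model file is missing the {key!r} key")
    model = MetabolicModel(
        provenance=data.get("provenance", ""),
        mu_per_biomass_flux=float(data.get("mu_per_biomass_flux", 1.0)),
    )
    for m in data["metabolites"]:
        try:
            model.add_metabolite(
                Metabolite(
                    id=m["id"],
                    name=m.get("name", ""),
                    formula={k: float(v) for k, v in m.get("formula", {}).items()},
                    charge=int(m.get("charge", 0)),
                    compartment=m.get("compartment", "c"),
                )
            )
        except KeyError as exc:
            raise SchemaError(f"metabolite entry missing key {exc}") from exc
    for r in data["reactions"]:
        try:
            model.add_reaction(
                Reaction(
                    id=r["id"],
                    name=r.get("name", ""),
                    stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
                    lower_bound=float(r["lower_bound"]),
                    upper_bound=float(r["upper_bound"]),
                    is_exchange=bool(r.get("is_exchange", False)),
                )
            )
        except KeyError as exc:
            raise SchemaError(f"reaction entry missing key {exc}") from exc
    for role, rid in data.get("roles", {}).items():
        model.set_role(role, rid)
    return model


def models_equal(a: MetabolicModel, b: MetabolicModel, tol: float = 0.0) -> bool:
    """Structural equality (ids, formulas, stoichiometry, bounds, roles)."""
    da, db = _model_to_dict(a), _model_to_dict(b)
    if tol == 0.0:
        return da == db
    return json.dumps(da, sort_keys=True) == json.dumps(db, sort_keys=True)
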