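"""Production-envelope computation and strain overlay.

The envelope of a model is traced by fixing glucose uptake, finding the
maximal growth rate, then at each point of a linear growth-fraction grid
fixing growth and minimising/maximising product secretion.  One envelope is
computed per bicarbonate setting — either a cap on the carbonic-anhydrase
formation flux (native CO2-derived supply) or an uptake allowance on the
bicarbonate exchange (external supplementation) — each expressed as a
dimensionless ratio to glucose uptake.

Yields are mass-based so fermentation endpoints plot on the same plane:
yield_product = v_p * MW_p / (|v_glc| * MW_glc), and the biomass yield uses
the Cmol mass of the declared biomass composition.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .fba import FluxSolution, fix_flux, flux_range_at_optimum, parsimonious_refine, set_bounds, solve_fba
from .model import MetabolicModel, ModelValidationError
from .pathway import UNBOUNDED, cap_bicarbonate_formation, enable_bicarbonate_uptake
from .units import CONSTANTS, formula_mass

MODES = ("formation_cap", "uptake_allowance", "none")


@dataclass
class EnvelopeSpec:
    glucose_uptake: float = 1.0          # mmol/gDCW/h (magnitude)
    n_growth_points: int = 21
    ratios: Sequence[float] = (UNBOUNDED,)
    mode: str = "formation_cap"          # applied to every ratio
    product: Optional[str] = None        # defaults to the product_exchange role

    def __post_init__(self) -> None:
        if self.n_growth_points < 2:
            raise ValueError("need at least 2 growth points")
        if any(r < 0 for r in self.ratios):
            raise ValueError("bicarbonate ratios must be >= 0")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")


@dataclass
class EnvelopePoint:
    growth_rate: float        # mu, 1/h
    growth_fraction: float    # mu / mu_max
    product_min: float
    product_max: float
    yield_product: float      # g product / g glucose at product_max
    yield_biomass: float      # g DCW / g glucose
    feasible: bool = True


@dataclass
class EnvelopeSweep:
    ratio: float
    mode: str
    mu_max: float
    points: List[EnvelopePoint]


@dataclass
class EnvelopeGrid:
    spec: EnvelopeSpec
    sweeps: List[EnvelopeSweep]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for sw in self.sweeps:
            for pt in sw.points:
                rows.append({
                    "ratio": sw.ratio, "mode": sw.mode,
                    "mu": pt.growth_rate, "growth_fraction": pt.growth_fraction,
                    "product_min": pt.product_min, "product_max": pt.product_max,
                    "yield_product": pt.yield_product,
                    "yield_biomass": pt.yield_biomass,
                    "feasible": pt.feasible,
                })
        return pd.DataFrame(rows)

    def upper_yield(self, sweep: EnvelopeSweep, yield_biomass: float) -> float:
        """Maximal product yield of one sweep at a biomass yield, by linear
        interpolation; -inf beyond the attainable biomass range."""
        pts = [p for p in sweep.points if p.feasible]
        xb = np.array([p.yield_biomass for p in pts])
        yp = np.array([p.yield_product for p in pts])
        order = np.argsort(xb)
        xb, yp = xb[order], yp[order]
        if yield_biomass > xb[-1] + 1e-12:
            return -math.inf
        return float(np.interp(yield_biomass, xb, yp))


def _apply_bicarbonate(model: MetabolicModel, ratio: float, mode: str,
                       glucose_uptake: float) -> MetabolicModel:
    if mode == "formation_cap":
        return cap_bicarbonate_formation(model, ratio, glucose_uptake)
    if mode == "uptake_allowance":
        return enable_bicarbonate_uptake(model, ratio, glucose_uptake)
    return model.copy()


def _mass_ratio(model: MetabolicModel, product_rxn: str) -> Tuple[float, float]:
    """(MW_product, MW_glucose) from the exchanged metabolites' formulas."""
    prod = model.reactions[product_rxn]
    pm = next(iter(prod.stoichiometry))
    glc = model.role_reaction("glucose_exchange")
    gm = next(iter(glc.stoichiometry))
    return (model.metabolites[pm].molar_mass(), model.metabolites[gm].molar_mass())


def compute_envelope(model: MetabolicModel, spec: EnvelopeSpec | None = None) -> EnvelopeGrid:
    """Sweep the production envelope for each bicarbonate setting.

    Growth grid is linear in growth fraction over [0, 1]; the maximal growth
    rate is recomputed per ratio, since bicarbonate caps can lower it.
    Infeasible grid points are retried once with growth relaxed by 1e-9 and
    otherwise marked infeasible, never dropped.
    """
    spec = spec or EnvelopeSpec()
    product = spec.product or model.roles.get("product_exchange")
    if product is None:
        raise ModelValidationError("product reaction not set (role product_exchange)")
    biomass_id = model.roles.get("biomass")
    if biomass_id is None:
        raise ModelValidationError("biomass role not set")
    glc_id = model.role_reaction("glucose_exchange").id
    mw_p, mw_s = _mass_ratio(model, product)
    mass_glc = spec.glucose_uptake * mw_s  # mg glucose /gDCW/h

    sweeps: List[EnvelopeSweep] = []
    for ratio in spec.ratios:
        m = _apply_bicarbonate(model, ratio, spec.mode, spec.glucose_uptake)
        m = fix_flux(m, glc_id, -spec.glucose_uptake)
        growth_sol = solve_fba(m, biomass_id, "max")
        if not growth_sol.optimal:
            raise ModelValidationError(
                f"model infeasible when maximising growth (ratio={ratio}): "
                f"{growth_sol.status}")
        # biomass flux is non-negative by construction; clamp -0.0 LP noise
        v_bio_max = max(0.0, growth_sol.objective_value)
        mu_max = v_bio_max * m.mu_per_biomass_flux
        points: List[EnvelopePoint] = []
        for frac in np.linspace(0.0, 1.0, spec.n_growth_points):
            v_bio = frac * v_bio_max
            mg = fix_flux(m, biomass_id, v_bio)
            lo = solve_fba(mg, product, "min")
            hi = solve_fba(mg, product, "max")
            if not (lo.optimal and hi.optimal):
                # numerical edge near mu_max: retry with growth slightly relaxed
                mg = set_bounds(m, biomass_id, max(0.0, v_bio - 1e-9), v_bio)
                lo = solve_fba(mg, product, "min")
                hi = solve_fba(mg, product, "max")
            feasible = lo.optimal and hi.optimal
            pmin = lo.objective_value if feasible else math.nan
            pmax = hi.objective_value if feasible else math.nan
            mu = v_bio * m.mu_per_biomass_flux
            points.append(EnvelopePoint(
                growth_rate=mu,
                growth_fraction=frac,
                product_min=pmin,
                product_max=pmax,
                yield_product=(pmax * mw_p / mass_glc) if feasible else math.nan,
                yield_biomass=mu * 1000.0 / mass_glc,
                feasible=feasible,
            ))
        sweeps.append(EnvelopeSweep(ratio=ratio, mode=spec.mode,
                                    mu_max=mu_max, points=points))
    return EnvelopeGrid(spec=spec, sweeps=sweeps)


@dataclass
class YieldResult:
    mol_per_mol: float
    g_per_g: float


def max_theoretical_yield(model: MetabolicModel, glucose_uptake: float = 1.0,
                          product: Optional[str] = None) -> YieldResult:
    """Maximal product yield at zero growth under the model's current
    bicarbonate setting, in mol/mol and g/g."""
    product = product or model.role_reaction("product_exchange").id
    glc_id = model.role_reaction("glucose_exchange").id
    m = fix_flux(model, glc_id, -glucose_uptake)
    if "biomass" in m.roles:
        m = fix_flux(m, m.roles["biomass"], 0.0)
    sol = solve_fba(m, product, "max")
    if not sol.optimal:
        raise ModelValidationError(f"product optimisation {sol.status}")
    molar = sol.objective_value / glucose_uptake
    mw_p, mw_s = _mass_ratio(model, product)
    return YieldResult(mol_per_mol=molar, g_per_g=molar * mw_p / mw_s)


@dataclass
class BicarbonateDemand:
    ratio: float          # (formation + uptake flux) / |glucose uptake|
    fva_min: float        # variability of the formation flux at the optimum
    fva_max: float


def bicarbonate_ratio_at_optimum(model: MetabolicModel,
                                 glucose_uptake: float = 1.0) -> BicarbonateDemand:
    """Bicarbonate supply per glucose at the zero-growth product optimum.

    The reported ratio uses the parsimonious optimum (canonical
    representative); the flux-variability range of the formation flux over
    the optimal face is reported alongside.
    """
    product = model.role_reaction("product_exchange").id
    glc_id = model.role_reaction("glucose_exchange").id
    form_id = model.role_reaction("bicarbonate_formation").id
    m = fix_flux(model, glc_id, -glucose_uptake)
    if "biomass" in m.roles:
        m = fix_flux(m, m.roles["biomass"], 0.0)
    sol = parsimonious_refine(m, product, "max")
    if not sol.optimal:
        raise ModelValidationError(f"product optimisation {sol.status}")
    formation = max(sol.fluxes.get(form_id, 0.0), 0.0)
    uptake = 0.0
    if "bicarbonate_exchange" in m.roles:
        uptake = max(-sol.fluxes.get(m.roles["bicarbonate_exchange"], 0.0), 0.0)
    lo, hi = flux_range_at_optimum(m, product, form_id)
    return BicarbonateDemand(ratio=(formation + uptake) / glucose_uptake,
                             fva_min=lo, fva_max=hi)


# ---------------------------------------------------------------------------
# Strain overlay
# ---------------------------------------------------------------------------


@dataclass
class StrainPlacement:
    strain: str
    yield_product: float
    yield_biomass: float
    classification: Dict[Tuple[float, str], str]  # (ratio, mode) -> inside/on/outside


@dataclass
class OverlayReport:
    placements: List[StrainPlacement]
    warnings: List[str] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for p in self.placements:
            row = {"strain": p.strain, "yield_product": p.yield_product,
                   "yield_biomass": p.yield_biomass}
            for (ratio, mode), cls in p.classification.items():
                row[f"vs_ratio_{ratio}_{mode}"] = cls
            rows.append(row)
        return pd.DataFrame(rows)


def overlay_strains(grid: EnvelopeGrid, table, od_to_dcw_factor: float | None = None,
                    tol: float = 1e-3) -> OverlayReport:
    """Map fermentation endpoints onto the envelope plane and classify each
    against each sweep's upper envelope.

    ``table`` is a DataFrame (or StrainTable) with columns ``strain``,
    ``titre_g_l``, ``glucose_g_l`` and either ``dcw_g_l`` or ``od600``; DCW
    is imputed as 0.7 x OD600 when absent.
    """
    factor = od_to_dcw_factor if od_to_dcw_factor is not None else CONSTANTS.od_to_dcw_factor
    df = getattr(table, "data", table)
    placements, warns = [], []
    # the most permissive sweep bounds what is attainable at all
    best = max(grid.sweeps, key=lambda sw: max(
        (p.yield_product for p in sw.points if p.feasible), default=-math.inf))
    for _, row in df.iterrows():
        glucose = float(row["glucose_g_l"])
        if glucose <= 0:
            raise ValueError(f"strain {row['strain']}: glucose consumed must be > 0")
        yp = float(row["titre_g_l"]) / glucose
        dcw = row.get("dcw_g_l")
        if dcw is None or (isinstance(dcw, float) and math.isnan(dcw)):
            od = row.get("od600")
            if od is None or (isinstance(od, float) and math.isnan(od)):
                raise ValueError(f"strain {row['strain']}: needs dcw_g_l or od600")
            dcw = factor * float(od)
        yb = float(dcw) / glucose
        classification = {}
        for sw in grid.sweeps:
            env = grid.upper_yield(sw, yb)
            if yp > env + tol:
                cls = "outside"
            elif yp >= env - tol:
                cls = "on"
            else:
                cls = "inside"
            classification[(sw.ratio, sw.mode)] = cls
        if classification[(best.ratio, best.mode)] == "outside":
            msg = (f"strain {row['strain']} lies outside the most permissive "
                   f"envelope (ratio={best.ratio}, mode={best.mode})")
            warns.append(msg)
            warnings.warn(msg, stacklevel=2)
        placements.append(StrainPlacement(str(row["strain"]), yp, yb, classification))
    return OverlayReport(placements=placements, warnings=warns)


def plot_envelope(grid: EnvelopeGrid, overlay: OverlayReport | None = None, path=None):
    """Plot product yield vs biomass yield, one curve pair per sweep, with
    optional strain endpoints, in the layout of a phenotype phase plane."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    for sw in grid.sweeps:
        pts = [p for p in sw.points if p.feasible]
        xb = [p.yield_biomass for p in pts]
        label = f"ratio={'unbounded' if math.isinf(sw.ratio) else sw.ratio} ({sw.mode})"
        ax.plot(xb, [p.yield_product for p in pts], "-o", ms=3, label=label)
    if overlay is not None:
        ax.scatter([p.yield_biomass for p in overlay.placements],
                   [p.yield_product for p in overlay.placements],
                   marker="D", c="k", zorder=5, label="strains")
        for p in overlay.placements:
            ax.annotate(p.strain, (p.yield_biomass, p.yield_product),
                        fontsize=7, xytext=(3, 3), textcoords="offset points")
    ax.set_xlabel("biomass yield (g DCW / g glucose)")
    ax.set_ylabel("3-HP yield (g / g glucose)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
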