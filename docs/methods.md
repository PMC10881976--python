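# Methods

## Model and optimisation

All analyses are standard constraint-based modelling: a flux vector
*v* (mmol/gDCW/h) over the reactions of a stoichiometric model must satisfy
steady state *S·v = 0* within flux bounds, and quantities of interest are
linear-programming optima of single reaction fluxes.  The LP backend is
HiGHS (through `scipy.optimize.linprog`) with primal and dual feasibility
tolerances of 1e-9; objective values are reported at 1e-6 precision.  Sign
convention: exchange fluxes are negative for uptake, positive for
secretion.

LPs generically have alternate optimal flux distributions.  Wherever a
single flux value is reported (e.g. the bicarbonate flux at the product
optimum), it comes from a parsimonious refinement — the objective is fixed
at its optimum (within 1e-9 relative) and the total flux Σ|v| is minimised
via the standard split of each flux into non-negative forward and reverse
parts.  Wherever the ambiguity itself matters, the flux-variability range
over the optimal face is reported instead.  Objective *values* are
solver-independent for these LPs; flux *vectors* are not, which is why the
package never claims a unique flux distribution, only a canonical one.

## Production envelopes

Glucose uptake is fixed (default 1 mmol/gDCW/h), the maximal growth rate is
found by FBA, and at each of *n* points on a linear growth-fraction grid
over [0, 1] the product secretion is minimised and maximised.  The maximal
growth rate is recomputed per bicarbonate setting, since tight caps lower
it.  Two bicarbonate modes are swept: a cap on the carbonic-anhydrase
CO2 → HCO3⁻ flux (native, CO2-derived supply) and an uptake allowance on
the bicarbonate exchange (medium supplementation), each expressed as a
ratio to glucose uptake.  Grid points that come back infeasible (a
numerical edge case at the very top of the growth range) are retried once
with the growth flux relaxed by 1e-9 and otherwise marked infeasible rather
than dropped.

Axes are mass yields so that fermentation endpoints and model envelopes
share a plane: product yield = v_p·MW_p/(|v_glc|·MW_glc) with molar masses
computed from metabolite formulas; biomass yield = μ·1000/(|v_glc|·MW_glc)
with μ in 1/h.  For models whose biomass flux is expressed per Cmol (the
bundled core model), μ = v_biomass·M_biomass/1000 with M_biomass computed
from the composition CH1.8O0.5N0.2 (≈24.63 g/Cmol); genome-scale models
whose biomass flux is already the growth rate use a scale factor of 1.

Strain endpoints are mapped as titre/glucose and DCW/glucose, with DCW
imputed as 0.7 × OD600 when only OD was measured.  Classification against
an envelope interpolates the upper curve at the strain's biomass yield and
uses a tolerance of 1e-3 g/g for "on" — the scale of the differences that
matter in this analysis.

## The core model

The bundled model is a curated ~45-reaction lumped network, not a reduction
of a genome-scale reconstruction.  Lumping granularity was chosen so that
every flux the bicarbonate argument touches is an individually boundable
reaction: glycolysis (net 2 ATP + 2 NADH per glucose), the oxidative
pentose-phosphate branch (2 NADPH + 1 CO2 per hexose phosphate, with a
reversible non-oxidative rearrangement 3 X5P ↔ 2 F6P + GAP), the
phosphoketolase bypass (X5P → acetyl-phosphate + GAP; acetyl-CoA without
decarboxylation), the pyruvate node (PDH, the PDH bypass via
acetaldehyde/acetate with its 2-ATP acetyl-CoA activation cost, ethanol
fermentation, glycerol formation as the anaerobic NADH sink, pyruvate
carboxylase consuming HCO3⁻), a lumped TCA cycle (1 ATP-equivalent +
3 NADH + 1 FADH2 per acetyl-CoA), oxidative phosphorylation crediting P/O
ATP per NADH and per FADH2, carbonic anhydrase CO2 ↔ HCO3⁻, a Sul1-like
influx-only bicarbonate transporter, Acc1, and an ATP-dissipation reaction.

Elemental bookkeeping uses a carrier convention that avoids an explicit
proton species: NAD(P)H = NAD(P) + H2, FADH2 = FAD + H2, ATP = ADP + HPO3,
Pi = H3PO4, and bicarbonate is carried as the carbonic-acid lump CH2O3.
Under this convention every internal reaction balances exactly in
{C,H,O,N,P,S}, and the validator enforces it; the biomass pseudo-reaction
is exempt from the full check but is carbon-audited.

The biomass reaction produces one Cmol of CH1.8O0.5N0.2 from 0.2 G6P +
0.075 OAA + 0.2 NH3 + 0.3 NADPH, releasing 0.5 CO2 (1.5 Cmol in per Cmol
out — a biomass yield of ~0.55 g/g before maintenance, a realistic aerobic
yeast figure) and returning the sugar phosphate's Pi.  Routing OAA through
biomass gives pyruvate carboxylase, the competing bicarbonate consumer, a
physiological sink; at zero growth it is structurally silent, which is why
the bicarbonate demand at the product optimum has zero flux variability.
Growth-associated maintenance defaults to 30 mmol ATP/gDCW (embedded in the
biomass reaction); non-growth maintenance defaults to 0 — maintenance
energetics are conventional defaults, not fitted values.

With P/O = 1 the model's full respiratory budget is 16 mol ATP/mol glucose
(4 substrate-level + 10 NADH + 2 FADH2 at 1 ATP each), and 22 at P/O = 1.5
— an exact consequence of the lumped stoichiometry, verifiable by hand.
The model's unconstrained maximum 3-HP yield is 1.737 mol/mol
(0.868 g/g); this is the core model's own number and is *not* a substitute
for the theoretical yield of a genome-scale yeast model, which depends on
the full network.  Genome-scale analyses load the published SBML file via
`read_sbml` with role ids supplied in config; any reproduction should
record the model release used, since published reconstructions evolve.

## Synthetic data: what it emulates and what it does not

The toy branch model (substrate splitting 1:1 between product and biomass,
all species CH2O) has the closed-form envelope
yield = Ymax·(1 − growth fraction); it is the independent oracle for the
envelope sweep machinery.  The strain-table generator perturbs known
ground-truth yields with multiplicative Gaussian noise of chosen CV under
an explicit seed (no global random state), clipping negative draws at zero
with a warning.  Passing the recovery tests therefore shows that the
overlay arithmetic is exact and unbiased under symmetric measurement
noise; it says nothing about real fermentation error structure
(evaporation, sampling loss, correlated OD–DCW errors), which the
generator does not attempt to model.  The core model likewise encodes no
regulation (glucose repression, Acc1 phosphorylation, transcription-factor
effects) — only stoichiometric capability, which is exactly what an
envelope claims.

## Numerical choices and degenerate inputs

- Feasibility/optimality tolerances 1e-9; steady-state residuals of
  accepted solutions ≤1e-6; bound satisfaction checked to 1e-9.
- Infeasible or unbounded LPs return a status, never raise; only
  structurally broken inputs (unknown reactions, inverted bounds,
  unresolved roles) raise.
- "Unbounded" flux is represented as ±1000 mmol/gDCW/h, far above any
  attainable flux at glucose uptake 1.
- A bicarbonate ratio of 0 closes the supply entirely; on the core model
  this also makes growth infeasible (biomass needs carboxylation-derived
  OAA), so the ratio-0 envelope is the degenerate point μ = 0, product = 0.
- Carbonate constants are apparent (no activity corrections): pKa1 6.06,
  pKa2 10.33, kH 0.039 mol/(L·atm) near 20 °C, pCO2 4.0e-4 atm.  The
  frequently quoted air-equilibrium pair (0.012 mM CO2, 0.26 mM HCO3⁻ at
  pH 7.4) is internally consistent with pKa1 ≈ 6.06; the package treats
  this as a consistency check, not an assertion about any particular
  published constant set.

## Design choices that were genuinely open

- Both MCR reduction steps default to NADPH (the enzyme's cofactor in its
  source organism) but are configurable, since host-model cofactor usage is
  a modelling decision; the pathway is placed in the cytosol and the 3-HP
  exchange is secretion-only (no re-uptake).
- The bicarbonate transporter in the core model is influx-only.  An efflux
  path would create a zero-cost CO2-uptake → bicarbonate-secretion cycle
  that inflates flux-variability ranges without physical meaning.
- Problem sizes in tests and the acceptance script (9–21 grid points,
  50–200 synthetic strains) were chosen as the smallest sizes at which the
  checked properties are non-trivial; envelopes at finer grids agree
  exactly at shared points, which is itself a tested invariant.

## Known limitations

- SBML support is read-only and limited to species/reactions/FBC bounds;
  groups, layout and kinetics are ignored (with a log line).  No SBML
  writing.
- No MILP (knockout design), no flux sampling, no thermodynamic or kinetic
  feasibility: the claim that bicarbonate-dependent carboxylation is
  thermodynamically favourable is outside what stoichiometry can show.
- Lumped reactions mean intracellular flux values are not comparable
  reaction-by-reaction with genome-scale models; only exchange fluxes,
  yields and the envelope geometry are.
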