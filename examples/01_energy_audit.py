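"""Energy audit of the core model: ATP yield per glucose.

Builds the yeast central-carbon core model, fixes glucose uptake at
1 mmol/gDCW/h and growth at zero, and maximises the ATP-dissipation flux.
With a P/O ratio of 1 the optimum is 16 mol ATP/mol glucose (4 from
substrate-level phosphorylation, 12 from respiring 10 NADH + 2 FADH2);
raising P/O shows how strongly the total depends on respiratory coupling.
"""

import bicarbenv as bv

for po in (1.0, 1.5):
    model = bv.build_core_model(bv.CoreModelConfig(po_ratio=po))
    model = bv.fix_flux(model, "EX_glc", -1.0)
    model = bv.fix_flux(model, "BIOMASS", 0.0)
    solution = bv.solve_fba(model, "ATPM", "max")
    print(f"P/O = {po}: {solution.objective_value:.1f} mol ATP / mol glucose")
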