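"""Inorganic-carbon speciation at cytosolic pH.

At near-neutral pH, dissolved inorganic carbon is predominantly bicarbonate:
the reason intracellular HCO3- supply (not dissolved CO2) is treated as the
carboxylation substrate pool.  The script prints the equilibrium state for
air-equilibrated water at pH 7.4 and the fraction profile across pH.
"""

import bicarbenv as bv

params = bv.CarbonateParams(ph=7.4)
state = bv.speciate(params)
print(f"pH {params.ph}, pCO2 {params.pco2} atm:")
print(f"  CO2(aq) {state.co2_mM:.4f} mM | HCO3- {state.hco3_mM:.4f} mM "
      f"| CO3^2- {state.co3_mM:.6f} mM")
f = state.fractions
print(f"  fractions: CO2 {f[0]:.3f}, HCO3- {f[1]:.3f}, CO3^2- {f[2]:.5f}")

print("\npH sweep (fraction of DIC as bicarbonate):")
for ph in (5.0, 6.06, 7.0, 7.4, 8.0):
    _, f_hco3, _ = bv.species_fractions(ph, params.pka1, params.pka2)
    print(f"  pH {ph:4.2f}: {f_hco3:.3f}")
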