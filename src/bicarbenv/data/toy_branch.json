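{
 "provenance": "toy branch model",
 "mu_per_biomass_flux": 0.030026,
 "metabolites": [
  {
   "id": "S_e",
   "name": "S_e",
   "formula": {
    "C": 1,
    "H": 2,
    "O": 1
   },
   "charge": 0,
   "compartment": "e"
  },
  {
   "id": "S",
   "name": "S",
   "formula": {
    "C": 1,
    "H": 2,
    "O": 1
   },
   "charge": 0,
   "compartment": "c"
  },
  {
   "id": "P",
   "name": "P",
   "formula": {
    "C": 1,
    "H": 2,
    "O": 1
   },
   "charge": 0,
   "compartment": "c"
  },
  {
   "id": "P_e",
   "name": "P_e",
   "formula": {
    "C": 1,
    "H": 2,
    "O": 1
   },
   "charge": 0,
   "compartment": "e"
  },
  {
   "id": "X",
   "name": "X",
   "formula": {
    "C": 1,
    "H": 2,
    "O": 1
   },
   "charge": 0,
   "compartment": "c"
  }
 ],
 "reactions": [
  {
   "id": "EX_S",
   "name": "S exchange",
   "stoichiometry": {
    "S_e": -1
   },
   "lower_bound": -1.0,
   "upper_bound": 0.0,
   "is_exchange": true
  },
  {
   "id": "St",
   "name": "S uptake",
   "stoichiometry": {
    "S_e": -1,
    "S": 1
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "is_exchange": false
  },
  {
   "id": "SP",
   "name": "S -> P",
   "stoichiometry": {
    "S": -1,
    "P": 1
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "is_exchange": false
  },
  {
   "id": "SX",
   "name": "S -> biomass",
   "stoichiometry": {
    "S": -1,
    "X": 1
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "is_exchange": false
  },
  {
   "id": "Pt",
   "name": "P export",
   "stoichiometry": {
    "P": -1,
    "P_e": 1
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "is_exchange": false
  },
  {
   "id": "EX_P",
   "name": "P exchange",
   "stoichiometry": {
    "P_e": -1
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "is_exchange": true
  },
  {
   "id": "EX_X",
   "name": "biomass drain",
   "stoichiometry": {
    "X": -1
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "is_exchange": true
  }
 ],
 "roles": {
  "glucose_exchange": "EX_S",
  "product_exchange": "EX_P",
  "biomass": "SX"
 }
}
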