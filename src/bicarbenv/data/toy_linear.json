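{
 "provenance": "toy linear chain",
 "mu_per_biomass_flux": 1.0,
 "metabolites": [
  {
   "id": "A_e",
   "name": "A_e",
   "formula": {
    "C": 1,
    "H": 2,
    "O": 1
   },
   "charge": 0,
   "compartment": "e"
  },
  {
   "id": "A",
   "name": "A",
   "formula": {
    "C": 1,
    "H": 2,
    "O": 1
   },
   "charge": 0,
   "compartment": "c"
  },
  {
   "id": "B",
   "name": "B",
   "formula": {
    "C": 1,
    "H": 2,
    "O": 1
   },
   "charge": 0,
   "compartment": "c"
  },
  {
   "id": "B_e",
   "name": "B_e",
   "formula": {
    "C": 1,
    "H": 2,
    "O": 1
   },
   "charge": 0,
   "compartment": "e"
  }
 ],
 "reactions": [
  {
   "id": "EX_A",
   "name": "A exchange",
   "stoichiometry": {
    "A_e": -1
   },
   "lower_bound": -1.0,
   "upper_bound": 0.0,
   "is_exchange": true
  },
  {
   "id": "At",
   "name": "A uptake",
   "stoichiometry": {
    "A_e": -1,
    "A": 1
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "is_exchange": false
  },
  {
   "id": "AB",
   "name": "A -> B",
   "stoichiometry": {
    "A": -1,
    "B": 1
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "is_exchange": false
  },
  {
   "id": "Bt",
   "name": "B export",
   "stoichiometry": {
    "B": -1,
    "B_e": 1
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "is_exchange": false
  },
  {
   "id": "EX_B",
   "name": "B exchange",
   "stoichiometry": {
    "B_e": -1
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "is_exchange": true
  }
 ],
 "roles": {
  "glucose_exchange": "EX_A",
  "product_exchange": "EX_B"
 }
}
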