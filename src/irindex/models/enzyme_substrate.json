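{
  "species": [
    {"name": "E", "initial_value": 10.0},
    {"name": "S", "initial_value": 0.0},
    {"name": "ES", "initial_value": 0.0},
    {"name": "P", "initial_value": 0.0}
  ],
  "parameters": [
    {"name": "k_on", "value": 1.0, "unit": "1/nM/min"},
    {"name": "k_off", "value": 400.0, "unit": "1/min"},
    {"name": "k_cat", "value": 10.0, "unit": "1/min"},
    {"name": "k_deg_P", "value": 1.0, "unit": "1/min"}
  ],
  "reactions": [
    {
      "id": "binding",
      "reactants": [{"species": "E", "stoichiometry": 1}, {"species": "S", "stoichiometry": 1}],
      "products": [{"species": "ES", "stoichiometry": 1}],
      "rate_law": "k_on * E * S"
    },
    {
      "id": "unbinding",
      "reactants": [{"species": "ES", "stoichiometry": 1}],
      "products": [{"species": "E", "stoichiometry": 1}, {"species": "S", "stoichiometry": 1}],
      "rate_law": "k_off * ES"
    },
    {
      "id": "catalysis",
      "reactants": [{"species": "ES", "stoichiometry": 1}],
      "products": [{"species": "E", "stoichiometry": 1}, {"species": "P", "stoichiometry": 1}],
      "rate_law": "k_cat * ES"
    },
    {
      "id": "deg_P",
      "reactants": [{"species": "P", "stoichiometry": 1}],
      "products": [],
      "rate_law": "k_deg_P * P"
    }
  ],
  "metadata": {
    "time_unit": "min",
    "concentration_unit": "nM",
    "description": "Michaelis-Menten binding network: enzyme E converts a substrate pulse S into product P through a fast-equilibrating complex ES."
  }
}
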