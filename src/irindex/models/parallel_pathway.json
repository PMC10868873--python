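{
  "species": [
    {"name": "A", "initial_value": 0.0},
    {"name": "E1", "initial_value": 10.0},
    {"name": "C1", "initial_value": 0.0},
    {"name": "E2", "initial_value": 10.0},
    {"name": "C2", "initial_value": 0.0},
    {"name": "D", "initial_value": 0.0}
  ],
  "parameters": [
    {"name": "k_on1", "value": 2.0, "unit": "1/nM/min"},
    {"name": "k_cat1", "value": 20.0, "unit": "1/min"},
    {"name": "k_on2", "value": 2.0, "unit": "1/nM/min"},
    {"name": "k_cat2", "value": 20.0, "unit": "1/min"},
    {"name": "k_deg_D", "value": 1.0, "unit": "1/min"}
  ],
  "reactions": [
    {
      "id": "bind1",
      "reactants": [{"species": "A", "stoichiometry": 1}, {"species": "E1", "stoichiometry": 1}],
      "products": [{"species": "C1", "stoichiometry": 1}],
      "rate_law": "k_on1 * A * E1"
    },
    {
      "id": "cat1",
      "reactants": [{"species": "C1", "stoichiometry": 1}],
      "products": [{"species": "E1", "stoichiometry": 1}, {"species": "D", "stoichiometry": 1}],
      "rate_law": "k_cat1 * C1"
    },
    {
      "id": "bind2",
      "reactants": [{"species": "A", "stoichiometry": 1}, {"species": "E2", "stoichiometry": 1}],
      "products": [{"species": "C2", "stoichiometry": 1}],
      "rate_law": "k_on2 * A * E2"
    },
    {
      "id": "cat2",
      "reactants": [{"species": "C2", "stoichiometry": 1}],
      "products": [{"species": "E2", "stoichiometry": 1}, {"species": "D", "stoichiometry": 1}],
      "rate_law": "k_cat2 * C2"
    },
    {
      "id": "deg_D",
      "reactants": [{"species": "D", "stoichiometry": 1}],
      "products": [],
      "rate_law": "k_deg_D * D"
    }
  ],
  "metadata": {
    "time_unit": "min",
    "concentration_unit": "nM",
    "description": "Two kinetically equivalent adaptor routes convert the signal A into the response D; either route alone can carry the full signal (compensation)."
  }
}
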