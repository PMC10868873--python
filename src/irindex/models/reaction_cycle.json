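{
  "species": [
    {"name": "A", "initial_value": 0.0},
    {"name": "B", "initial_value": 100.0},
    {"name": "C", "initial_value": 5.0},
    {"name": "D", "initial_value": 0.0}
  ],
  "parameters": [
    {"name": "k_on", "value": 2.5, "unit": "1/nM/min"},
    {"name": "k_act", "value": 100.0, "unit": "1/min"},
    {"name": "k_rec", "value": 0.1, "unit": "1/min"},
    {"name": "k_deg_A", "value": 1.0, "unit": "1/min"},
    {"name": "k_deg_C", "value": 0.0, "unit": "1/min"},
    {"name": "k_deg_D", "value": 3.0, "unit": "1/min"}
  ],
  "reactions": [
    {
      "id": "transformation",
      "reactants": [{"species": "A", "stoichiometry": 1}, {"species": "B", "stoichiometry": 1}],
      "products": [{"species": "A", "stoichiometry": 1}, {"species": "C", "stoichiometry": 1}],
      "rate_law": "k_on * A * B"
    },
    {
      "id": "activation",
      "reactants": [{"species": "C", "stoichiometry": 1}],
      "products": [{"species": "D", "stoichiometry": 1}],
      "rate_law": "k_act * C"
    },
    {
      "id": "recycling",
      "reactants": [{"species": "D", "stoichiometry": 1}],
      "products": [{"species": "B", "stoichiometry": 1}],
      "rate_law": "k_rec * D"
    },
    {
      "id": "deg_A",
      "reactants": [{"species": "A", "stoichiometry": 1}],
      "products": [],
      "rate_law": "k_deg_A * A"
    },
    {
      "id": "deg_C",
      "reactants": [{"species": "C", "stoichiometry": 1}],
      "products": [],
      "rate_law": "k_deg_C * C"
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
    "description": "Reaction cycle: the signal A catalyses transformation of the substrate B into the intermediate C, which activates the response D; D recycles back to B, closing the cycle B->C->D->B. A, C and D may degrade."
  }
}
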