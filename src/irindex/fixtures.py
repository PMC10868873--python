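"""Bundled fixture models and their index-analysis experiments.

Three small networks exercise every part of the analysis:

``reaction_cycle``
    Signal A binds substrate B into a complex C that either dissociates or
    activates the response D while recycling A; A, C and D may degrade.
    Input A, response D, baseline (A, B, C, D) = (0, 100, 5, 0) nM with a
    2 nM delta input on A.  Three parameter scenarios change which states
    are dynamically important: in scenario 1 the complex C is fast (partial
    steady state) while A, B and D carry the dynamics; in scenario 2 the
    complex is slow and every state is dynamic; in scenario 3 the signal
    degrades quickly, leaving the substrate pool B almost untouched
    (environmental) and C again fast.
``parallel_pathway``
    Two kinetically equivalent adaptor routes convert the signal into the
    response; knocking out either route alone barely changes the output
    (the other compensates) while the joint knockout silences it.
``enzyme_substrate``
    A Michaelis-Menten binding network whose complex ES is classifiable as
    partial steady state when dissociation is fast against turnover.

The time span of the reaction-cycle scenarios is [0, 10] min, the window on
which the documented index behaviour (interim values near 2 min, decay over
~10 min) unfolds.
"""

from __future__ import annotations

import importlib.resources as resources
import json

from .experiment import IOExperiment
from .network import ReactionNetwork, build_network

__all__ = ["FIXTURES", "FixtureLookupError", "fixture"]


class FixtureLookupError(KeyError):
    """Unknown fixture name or scenario."""


#: scenario-specific rate constants of the reaction cycle (1/min; k_on 1/nM/min)
REACTION_CYCLE_SCENARIOS = {
    1: {"k_on": 2.5, "k_act": 100.0, "k_rec": 0.1,
        "k_deg_A": 1.0, "k_deg_C": 0.0, "k_deg_D": 3.0},
    2: {"k_on": 2.5, "k_act": 1.0, "k_rec": 0.1,
        "k_deg_A": 1.0, "k_deg_C": 0.0, "k_deg_D": 3.0},
    3: {"k_on": 8.0, "k_act": 320.0, "k_rec": 200.0,
        "k_deg_A": 10.0, "k_deg_C": 0.0, "k_deg_D": 10.0},
}

_EXPERIMENTS = {
    "reaction_cycle": {"input": "A", "response": "D", "u0": 2.0, "t_end": 10.0},
    "parallel_pathway": {"input": "A", "response": "D", "u0": 5.0, "t_end": 10.0},
    "enzyme_substrate": {"input": "S", "response": "P", "u0": 20.0, "t_end": 10.0},
}

FIXTURES = tuple(_EXPERIMENTS)


def _load_model(name: str) -> ReactionNetwork:
    path = resources.files("irindex.models").joinpath(f"{name}.json")
    return build_network(json.loads(path.read_text()))


def fixture(name: str, scenario: int | None = None) -> tuple[ReactionNetwork, IOExperiment]:
    """Return ``(network, experiment)`` for a bundled fixture.

    ``scenario`` selects the reaction-cycle parameter set (1-3) and is
    meaningless for the other fixtures.
    """
    if name not in _EXPERIMENTS:
        raise FixtureLookupError(
            f"unknown fixture {name!r}; available: {sorted(_EXPERIMENTS)}"
        )
    net = _load_model(name)
    if name == "reaction_cycle":
        if scenario is None:
            scenario = 1
        if scenario not in REACTION_CYCLE_SCENARIOS:
            raise FixtureLookupError(
                f"unknown reaction_cycle scenario {scenario!r}; "
                f"available: {sorted(REACTION_CYCLE_SCENARIOS)}"
            )
        net = net.with_params(REACTION_CYCLE_SCENARIOS[scenario])
    elif scenario is not None:
        raise FixtureLookupError(f"fixture {name!r} has no scenarios")

    rec = _EXPERIMENTS[name]
    exp = IOExperiment(
        input_species=net.index(rec["input"]),
        response_species=net.index(rec["response"]),
        input_magnitude=rec["u0"],
        baseline_state=net.initial_state,
        t0=0.0,
        t_end=rec["t_end"],
    )
    return net, exp
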