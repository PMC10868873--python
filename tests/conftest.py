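"""Shared fixtures.

The classification pipelines are the expensive part of the suite (tens of
seconds each), so they are computed once per session and shared between the
unit tests and the acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import irindex as ix


@pytest.fixture(scope="session")
def cycle1():
    net, exp = ix.fixture("reaction_cycle", 1)
    return net, exp


@pytest.fixture(scope="session")
def cycle1_ref(cycle1):
    net, exp = cycle1
    return ix.simulate(net, exp.stimulated_state, exp.window)


@pytest.fixture(scope="session")
def scenario_analysis(cycle1, cycle1_ref):
    """report+artifacts per reaction-cycle scenario, computed once."""
    out = {}
    net, exp = cycle1
    out[1] = ix.run_classification(net, exp, ref=cycle1_ref)
    for scen in (2, 3):
        net, exp = ix.fixture("reaction_cycle", scen)
        out[scen] = ix.run_classification(net, exp)
    return out


@pytest.fixture(scope="session")
def enzyme_analysis():
    net, exp = ix.fixture("enzyme_substrate")
    report, art = ix.run_classification(net, exp)
    return net, exp, report, art


@pytest.fixture(scope="session")
def parallel_knockouts():
    net, exp = ix.fixture("parallel_pathway")
    ref = ix.simulate(net, exp.stimulated_state, exp.window)
    p1 = [net.index("E1"), net.index("C1")]
    p2 = [net.index("E2"), net.index("C2")]
    errs = {}
    for kind in ("pneg", "cneg"):
        errs[kind] = {
            "single1": ix.knockout_relative_error(net, ref, exp, kind, p1),
            "single2": ix.knockout_relative_error(net, ref, exp, kind, p2),
            "joint": ix.knockout_relative_error(net, ref, exp, kind, p1 + p2),
        }
    return net, exp, ref, errs


@pytest.fixture()
def rng():
    return np.random.default_rng(20240205)


def linear_decay_chain(k1: float = 1.3, k2: float = 0.0) -> ix.ReactionNetwork:
    """dx1/dt = -k1 x1, dx2/dt = k1 x1 - k2 x2 (closed for k2=0)."""
    return ix.build_network(
        {
            "species": [
                {"name": "X1", "initial_value": 5.0},
                {"name": "X2", "initial_value": 0.0},
            ],
            "parameters": [
                {"name": "k1", "value": k1, "unit": "1/min"},
                {"name": "k2", "value": k2, "unit": "1/min"},
            ],
            "reactions": [
                {
                    "id": "decay1",
                    "reactants": [{"species": "X1"}],
                    "products": [{"species": "X2"}],
                    "rate_law": "k1 * X1",
                },
                {
                    "id": "decay2",
                    "reactants": [{"species": "X2"}],
                    "products": [],
                    "rate_law": "k2 * X2",
                },
            ],
        }
    )
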