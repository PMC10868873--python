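"""Forward sensitivities, controllability/observability and the ir index."""

import numpy as np
import pytest
from scipy.linalg import expm

import irindex as ix
from irindex import sensitivity as sens
from irindex.series import GridMismatchError, IndexSeries

from conftest import linear_decay_chain


@pytest.fixture(scope="module")
def cycle_nir(cycle1, cycle1_ref):
    net, exp = cycle1
    grid = cycle1_ref.times
    idx = np.unique(np.linspace(0, len(grid) - 1, 80).round().astype(int))
    grid = grid[idx]
    C = sens.controllability_series(net, ref=cycle1_ref, exp=exp, t_grid=grid)
    O = sens.observability_series(net, ref=cycle1_ref, exp=exp, t_grid=grid)
    ir = sens.ir_series(C, O)
    nir, sum_ir = sens.nir_series(ir)
    return grid, C, O, ir, nir, sum_ir


class TestSensitivitySlice:
    def test_identity_at_anchor(self, cycle1, cycle1_ref):
        net, _ = cycle1
        sl = sens.sensitivity_slice(net, cycle1_ref, 1.0)
        assert np.allclose(sl.eval(1.0), np.eye(net.n))

    def test_linear_system_matches_matrix_exponential(self):
        net = linear_decay_chain(k1=1.3, k2=0.4)
        A = np.array([[-1.3, 0.0], [1.3, -0.4]])
        ref = ix.simulate(net, np.array([5.0, 1.0]), (0.0, 3.0))
        sl = sens.sensitivity_slice(net, ref, 0.5)
        for t2 in (0.9, 1.7, 3.0):
            assert np.allclose(sl.eval(t2), expm(A * (t2 - 0.5)), rtol=1e-6, atol=1e-9)

    def test_matches_finite_difference_propagation(self, cycle1, cycle1_ref):
        """Columns of S(t2; t1) against (Phi(x+eps e_j) - Phi(x)) / eps."""
        net, _ = cycle1
        t1, t2 = 0.5, 2.5
        sl = sens.sensitivity_slice(net, cycle1_ref, t1)
        x1 = cycle1_ref.dense_eval(t1)
        S = sl.eval(t2)
        for j in range(net.n):
            # eps large enough that the difference signal clears solver noise
            eps = 1e-3 * max(1.0, abs(x1[j]))
            plus = ix.simulate(net, x1 + eps * np.eye(net.n)[j], (t1, t2),
                               rtol=1e-11, atol=1e-13)
            minus = ix.simulate(net, x1 - eps * np.eye(net.n)[j], (t1, t2),
                                rtol=1e-11, atol=1e-13)
            fd = (plus.dense_eval(t2) - minus.dense_eval(t2)) / (2 * eps)
            assert np.allclose(S[:, j], fd, rtol=1e-3,
                               atol=1e-8 + 1e-3 * np.abs(fd).max())

    def test_semigroup_property(self, cycle1, cycle1_ref, rng):
        net, _ = cycle1
        for _ in range(5):
            t0, t1, t2 = np.sort(rng.uniform(0.0, 10.0, 3))
            a = sens.sensitivity_slice(net, cycle1_ref, t0)
            b = sens.sensitivity_slice(net, cycle1_ref, t1)
            left = a.eval(t2)
            right = b.eval(t2) @ a.eval(t1)
            assert np.allclose(left, right, rtol=1e-4, atol=1e-8 + 1e-4 * np.abs(left).max())

    def test_eval_outside_window_rejected(self, cycle1, cycle1_ref):
        net, _ = cycle1
        sl = sens.sensitivity_slice(net, cycle1_ref, 5.0)
        with pytest.raises(ValueError):
            sl.eval(4.0)


def _two_islands():
    """Two uncoupled conversion pairs: no path between the islands."""
    return ix.build_network(
        {
            "species": [
                {"name": "A1", "initial_value": 1.0},
                {"name": "B1", "initial_value": 0.0},
                {"name": "A2", "initial_value": 1.0},
                {"name": "B2", "initial_value": 0.0},
            ],
            "parameters": [{"name": "k", "value": 1.0, "unit": "1/min"}],
            "reactions": [
                {"id": "c1", "reactants": [{"species": "A1"}],
                 "products": [{"species": "B1"}], "rate_law": "k * A1"},
                {"id": "c2", "reactants": [{"species": "A2"}],
                 "products": [{"species": "B2"}], "rate_law": "k * A2"},
            ],
        }
    )


class TestControllability:
    def test_input_starts_at_one(self, cycle1, cycle1_ref, cycle_nir):
        net, exp = cycle1
        grid, C, *_ = cycle_nir
        assert C.values[0, exp.input_species] == 1.0
        assert C.t_grid[0] == 0.0

    def test_unreachable_states_have_zero_controllability(self):
        net = _two_islands()
        exp = ix.IOExperiment(0, 1, 1.0, net.initial_state, t_end=5.0)
        ref = ix.simulate(net, exp.stimulated_state, exp.window)
        grid = ref.times[:: max(1, len(ref.times) // 30)]
        C = sens.controllability_series(net, ref, exp, grid)
        assert np.allclose(C.column("A2"), 0.0, atol=1e-9)
        assert np.allclose(C.column("B2"), 0.0, atol=1e-9)

    def test_response_controllability_matches_input_perturbation(self, cycle1, cycle1_ref):
        """C_D(t*) equals the finite-difference response of D at t* to an
        input perturbation at t0."""
        net, exp = cycle1
        t_star = 2.0
        grid = np.array([0.0, t_star])
        C = sens.controllability_series(net, cycle1_ref, exp, grid)
        eps = 1e-6 * exp.input_magnitude
        up = exp.stimulated_state
        up[exp.input_species] += eps
        down = exp.stimulated_state
        down[exp.input_species] -= eps
        plus = ix.simulate(net, up, (0.0, t_star))
        minus = ix.simulate(net, down, (0.0, t_star))
        fd = (plus.dense_eval(t_star) - minus.dense_eval(t_star)) / (2 * eps)
        assert np.allclose(C.values[1], fd, rtol=1e-3, atol=1e-8)


class TestObservability:
    def test_zero_at_the_window_end(self, cycle1, cycle1_ref):
        net, exp = cycle1
        O = sens.observability_series(net, cycle1_ref, exp, np.array([exp.t_end]))
        assert np.allclose(O.values, 0.0)

    def test_unobservable_states_have_zero_observability(self):
        net = _two_islands()
        exp = ix.IOExperiment(0, 1, 1.0, net.initial_state, t_end=5.0)
        ref = ix.simulate(net, exp.stimulated_state, exp.window)
        grid = ref.times[:: max(1, len(ref.times) // 20)]
        O = sens.observability_series(net, ref, exp, grid)
        assert np.allclose(O.column("A2"), 0.0, atol=1e-9)
        assert np.allclose(O.column("B2"), 0.0, atol=1e-9)

    def test_matches_explicit_perturbation_quadrature(self, cycle1, cycle1_ref):
        """O_k(t*) against sqrt((1/T) int (dy/eps)^2 dt) from an explicit
        perturbation of x_k(t*), at three grid times."""
        net, exp = cycle1
        T = exp.t_end
        r = exp.response_species
        for t_star in (0.5, 2.0, 6.0):
            O = sens.observability_series(net, cycle1_ref, exp, np.array([t_star]))
            x1 = cycle1_ref.dense_eval(t_star)
            for k in (net.index("B"), net.index("D")):
                eps = 1e-3 * max(1.0, abs(x1[k]))
                plus = ix.simulate(net, x1 + eps * np.eye(net.n)[k], (t_star, T))
                minus = ix.simulate(net, x1 - eps * np.eye(net.n)[k], (t_star, T))
                tq = np.linspace(t_star, T, 4001)
                dy = (plus.dense_eval(tq)[:, r] - minus.dense_eval(tq)[:, r]) / (2 * eps)
                oracle = np.sqrt(np.trapezoid(dy**2, tq) / T)
                assert np.isclose(O.values[0, k], oracle, rtol=5e-3, atol=1e-10)


class TestIrNir:
    def test_grid_mismatch_rejected(self, cycle1, cycle_nir):
        net, _ = cycle1
        grid, C, O, *_ = cycle_nir
        other = IndexSeries(grid[:-1], O.values[:-1], "O", O.species)
        with pytest.raises(GridMismatchError):
            sens.ir_series(C, other)

    def test_ir_vanishes_at_the_window_end(self, cycle_nir):
        grid, C, O, ir, nir, sum_ir = cycle_nir
        assert grid[-1] == 10.0
        assert np.allclose(ir.values[-1], 0.0)

    def test_nir_rows_sum_to_one_where_sum_ir_positive(self, cycle_nir):
        grid, C, O, ir, nir, sum_ir = cycle_nir
        ok = ~nir.excluded
        assert ok.sum() > 50
        assert np.allclose(nir.values[ok].sum(axis=1), 1.0, atol=1e-12)
        assert np.nanmin(nir.values) >= 0.0 and np.nanmax(nir.values) <= 1.0

    def test_flagged_zero_sum_points_report_zero(self, cycle_nir):
        grid, C, O, ir, nir, sum_ir = cycle_nir
        assert nir.excluded[-1]
        assert np.allclose(nir.values[-1], 0.0)

    def test_dynamically_important_sets_per_scenario(self, scenario_analysis):
        expected = {1: {"A", "B", "D"}, 2: {"A", "B", "C", "D"}, 3: {"A", "D"}}
        for scen, want in expected.items():
            _, art = scenario_analysis[scen]
            nir = art["nir"]
            got = {s for s in nir.species if nir.max_over_time(s) >= 0.10}
            assert got == want, f"scenario {scen}: {got} != {want}"

    def test_ir_invariant_under_internal_unit_rescaling(self, cycle1, cycle1_ref):
        """Expressing the substrate in different units (factor 10) while
        rescaling its rate laws and stoichiometry consistently leaves the ir
        index of every state unchanged."""
        net, exp = cycle1
        scale = 10.0
        spec = ix.serialize(net)
        for srec in spec["species"]:
            if srec["name"] == "B":
                srec["initial_value"] *= scale
        for rrec in spec["reactions"]:
            if rrec["id"] == "transformation":
                rrec["rate_law"] = f"k_on * A * (B / {scale})"
                for side in ("reactants", "products"):
                    for item in rrec[side]:
                        if item["species"] == "B":
                            item["stoichiometry"] *= scale
            if rrec["id"] == "recycling":
                for item in rrec["products"]:
                    if item["species"] == "B":
                        item["stoichiometry"] *= scale
        net2 = ix.build_network(spec)
        exp2 = ix.IOExperiment(
            exp.input_species, exp.response_species, exp.input_magnitude,
            net2.initial_state, exp.t0, exp.t_end,
        )
        grid = np.array([0.3, 1.0, 2.5, 5.0])
        out = []
        for n_, e_, ref_ in ((net, exp, cycle1_ref), (net2, exp2, None)):
            if ref_ is None:
                ref_ = ix.simulate(n_, e_.stimulated_state, e_.window)
            C = sens.controllability_series(n_, ref_, e_, grid)
            O = sens.observability_series(n_, ref_, e_, grid)
            out.append(sens.ir_series(C, O).values)
        assert np.allclose(out[0], out[1], rtol=1e-5, atol=1e-10)


class TestInterimPlateau:
    def test_detects_shelf_and_skips_spike(self):
        t = np.linspace(0, 10, 400)
        # sharp spike at t~0.5, shelf at 0.45 around t~2-3, late rise
        curve = (
            0.75 * np.exp(-(((t - 0.5) / 0.08) ** 2))
            + 0.45 / (1 + np.exp(-(t - 1.2) / 0.2))
            + 0.4 / (1 + np.exp(-(t - 7.0) / 0.4))
        )
        series = IndexSeries(t, curve[:, None], "nir", ("B",))
        t_p, v = sens.interim_plateau(series, "B")
        assert 1.5 < t_p < 5.5
        assert v == pytest.approx(0.45, abs=0.03)

    def test_returns_nan_for_steadily_rising_curve(self):
        t = np.linspace(0, 10, 200)
        series = IndexSeries(t, (0.4 * t)[:, None], "nir", ("X",))
        t_p, v = sens.interim_plateau(series, "X")
        assert np.isnan(t_p) and np.isnan(v)
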