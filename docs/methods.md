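# Methods

## Model form and scope

`irindex` analyses autonomous reaction-kinetic ODE models
`dx/dt = f(x; p) = N α(x; p)` with a delta input `u0` added to one species at
`t0` and a single response coordinate `y = x_r`. Rate laws are stored as
symbolic (sympy) expressions and differentiated analytically; the compiled
Jacobian is exact, and its structural sparsity pattern is computed once per
network. Units are fixed to nM and minutes throughout; unit conversion is
the caller's responsibility. Time-dependent parameters, events, compartment
volume dynamics and rule-based model generation are out of scope, as are
multi-input/multi-output index matrices: only the scalar single-input /
single-response case is implemented.

## Reference trajectory and the t* grid

The reference system is integrated with an adaptive stiff solver (LSODA via
`scipy.integrate.solve_ivp`) with dense output, default tolerances
`rtol = 1e-8`, `atol = 1e-10` nM. The solver's accepted-step grid serves as
the grid of restart times t* for every index series, so the trapezoidal
quadratures downstream see the resolution the integrator itself deemed
necessary. For all-series pipelines the grid is uniformly thinned to a cap
(default 150 points) to bound the number of per-t* solves; the same thinned
grid serves the nir series, the classification indices and the state errors,
so the decision tree compares like with like. The problem sizes used
throughout the bundled analyses are the fixtures' own: 4-6 state variables,
150 grid points, [0, 10] min windows.

## Sensitivities

The sensitivity `S(t2; t1)` is obtained by integrating the variational
system `dS/dt = J_f(x(t)) S`, `S(t1) = I`, jointly with the state restarted
from `x_ref(t1)`. The controllability series needs a single solve (one
matrix column, anchored at `t0`); the observability series needs one full
variational solve per t*, whose accepted steps provide the quadrature grid
for `O_k(t*) = sqrt((1/T) ∫_{t*}^{T} S_{r,k}(t; t*)² dt)`. Two deliberate
conventions:

* the prefactor is `1/T` exactly, not `1/(T - t*)`, so O — and with it ir —
  shrinks toward the window end by construction; `O_k(T) = 0` identically;
* `ir_k = O_k · |C_k|` uses the absolute controllability value; the signed C
  series is retained for diagnostics.

`nir_k = ir_k / Σ_j ir_j` is defined as 0 (and the grid point flagged) where
the sum is zero, and likewise flagged where the sum has decayed below 1e-8
of its maximum: there the ir values sit at the integration-noise floor of
the variational solves and their ratios are meaningless. Flagged points are
excluded from thresholding.

## System modifications

All modified systems restart from the **unperturbed** reference state at t*;
there is no re-equilibration.

* `env`: the target rows of `f` (and of the Jacobian) are zeroed; the state
  is frozen at its restart value.
* `pss`: the target ODEs are replaced by `f_k(x) = 0`. The system is treated
  as a semi-explicit index-1 DAE and the algebraic variables are eliminated
  by a nested Newton iteration inside the right-hand side, warm-started
  across solver calls, using the corresponding Jacobian block. Consistent
  initialisation starts Newton at the reference value of the target; on
  failure it retries with deterministically perturbed guesses (factors 1.1,
  0.9, 0.5 of the reference value, in that order — up to three retries, no
  randomness). No implicit-DAE integrator backend is used; the nested
  elimination keeps the dependency surface to scipy only.
* `pneg`: every reaction with a target among its reactants is removed
  (rates masked to zero). This is the exact reaction-removal definition; the
  shortcut of clamping the state to zero is not used, so the behaviour is
  correct also when the target enters rate laws non-multiplicatively.
* `cneg`: every reaction with a target among its reactants **or products**
  is removed; targets become constant.

Failure of a modified integration — solver failure, non-finite values, or
any |x| exceeding 1e6 times the reference scale (blow-up) — is an expected
outcome, returned as a flagged object and consumed downstream as NaN. NaN
index values count as threshold violations in the decision tree: a state
whose pss system blows up is simply not in partial steady state.

## Classification indices, state errors and the decision tree

Each classification index is the relative L2 deviation of the output over
[t*, T], `sqrt(∫(y_ref − y_mod)² ds / ∫ y_ref² ds)`, with both integrals
evaluated by the trapezoidal rule **on the modified solve's accepted steps**
(the reference enters through its dense interpolant), so numerator and
normalisation are discretised consistently. The state-approximation error
has the same form on the modified coordinate itself and is meaningful for
`env` and `pss` only (for `pneg`/`cneg` it equals 1 by definition). The
normalisation `Z(t*) = ∫_{t*}^{T} y_ref² ds` vanishes as t* → T, making the
ratio ill-conditioned near the window end; grid points with
`Z(t*) < 1e-12 · Z(t0)` (always including `t* = T`) are excluded from
thresholding and marked in the series. Classification indices can exceed 1
and are never clipped.

The decision tree tests, in order: dynamic (`max nir ≥ δ_y`), environmental
(`env` index < δ_y at all evaluated t* **and** env state error < δ_x at all
t*), partial steady state (same two-part test on `pss`), completely
negligible (`cneg` < δ_y), partially negligible (`pneg` < δ_y), else
unclassified. The order makes labels unique; a secondary overlapping report
(each test evaluated independently) is also emitted, since the independent
tests need not be mutually exclusive. Both thresholds default to 10%.
Classification indices are only computed for states that fail the dynamic
test — dynamic states need no further characterisation. Threshold
monotonicity holds per test (raising δ_y shrinks the dynamic set and
enlarges every below-threshold set) but not for the composite "unclassified"
outcome, since a state leaving the dynamic set becomes a fresh candidate for
the remaining tests.

## Interim-plateau detection

Signalling index curves often rise steeply, hold an interim shelf, and only
later move to their eventual maximum. The plateau detector resamples a
series to a uniform 0.05 min grid, computes the slope, and walks candidate
points (sign changes of the slope, or local minima of its magnitude) in time
order, accepting the first whose ±0.4 min neighbourhood stays below a slope
magnitude of 0.20 fraction/min. Sharp transient spikes — for example the
structure produced where an input-sensitivity changes sign — carry
neighbourhood slopes an order of magnitude above the bound and are skipped.
The parameters are detector properties, not fit to any particular curve:
any bound between roughly 0.12 and 1.0 fraction/min selects the same shelf
on the bundled fixtures.

## Fixture models

The fixtures define the analysis conditions and are first-class, tested
code; `src/irindex/models/*.json` is the single source of truth for their
wiring.

**Reaction cycle** (4 species, 6 reactions): the signal A catalyses
transformation of the substrate B into the intermediate C
(`k_on·A·B`, `k_on` in 1/nM/min); C activates the response D (`k_act·C`);
D recycles to B (`k_rec·D`), closing the cycle B→C→D→B; A, C and D may
degrade. Baseline `(A, B, C, D) = (0, 100, 5, 0)` nM, input 2 nM on A,
response D, window [0, 10] min — the span on which the documented index
behaviour (interim values near 2 min, decay over ~10 min) unfolds. Three
rate-constant scenarios change the character of the states:

| scenario | k_on | k_act | k_rec | k_deg_A | k_deg_C | k_deg_D | character |
|---|---|---|---|---|---|---|---|
| 1 | 2.5 | 100 | 0.1 | 1 | 0 | 3 | C fast (pss); A, B, D dynamic |
| 2 | 2.5 | 1 | 0.1 | 1 | 0 | 3 | C slow: all four dynamic |
| 3 | 8 | 320 | 200 | 10 | 0 | 10 | signal transient: B environmental, C pss |

Two structural constraints shaped the parameter choice. First, the standing
intermediate pool must be consistent with its algebraic manifold at the
stimulated state — `C(0) = k_on·(A0+u0)·B0 / k_act`, i.e. `k_act = 40·k_on`
in scenarios 1 and 3 — otherwise the pss modification from `t* = 0` starts
with a spurious relaxation burst that dominates the state-error
normalisation. Second, in scenario 3 the substrate can only be
environmental if both the permanently destroyed mass and the in-transit
mass of the cycle stay small, which requires fast recycling relative to the
transformation flux; the response then takes its dynamic label from the
late window, where it is the only state with nonvanishing index. The
baseline of this fixture is deliberately not a steady state: pre-stimulus,
the standing C pool drains into D — the documented pre-stimulus behaviour,
asserted as such in the tests. The enzyme-substrate and parallel-pathway
fixtures rest at true steady states before stimulation.

**Parallel pathway** (6 species, 5 reactions): two kinetically identical
adaptor routes (`E1/C1`, `E2/C2`) convert the signal A into the response D.
Because the routes compete for the same conserved signal pool, removing one
route re-routes the full flux through the other: single-route knockouts
give ≈8% relative output error while the joint knockout gives exactly 100%
(the response stays at zero). This is the compensation caveat at fixture
scale — a low neglect index can reflect compensation rather than
irrelevance.

**Enzyme-substrate** (4 species, 4 reactions): Michaelis-Menten binding
with fast dissociation (`k_off = 400/min` against `k_cat = 10/min`), a
20 nM substrate pulse as input and the product as response. The complex ES
classifies as partial steady state, the free enzyme as environmental — the
classical quasi-steady-state picture recovered by the indices.

What the fixtures do **not** emulate: real signalling networks have far
more species, multiple conserved moieties, and stiffness spread over many
more decades; passing tests on these fixtures demonstrates correctness of
the machinery and of the documented qualitative patterns, not performance
or classification stability on models of realistic size.

## Numerical choices and limitations

* Solver tolerances `rtol 1e-8 / atol 1e-10`; variational and modified
  solves use the same settings. Finite-difference oracle tests perturb with
  `ε = 1e-3 ×` state scale and integrate the perturbed systems at
  `rtol 1e-11` so the difference signal clears solver noise.
* Tiny negative concentrations are passed through to rate laws (mass-action
  polynomials are well defined there); clipping to zero is applied only
  when a rate law contains non-integer powers of a species.
* The Newton elimination tolerance for the pss algebraic block is a step
  criterion of `1e-10·(1 + |x|)`, 30 iterations; a singular algebraic
  Jacobian (e.g. a state absent from its own RHS) is a flagged failure.
* SBML import is restricted to the kinetic-law subset described in
  `irindex/sbml.py`; reversible laws are split only when the expression
  separates into positively and negatively signed term groups.
* The EGFR-scale workflow (hundreds of states) is supported by the same
  code paths (sparse Jacobian pattern, grid cap) but is not exercised by
  the bundled fixtures; observability solves are O(n²) states per t* and
  dominate runtime on large models.
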