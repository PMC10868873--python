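"""Integration of the reference system and of modified systems.

Four modification kinds probe what a state variable contributes:

``env``   freeze the state (its ODE right-hand side is set to zero);
``pss``   replace its ODE by the algebraic condition f_k(x) = 0 (a
          semi-explicit index-1 DAE, solved here by eliminating the algebraic
          variables with a nested Newton iteration inside the RHS);
``pneg``  remove every reaction consuming the state (partial neglect);
``cneg``  remove every reaction consuming *or producing* it (complete neglect).

Modified systems are restarted from the unperturbed reference state at the
modification time t*.  Failure of a modified integration (typically a pss
blow-up or no consistent DAE initialisation) is an expected outcome and is
returned as a flagged object rather than raised.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .network import ReactionNetwork

__all__ = [
    "Trajectory",
    "SimulationError",
    "SimulationFailure",
    "ModifiedSystem",
    "make_modification",
    "simulate",
    "simulate_modified",
]

#: default solver tolerances (concentrations in nM)
RTOL = 1e-8
ATOL = 1e-10

#: |x| exceeding BLOWUP_FACTOR x the reference scale flags a blow-up
BLOWUP_FACTOR = 1e6

MOD_KINDS = ("env", "pss", "pneg", "cneg")


class SimulationError(RuntimeError):
    """Integration of the reference system failed."""

    def __init__(self, message: str, time: float | None = None):
        super().__init__(message)
        self.time = time


@dataclass(frozen=True)
class SimulationFailure:
    """Flagged failure of a modified-system integration (consumed as NaN)."""

    time: float
    reason: str
    failed: bool = True


class Trajectory:
    """Adaptive-solver output with dense interpolation.

    ``times`` is the solver's accepted-step grid; it doubles as the t* grid of
    the index analysis downstream.
    """

    failed = False

    def __init__(self, times: np.ndarray, states: np.ndarray, dense):
        self.times = np.asarray(times, dtype=float)
        self.states = np.asarray(states, dtype=float)
        self._dense = dense

    @property
    def start(self) -> float:
        return float(self.times[0])

    @property
    def end(self) -> float:
        return float(self.times[-1])

    def __call__(self, t):
        return self.dense_eval(t)

    def dense_eval(self, t):
        """Interpolated state at time(s) ``t``; exact at stored grid points."""
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.asarray(self._dense(t_arr), dtype=float)
        if out.ndim == 1:
            out = out[:, None]
        out = out.T  # (len(t), n)
        # snap to stored values at exact grid times
        idx = np.searchsorted(self.times, t_arr)
        for j, tj in enumerate(t_arr):
            for i in (idx[j] - 1, idx[j]):
                if 0 <= i < len(self.times) and self.times[i] == tj:
                    out[j] = self.states[i]
                    break
        if np.isscalar(t) or np.ndim(t) == 0:
            return out[0]
        return out

    def coordinate(self, k: int, t=None) -> np.ndarray:
        if t is None:
            return self.states[:, k]
        return np.atleast_2d(self.dense_eval(t))[:, k]

    def to_frame(self, species: Sequence[str]):
        import pandas as pd

        df = pd.DataFrame(self.states, columns=list(species))
        df.insert(0, "time", self.times)
        return df


# ---------------------------------------------------------------------- #
def simulate(
    net: ReactionNetwork,
    x_init: Sequence[float],
    window: tuple[float, float],
    rtol: float = RTOL,
    atol: float = ATOL,
) -> Trajectory:
    """Integrate dx/dt = f(x; p) with a stiff adaptive solver and dense output."""
    t0, t_end = float(window[0]), float(window[1])
    if not t0 < t_end:
        raise ValueError("window must satisfy start < end")
    x_init = np.asarray(x_init, dtype=float)
    if x_init.shape != (net.n,):
        raise ValueError(f"x_init must have length {net.n}")

    sol = solve_ivp(
        lambda t, x: net.rhs(x),
        (t0, t_end),
        x_init,
        method="LSODA",
        jac=lambda t, x: net.jac(x),
        rtol=rtol,
        atol=atol,
        dense_output=True,
    )
    if not sol.success:
        raise SimulationError(f"integration failed: {sol.message}", time=float(sol.t[-1]))
    if not np.all(np.isfinite(sol.y)):
        raise SimulationError("non-finite state encountered", time=float(sol.t[-1]))
    return Trajectory(sol.t, sol.y.T, sol.sol)


# ---------------------------------------------------------------------- #
@dataclass(frozen=True)
class ModifiedSystem:
    """A system modification applied from ``start_time`` onward."""

    base: ReactionNetwork
    kind: str
    targets: frozenset[int]
    start_time: float

    def __post_init__(self):
        if self.kind not in MOD_KINDS:
            raise ValueError(f"kind must be one of {MOD_KINDS}, got {self.kind!r}")
        if not self.targets:
            raise ValueError("modification needs a nonempty target set")
        bad = [k for k in self.targets if not 0 <= k < self.base.n]
        if bad:
            raise ValueError(f"target indices out of range: {bad}")


def make_modification(
    net: ReactionNetwork, kind: str, targets: Iterable[int], start_time: float
) -> ModifiedSystem:
    return ModifiedSystem(net, kind, frozenset(int(k) for k in targets), float(start_time))


class _PssSolveError(RuntimeError):
    pass


class _AlgebraicEliminator:
    """Solve f_T(x_free, x_T) = 0 for the pss target block by Newton iteration."""

    def __init__(self, net: ReactionNetwork, targets: Sequence[int]):
        self.net = net
        self.targets = np.asarray(sorted(targets), dtype=int)
        self.free = np.asarray(
            [k for k in range(net.n) if k not in set(self.targets)], dtype=int
        )
        self.guess: np.ndarray | None = None  # warm start across RHS calls

    def solve(self, x_free: np.ndarray, guess: np.ndarray, max_iter: int = 30) -> np.ndarray:
        x = np.empty(self.net.n)
        x[self.free] = x_free
        xt = np.asarray(guess, dtype=float).copy()
        for _ in range(max_iter):
            x[self.targets] = xt
            try:
                g = self.net.rhs(x)[self.targets]
                J = self.net.jac(x)[np.ix_(self.targets, self.targets)]
            except ValueError as exc:  # non-finite iterate
                raise _PssSolveError(str(exc)) from exc
            try:
                step = np.linalg.solve(J, g)
            except np.linalg.LinAlgError as exc:
                raise _PssSolveError(f"singular algebraic Jacobian: {exc}") from exc
            if not np.all(np.isfinite(step)):
                raise _PssSolveError("non-finite Newton step")
            xt = xt - step
            if np.all(np.abs(step) <= 1e-10 * (1.0 + np.abs(xt))):
                self.guess = xt
                return xt
        raise _PssSolveError("Newton iteration for f_k(x)=0 did not converge")


class _PssTrajectory(Trajectory):
    """Trajectory of a pss system; target coordinates come from the algebraic solve."""

    def __init__(self, times, states, reduced_dense, eliminator: _AlgebraicEliminator):
        super().__init__(times, states, None)
        self._reduced = reduced_dense
        self._elim = eliminator

    def dense_eval(self, t):
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        free_vals = np.asarray(self._reduced(t_arr), dtype=float)
        if free_vals.ndim == 1:
            free_vals = free_vals[:, None]
        free_vals = free_vals.T
        out = np.empty((len(t_arr), self.states.shape[1]))
        for j, tj in enumerate(t_arr):
            i = int(np.clip(np.searchsorted(self.times, tj) - 1, 0, len(self.times) - 1))
            exact = None
            for ii in (i, i + 1):
                if 0 <= ii < len(self.times) and self.times[ii] == tj:
                    exact = ii
                    break
            if exact is not None:
                out[j] = self.states[exact]
                continue
            guess = self.states[i][self._elim.targets]
            xt = self._elim.solve(free_vals[j], guess)
            row = np.empty(self.states.shape[1])
            row[self._elim.free] = free_vals[j]
            row[self._elim.targets] = xt
            out[j] = row
        if np.isscalar(t) or np.ndim(t) == 0:
            return out[0]
        return out


#: deterministic retry guesses for consistent DAE initialisation, as factors
#: applied to the reference value of the target coordinate
_PSS_RETRY_FACTORS = (1.0, 1.1, 0.9, 0.5)


def simulate_modified(
    mod: ModifiedSystem,
    x_start: Sequence[float],
    window: tuple[float, float],
    rtol: float = RTOL,
    atol: float = ATOL,
    ref_scale: float | None = None,
):
    """Integrate a modified system from the (unperturbed) reference state at t*.

    Returns a :class:`Trajectory`, or a :class:`SimulationFailure` when the
    integration blows up or no consistent initialisation can be found.
    """
    net = mod.base
    t_start, t_end = float(window[0]), float(window[1])
    x_start = np.asarray(x_start, dtype=float)
    if ref_scale is None:
        ref_scale = max(1.0, float(np.max(np.abs(x_start))))
    bound = BLOWUP_FACTOR * ref_scale

    if mod.kind == "pss":
        return _simulate_pss(mod, x_start, (t_start, t_end), rtol, atol, bound)

    targets = sorted(mod.targets)
    if mod.kind == "env":
        def rhs(t, x):
            dx = net.rhs(x)
            dx[targets] = 0.0
            return dx

        def jac(t, x):
            J = net.jac(x)
            J[targets, :] = 0.0
            return J
    else:  # pneg / cneg: reaction removal
        mask = net.reaction_mask(mod.targets, "reactant" if mod.kind == "pneg" else "any")

        def rhs(t, x):
            return net.rhs(x, mask=mask)

        def jac(t, x):
            return net.jac(x, mask=mask)

    try:
        sol = solve_ivp(
            rhs,
            (t_start, t_end),
            x_start,
            method="LSODA",
            jac=jac,
            rtol=rtol,
            atol=atol,
            dense_output=True,
        )
    except (ValueError, FloatingPointError) as exc:
        return SimulationFailure(time=t_start, reason=f"integration error: {exc}")
    if not sol.success:
        return SimulationFailure(time=float(sol.t[-1]), reason=sol.message)
    if not np.all(np.isfinite(sol.y)) or np.max(np.abs(sol.y)) > bound:
        return SimulationFailure(time=float(sol.t[-1]), reason="state blow-up")
    return Trajectory(sol.t, sol.y.T, sol.sol)


def _simulate_pss(mod, x_start, window, rtol, atol, bound):
    net = mod.base
    elim = _AlgebraicEliminator(net, sorted(mod.targets))
    t_start, t_end = window

    # consistent initialisation: Newton from the reference value, retried with
    # deterministically perturbed guesses
    xt0 = None
    ref_t = x_start[elim.targets]
    for factor in _PSS_RETRY_FACTORS:
        try:
            xt0 = elim.solve(x_start[elim.free], factor * ref_t)
            break
        except _PssSolveError:
            continue
    if xt0 is None:
        return SimulationFailure(time=t_start, reason="no consistent DAE initialisation")

    elim.guess = xt0

    def rhs(t, x_free):
        xt = elim.solve(x_free, elim.guess)
        x = np.empty(net.n)
        x[elim.free] = x_free
        x[elim.targets] = xt
        if np.max(np.abs(x)) > bound:
            raise _PssSolveError("pss blow-up")
        return net.rhs(x)[elim.free]

    try:
        sol = solve_ivp(
            rhs,
            (t_start, t_end),
            x_start[elim.free],
            method="LSODA",
            rtol=rtol,
            atol=atol,
            dense_output=True,
        )
    except (_PssSolveError, ValueError, FloatingPointError) as exc:
        return SimulationFailure(time=t_start, reason=f"pss integration failed: {exc}")
    if not sol.success:
        return SimulationFailure(time=float(sol.t[-1]), reason=sol.message)
    if not np.all(np.isfinite(sol.y)) or np.max(np.abs(sol.y)) > bound:
        return SimulationFailure(time=float(sol.t[-1]), reason="state blow-up")

    # reconstruct full states on the accepted grid
    states = np.empty((len(sol.t), net.n))
    guess = xt0
    try:
        for j in range(len(sol.t)):
            xt = elim.solve(sol.y[:, j], guess)
            guess = xt
            states[j, elim.free] = sol.y[:, j]
            states[j, elim.targets] = xt
    except _PssSolveError as exc:
        return SimulationFailure(time=float(sol.t[j]), reason=str(exc))
    if np.max(np.abs(states)) > bound:
        return SimulationFailure(time=float(sol.t[-1]), reason="state blow-up")
    return _PssTrajectory(sol.t, states, sol.sol, elim)
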