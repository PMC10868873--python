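"""Forward sensitivities and the input-response index.

The state-transition sensitivity

    S(t2; t1) = d Phi_{t2,t1}(x) / dx  at  x = x_ref(t1)

is obtained by integrating the variational system dS/dt = J_f(x(t)) S with
S(t1) = I alongside the state.  From it the analysis builds, per state k on a
grid of restart times t*:

* controllability  C_k(t*) = S_{k,i}(t*; t0)           (impact of the input),
* observability    O_k(t*) = sqrt( (1/T) int_{t*}^{T} S_{r,k}(t; t*)^2 dt ),
* input-response   ir_k(t*) = O_k(t*) * |C_k(t*)|,
* normalised       nir_k(t*) = ir_k / sum_j ir_j.

i is the input species, r the response species.  The observability prefactor
is 1/T with T the end of the analysis window — not 1/(T - t*) — so O (and
hence ir) shrinks toward T by construction; the quadrature runs on the
accepted steps of each per-t* variational solve (trapezoidal rule).
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from .experiment import IOExperiment
from .network import ReactionNetwork
from .series import GridMismatchError, IndexSeries
from .trajectory import RTOL, ATOL, SimulationError, Trajectory

__all__ = [
    "SensitivitySlice",
    "sensitivity_slice",
    "controllability_series",
    "observability_series",
    "ir_series",
    "nir_series",
    "interim_plateau",
]


class SensitivitySlice:
    """The sensitivity matrix function S( . ; t1) anchored at time t1."""

    def __init__(self, anchor_time: float, t_end: float, times, dense, n: int):
        self.anchor_time = float(anchor_time)
        self.t_end = float(t_end)
        self.times = np.asarray(times, dtype=float)  # accepted steps of the solve
        self._dense = dense
        self.n = n

    def eval(self, t2: float) -> np.ndarray:
        """n x n matrix S(t2; t1)."""
        if not self.anchor_time <= t2 <= self.t_end + 1e-12:
            raise ValueError(
                f"t2={t2} outside [{self.anchor_time}, {self.t_end}]"
            )
        if t2 == self.anchor_time:
            return np.eye(self.n)
        z = np.asarray(self._dense(t2), dtype=float)
        return z[self.n :].reshape(self.n, self.n)

    def state(self, t2: float) -> np.ndarray:
        z = np.asarray(self._dense(t2), dtype=float)
        return z[: self.n]

    def row_history(self, r: int) -> tuple[np.ndarray, np.ndarray]:
        """(times, S_{r,:}(times; t1)) on the solve's accepted steps."""
        rows = np.empty((len(self.times), self.n))
        for j, t in enumerate(self.times):
            rows[j] = self.eval(float(t))[r]
        return self.times, rows


def sensitivity_slice(
    net: ReactionNetwork,
    ref: Trajectory,
    t1: float,
    t_end: float | None = None,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> SensitivitySlice:
    """Integrate the variational system from x_ref(t1) with S(t1) = I."""
    if t_end is None:
        t_end = ref.end
    if not ref.start <= t1 <= t_end:
        raise ValueError(f"anchor time {t1} outside [{ref.start}, {t_end}]")
    n = net.n
    x1 = ref.dense_eval(t1)
    z0 = np.concatenate([x1, np.eye(n).ravel()])

    def rhs(t, z):
        x = z[:n]
        S = z[n:].reshape(n, n)
        J = net.jac(x)
        return np.concatenate([net.rhs(x), (J @ S).ravel()])

    if t1 == t_end:
        # degenerate slice: identity at the anchor, nothing to integrate
        dense = lambda t: z0
        return SensitivitySlice(t1, t_end, np.array([t1]), dense, n)

    sol = solve_ivp(rhs, (t1, t_end), z0, method="LSODA", rtol=rtol, atol=atol,
                    dense_output=True)
    if not sol.success:
        raise SimulationError(f"variational solve failed: {sol.message}", time=float(sol.t[-1]))
    return SensitivitySlice(t1, t_end, sol.t, sol.sol, n)


# ---------------------------------------------------------------------- #
def controllability_series(
    net: ReactionNetwork,
    ref: Trajectory,
    exp: IOExperiment,
    t_grid: np.ndarray,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> IndexSeries:
    """C_k(t*) = S_{k,i}(t*; t0): column i of a single slice anchored at t0.

    One variational solve total (a single column suffices); the raw series
    keeps the sign — the ir index takes |C| later.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    n = net.n
    i = exp.input_species
    z0 = np.concatenate([ref.dense_eval(ref.start), np.eye(n)[:, i]])

    def rhs(t, z):
        x, s = z[:n], z[n:]
        return np.concatenate([net.rhs(x), net.jac(x) @ s])

    sol = solve_ivp(rhs, (ref.start, ref.end), z0, method="LSODA", rtol=rtol,
                    atol=atol, dense_output=True)
    if not sol.success:
        raise SimulationError(f"variational solve failed: {sol.message}", time=float(sol.t[-1]))

    vals = np.empty((len(t_grid), n))
    for j, t in enumerate(t_grid):
        if t == ref.start:
            vals[j] = np.eye(n)[:, i]
        else:
            vals[j] = np.asarray(sol.sol(t), dtype=float)[n:]
    return IndexSeries(t_grid, vals, "C", tuple(net.species))


def observability_series(
    net: ReactionNetwork,
    ref: Trajectory,
    exp: IOExperiment,
    t_grid: np.ndarray,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> IndexSeries:
    """O_k(t*) = sqrt( (1/T) int_{t*}^{T} S_{r,k}(t; t*)^2 dt ).

    One full variational solve per t*; per-t* failures are recorded as NaN
    rows rather than raised.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    r = exp.response_species
    T = exp.t_end
    vals = np.full((len(t_grid), net.n), np.nan)
    for j, t_star in enumerate(t_grid):
        if t_star == ref.end:
            vals[j] = 0.0  # empty integration interval
            continue
        try:
            sl = sensitivity_slice(net, ref, float(t_star), ref.end, rtol, atol)
            times, rows = sl.row_history(r)
        except SimulationError:
            continue
        vals[j] = np.sqrt(np.trapezoid(rows**2, times, axis=0) / T)
    return IndexSeries(t_grid, vals, "O", tuple(net.species))


def ir_series(C: IndexSeries, O: IndexSeries) -> IndexSeries:
    """ir_k(t*) = O_k(t*) * |C_k(t*)| on the shared grid."""
    if not np.array_equal(C.t_grid, O.t_grid):
        raise GridMismatchError("C and O series must share the t* grid")
    if C.species != O.species:
        raise GridMismatchError("C and O series must cover the same species")
    return IndexSeries(C.t_grid, O.values * np.abs(C.values), "ir", C.species)


def nir_series(ir: IndexSeries) -> tuple[IndexSeries, np.ndarray]:
    """Normalise ir to sum to one across states; returns (nir, sum_ir).

    Where sum_ir(t*) = 0 (all-zero sensitivities) nir is defined as 0 for all
    states and the grid point is flagged in ``nir.excluded``.  Grid points
    where sum_ir has decayed below 1e-8 of its maximum are likewise flagged:
    there the ir values sit at the integration-noise floor and their ratios
    carry no information.
    """
    sum_ir = ir.values.sum(axis=1)  # NaN propagates: a failed O row stays NaN
    with np.errstate(invalid="ignore"):
        floor = 1e-8 * np.nanmax(sum_ir) if np.any(np.isfinite(sum_ir)) else 0.0
        positive = sum_ir > max(floor, 0.0)
    failed = np.isnan(sum_ir)
    vals = np.zeros_like(ir.values)
    vals[positive] = ir.values[positive] / sum_ir[positive, None]
    vals[failed] = np.nan
    series = IndexSeries(ir.t_grid, vals, "nir", ir.species, excluded=~positive)
    return series, sum_ir


# ---------------------------------------------------------------------- #
def interim_plateau(
    series: IndexSeries,
    name: str,
    dt: float = 0.05,
    window: float = 0.4,
    max_slope: float = 0.20,
) -> tuple[float, float]:
    """Locate the first interim plateau of an index curve.

    Signalling indices often rise steeply, hold an interim value (a shelf)
    and only later move on to their eventual maximum.  The detector resamples
    the curve uniformly (step ``dt`` minutes, linear interpolation), walks its
    stationary points (sign changes of the slope) in time order and accepts
    the first one whose +/- ``window`` neighbourhood stays flat, i.e. has
    |slope| <= ``max_slope`` (fraction per minute).  Sharp transient spikes
    fail the flatness test by an order of magnitude and are skipped.

    Returns ``(time, value)``; ``(nan, nan)`` when no plateau exists.
    """
    t_grid = series.t_grid
    col = series.column(name)
    tu = np.arange(t_grid[0], t_grid[-1] + 1e-12, dt)
    cu = np.interp(tu, t_grid, col)
    slope = np.gradient(cu, tu)
    mag = np.abs(slope)
    for j in range(1, len(tu) - 1):
        stationary = slope[j - 1] * slope[j] < 0 or slope[j] == 0
        flattest = mag[j] < mag[j - 1] and mag[j] <= mag[j + 1]
        if stationary or flattest:
            m = (tu >= tu[j] - window) & (tu <= tu[j] + window)
            if np.max(mag[m]) <= max_slope:
                return float(tu[j]), float(cu[j])
    return float("nan"), float("nan")
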