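"""State-classification indices, state-approximation errors and the decision tree.

Each classification index compares the output of the reference system with
that of a modified system restarted from the unperturbed reference state at
time t*:

    ind_k(t*) = sqrt( int_{t*}^{T} (y_ref - y_mod(k))^2 ds  /  Z(t*) ),
    Z(t*)     = int_{t*}^{T} y_ref^2 ds,

with y the response coordinate.  The relative state-approximation error has
the same form on the modified coordinate itself (meaningful for the env and
pss modifications only; for pneg/cneg it equals one by definition).  The
normalisation Z(t*) vanishes as t* approaches T, so grid points where Z drops
below 1e-12 of its initial value are excluded from thresholding and marked.

The decision tree labels each state, in order: dynamic -> environmental ->
partial steady state -> completely negligible -> partially negligible ->
unclassified.  NaN index values (failed modified integrations) count as
threshold violations.  Classification indices may exceed 1 and are never
clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .experiment import IOExperiment
from .network import ReactionNetwork
from .series import GridMismatchError, IndexSeries
from .trajectory import (
    RTOL,
    ATOL,
    SimulationFailure,
    Trajectory,
    make_modification,
    simulate_modified,
)

__all__ = [
    "LABELS",
    "ClassificationReport",
    "classification_index_series",
    "state_error_series",
    "classify_states",
    "knockout_relative_error",
    "run_classification",
]

LABELS = (
    "dynamic",
    "environmental",
    "partial_steady_state",
    "completely_negligible",
    "partially_negligible",
    "unclassified",
)

#: Z(t*) below this fraction of Z(t0) is considered degenerate
Z_CUTOFF = 1e-12


def _relative_l2_error(
    ref: Trajectory, mod, coord: int, t_star: float
) -> float:
    """Eq-style relative L2 error of coordinate ``coord`` over [t*, T].

    Quadrature (trapezoidal) runs on the modified solve's accepted steps;
    the reference enters through its dense interpolant on the same grid so
    numerator and normalisation are computed consistently.
    """
    if isinstance(mod, SimulationFailure) or getattr(mod, "failed", False):
        return float("nan")
    grid = mod.times
    y_mod = mod.states[:, coord]
    y_ref = np.atleast_2d(ref.dense_eval(grid))[:, coord]
    num = np.trapezoid((y_ref - y_mod) ** 2, grid)
    den = np.trapezoid(y_ref**2, grid)
    if den <= 0:
        return float("nan")
    return float(np.sqrt(num / den))


def _exclusion_mask(ref: Trajectory, coord: int, t_grid: np.ndarray) -> np.ndarray:
    """Grid points where Z(t*) = int_{t*}^{T} x_coord^2 ds is degenerate."""
    y2 = ref.states[:, coord] ** 2
    dt = np.diff(ref.times)
    seg = 0.5 * (y2[:-1] + y2[1:]) * dt
    tail = np.concatenate([np.cumsum(seg[::-1])[::-1], [0.0]])  # Z at each ref time
    z0 = tail[0]
    z_at = np.interp(t_grid, ref.times, tail)
    if z0 <= 0:
        return np.ones(len(t_grid), dtype=bool)
    return (z_at < Z_CUTOFF * z0) | (t_grid >= ref.end)


def classification_index_series(
    net: ReactionNetwork,
    ref: Trajectory,
    exp: IOExperiment,
    kind: str,
    k: int,
    t_grid: np.ndarray,
    rtol: float = RTOL,
    atol: float = ATOL,
    progress=None,
) -> IndexSeries:
    """One of the four classification index series (env/pss/pneg/cneg) for state k."""
    t_grid = np.asarray(t_grid, dtype=float)
    r = exp.response_species
    excluded = _exclusion_mask(ref, r, t_grid)
    ref_scale = max(1.0, float(np.max(np.abs(ref.states))))
    vals = np.full(len(t_grid), np.nan)
    for j, t_star in enumerate(t_grid):
        if excluded[j]:
            continue
        mod = make_modification(net, kind, {k}, float(t_star))
        traj = simulate_modified(
            mod, ref.dense_eval(float(t_star)), (float(t_star), ref.end),
            rtol=rtol, atol=atol, ref_scale=ref_scale,
        )
        vals[j] = _relative_l2_error(ref, traj, r, float(t_star))
        if progress is not None:
            progress(j, len(t_grid))
    return IndexSeries(t_grid, vals, kind, (net.species[k],), excluded=excluded)


def state_error_series(
    net: ReactionNetwork,
    ref: Trajectory,
    kind: str,
    k: int,
    t_grid: np.ndarray,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> IndexSeries:
    """Relative state-approximation error series for the env or pss modification."""
    if kind not in ("env", "pss"):
        raise ValueError("state errors are defined for the env and pss modifications only")
    t_grid = np.asarray(t_grid, dtype=float)
    excluded = _exclusion_mask(ref, k, t_grid)
    ref_scale = max(1.0, float(np.max(np.abs(ref.states))))
    vals = np.full(len(t_grid), np.nan)
    for j, t_star in enumerate(t_grid):
        if excluded[j]:
            continue
        mod = make_modification(net, kind, {k}, float(t_star))
        traj = simulate_modified(
            mod, ref.dense_eval(float(t_star)), (float(t_star), ref.end),
            rtol=rtol, atol=atol, ref_scale=ref_scale,
        )
        vals[j] = _relative_l2_error(ref, traj, k, float(t_star))
    return IndexSeries(t_grid, vals, "state_err", (net.species[k],), excluded=excluded)


def knockout_relative_error(
    net: ReactionNetwork,
    ref: Trajectory,
    exp: IOExperiment,
    kind: str,
    targets,
    t_start: float | None = None,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> float:
    """Set-valued knockout: the classification-index error for removing
    ``targets`` jointly (kind 'pneg' or 'cneg') from ``t_start`` (default t0)."""
    if kind not in ("pneg", "cneg"):
        raise ValueError("knockouts use the pneg or cneg modification")
    if t_start is None:
        t_start = ref.start
    mod = make_modification(net, kind, targets, float(t_start))
    traj = simulate_modified(
        mod, ref.dense_eval(float(t_start)), (float(t_start), ref.end),
        rtol=rtol, atol=atol,
        ref_scale=max(1.0, float(np.max(np.abs(ref.states)))),
    )
    return _relative_l2_error(ref, traj, exp.response_species, float(t_start))


# ---------------------------------------------------------------------- #
@dataclass
class ClassificationReport:
    """Final labels with supporting evidence.

    ``labels`` assigns exactly one label per species (decision-tree order
    makes the classification non-overlapping); ``overlapping`` is the
    secondary report where each index is tested independently, so a species
    may satisfy several classifications.
    """

    species: tuple[str, ...]
    labels: dict[str, str]
    evidence: dict[str, dict]
    overlapping: dict[str, list[str]]
    delta_y: float
    delta_x: float

    def to_dict(self) -> dict:
        return {
            "thresholds": {"delta_y": self.delta_y, "delta_x": self.delta_x},
            "labels": dict(self.labels),
            "overlapping": {k: list(v) for k, v in self.overlapping.items()},
            "evidence": self.evidence,
        }

    def to_frame(self):
        import pandas as pd

        rows = []
        for s in self.species:
            ev = self.evidence[s]
            rows.append(
                {
                    "species": s,
                    "label": self.labels[s],
                    "max_nir": ev.get("max_nir"),
                    "max_env": ev.get("max_env"),
                    "max_pss": ev.get("max_pss"),
                    "max_cneg": ev.get("max_cneg"),
                    "max_pneg": ev.get("max_pneg"),
                    "max_state_err_env": ev.get("max_state_err_env"),
                    "max_state_err_pss": ev.get("max_state_err_pss"),
                }
            )
        return pd.DataFrame(rows)

    def count(self, label: str) -> int:
        return sum(1 for v in self.labels.values() if v == label)


def _check_grid(base: IndexSeries, other: IndexSeries) -> None:
    if not np.array_equal(base.t_grid, other.t_grid):
        raise GridMismatchError("all series entering the decision tree must share the t* grid")


def classify_states(
    nir: IndexSeries,
    class_indices: dict[str, dict[str, IndexSeries]],
    state_errs: dict[str, dict[str, IndexSeries]],
    delta_y: float = 0.10,
    delta_x: float = 0.10,
) -> ClassificationReport:
    """Apply the decision tree to the index series.

    ``class_indices[kind][species]`` and ``state_errs[kind][species]`` hold
    the per-species series for the kinds computed (only states that are not
    dynamic need them).
    """
    for kind_map in list(class_indices.values()) + list(state_errs.values()):
        for s in kind_map.values():
            _check_grid(nir, s)

    labels: dict[str, str] = {}
    evidence: dict[str, dict] = {}
    overlapping: dict[str, list[str]] = {}

    def below(kind_map, name, threshold):
        series = kind_map.get(name)
        if series is None:
            return False
        return series.below_threshold_everywhere(name, threshold)

    for name in nir.species:
        max_nir = nir.max_over_time(name)
        ev = {"max_nir": None if np.isnan(max_nir) else max_nir}
        for kind in ("env", "pss", "pneg", "cneg"):
            s = class_indices.get(kind, {}).get(name)
            m = s.max_over_time(name) if s is not None else float("nan")
            ev[f"max_{kind}"] = None if np.isnan(m) else m
        for kind in ("env", "pss"):
            s = state_errs.get(kind, {}).get(name)
            m = s.max_over_time(name) if s is not None else float("nan")
            ev[f"max_state_err_{kind}"] = None if np.isnan(m) else m
        evidence[name] = ev

        dynamic = (not np.isnan(max_nir)) and max_nir >= delta_y
        env_ok = below(class_indices.get("env", {}), name, delta_y) and below(
            state_errs.get("env", {}), name, delta_x
        )
        pss_ok = below(class_indices.get("pss", {}), name, delta_y) and below(
            state_errs.get("pss", {}), name, delta_x
        )
        cneg_ok = below(class_indices.get("cneg", {}), name, delta_y)
        pneg_ok = below(class_indices.get("pneg", {}), name, delta_y)

        over = []
        if dynamic:
            over.append("dynamic")
        if env_ok:
            over.append("environmental")
        if pss_ok:
            over.append("partial_steady_state")
        if cneg_ok:
            over.append("completely_negligible")
        if pneg_ok:
            over.append("partially_negligible")
        overlapping[name] = over

        if dynamic:
            labels[name] = "dynamic"
        elif env_ok:
            labels[name] = "environmental"
        elif pss_ok:
            labels[name] = "partial_steady_state"
        elif cneg_ok:
            labels[name] = "completely_negligible"
        elif pneg_ok:
            labels[name] = "partially_negligible"
        else:
            labels[name] = "unclassified"

    return ClassificationReport(
        species=nir.species,
        labels=labels,
        evidence=evidence,
        overlapping=overlapping,
        delta_y=delta_y,
        delta_x=delta_x,
    )


# ---------------------------------------------------------------------- #
def run_classification(
    net: ReactionNetwork,
    exp: IOExperiment,
    rtol: float = RTOL,
    atol: float = ATOL,
    grid_cap: int | None = 150,
    ref: Trajectory | None = None,
    log=None,
):
    """Full pipeline: reference solve, nir series, classification indices for
    every non-dynamic state, decision tree.

    Returns ``(report, artifacts)`` where ``artifacts`` carries the reference
    trajectory and every intermediate series for reporting.
    The t* grid is the reference solver's accepted-step grid, uniformly
    thinned to at most ``grid_cap`` points; the same grid serves the nir and
    all classification series so the decision tree compares like with like.
    """
    from . import sensitivity as sens
    from .trajectory import simulate

    def say(msg):
        if log is not None:
            log(msg)

    if ref is None:
        say("integrating reference trajectory")
        ref = simulate(net, exp.stimulated_state, exp.window, rtol=rtol, atol=atol)
    t_grid = ref.times
    if grid_cap is not None and len(t_grid) > grid_cap:
        idx = np.unique(np.linspace(0, len(t_grid) - 1, grid_cap).round().astype(int))
        t_grid = t_grid[idx]

    say(f"t* grid: {len(t_grid)} points")
    C = sens.controllability_series(net, ref, exp, t_grid, rtol, atol)
    say("observability series")
    O = sens.observability_series(net, ref, exp, t_grid, rtol, atol)
    ir = sens.ir_series(C, O)
    nir, sum_ir = sens.nir_series(ir)

    class_indices: dict[str, dict[str, IndexSeries]] = {k: {} for k in ("env", "pss", "pneg", "cneg")}
    state_errs: dict[str, dict[str, IndexSeries]] = {k: {} for k in ("env", "pss")}
    for k, name in enumerate(net.species):
        max_nir = nir.max_over_time(name)
        if not np.isnan(max_nir) and max_nir >= exp.delta_y:
            continue  # dynamic: no further characterisation needed
        say(f"classification indices for {name}")
        for kind in ("env", "pss", "pneg", "cneg"):
            class_indices[kind][name] = classification_index_series(
                net, ref, exp, kind, k, t_grid, rtol, atol
            )
        for kind in ("env", "pss"):
            state_errs[kind][name] = state_error_series(
                net, ref, kind, k, t_grid, rtol, atol
            )

    report = classify_states(nir, class_indices, state_errs, exp.delta_y, exp.delta_x)
    artifacts = {
        "reference": ref,
        "t_grid": t_grid,
        "C": C,
        "O": O,
        "ir": ir,
        "nir": nir,
        "sum_ir": sum_ir,
        "class_indices": class_indices,
        "state_errs": state_errs,
    }
    return report, artifacts
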