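"""Per-state index values over the t* grid."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["IndexSeries", "GridMismatchError"]

INDEX_KINDS = ("C", "O", "ir", "nir", "env", "pss", "pneg", "cneg", "state_err")


class GridMismatchError(ValueError):
    """Two series that must share a t* grid do not."""


@dataclass
class IndexSeries:
    """Index values on the t* grid.

    ``values`` has shape (len(t_grid), len(species)); NaN marks failed
    computations, and ``excluded`` marks grid points dropped from
    thresholding (e.g. where the Eq-normalisation integral degenerates
    near the end of the window).
    """

    t_grid: np.ndarray
    values: np.ndarray
    kind: str
    species: tuple[str, ...]
    excluded: np.ndarray | None = None

    def __post_init__(self):
        self.t_grid = np.asarray(self.t_grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.values.shape != (len(self.t_grid), len(self.species)):
            raise ValueError(
                f"values shape {self.values.shape} does not match grid x species "
                f"({len(self.t_grid)}, {len(self.species)})"
            )
        if self.excluded is None:
            self.excluded = np.zeros(len(self.t_grid), dtype=bool)
        else:
            self.excluded = np.asarray(self.excluded, dtype=bool)

    # ------------------------------------------------------------------ #
    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.species.index(name)]

    @property
    def valid_mask(self) -> np.ndarray:
        return ~self.excluded

    def max_over_time(self, name: str | None = None):
        """NaN-aware maximum over non-excluded grid points (per species)."""
        vals = self.values[self.valid_mask]
        if vals.size == 0:
            out = np.full(len(self.species), np.nan)
        else:
            with np.errstate(all="ignore"):
                out = np.where(
                    np.all(np.isnan(vals), axis=0), np.nan, np.nanmax(vals, axis=0)
                )
        if name is None:
            return dict(zip(self.species, out))
        return float(out[self.species.index(name)])

    def argmax_time(self, name: str) -> float:
        col = self.column(name).copy()
        col[self.excluded] = np.nan
        if np.all(np.isnan(col)):
            return float("nan")
        return float(self.t_grid[np.nanargmax(col)])

    def below_threshold_everywhere(self, name: str, threshold: float) -> bool:
        """True if the index stays strictly below ``threshold`` at every
        evaluated (non-excluded) grid point; NaN counts as a violation."""
        col = self.column(name)[self.valid_mask]
        if col.size == 0:
            return False
        if np.any(np.isnan(col)):
            return False
        return bool(np.all(col < threshold))

    # ------------------------------------------------------------------ #
    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.values, columns=list(self.species))
        df.insert(0, "t_star", self.t_grid)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, lineterminator="\n")

    def summary(self) -> dict:
        """Per-state maxima and argmax times (JSON-friendly)."""
        return {
            "kind": self.kind,
            "per_state": {
                s: {
                    "max": _jsonify(self.max_over_time(s)),
                    "argmax_time": _jsonify(self.argmax_time(s)),
                }
                for s in self.species
            },
        }


def _jsonify(x: float):
    return None if np.isnan(x) else float(x)
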