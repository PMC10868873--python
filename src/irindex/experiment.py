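"""Input/response experiment definitions.

An :class:`IOExperiment` fixes everything the indices are conditional on: the
input species and the magnitude of the delta stimulus applied at ``t0``, the
response species read out, the pre-stimulus baseline state, the analysis
window, and the two classification thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["IOExperiment"]


@dataclass(frozen=True)
class IOExperiment:
    """A single-input / single-response index-analysis experiment.

    Attributes
    ----------
    input_species, response_species:
        Species indices i and r; the response map is the coordinate selector
        y(t) = x_r(t).  The formalism assumes r != i.
    input_magnitude:
        Delta-input u0 (nM) added to the baseline at t0.
    baseline_state:
        Pre-stimulus state x0 (nM).
    t0, t_end:
        Analysis window [t0, T] in minutes.
    delta_y, delta_x:
        Output-index and state-error thresholds (fractions, default 10%).
    """

    input_species: int
    response_species: int
    input_magnitude: float
    baseline_state: np.ndarray
    t0: float = 0.0
    t_end: float = 10.0
    delta_y: float = 0.10
    delta_x: float = 0.10

    def __post_init__(self):
        x0 = np.asarray(self.baseline_state, dtype=float)
        object.__setattr__(self, "baseline_state", x0)
        if self.response_species == self.input_species:
            raise ValueError("response species must differ from the input species")
        if not self.t0 < self.t_end:
            raise ValueError("require t0 < T")
        if np.any(x0 < 0):
            raise ValueError("baseline state must be componentwise nonnegative")
        if not self.input_magnitude > 0:
            raise ValueError("input magnitude u0 must be positive")
        for name in ("delta_y", "delta_x"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be a fraction in (0, 1), got {v}")

    @property
    def stimulated_state(self) -> np.ndarray:
        """x0 + u0 e_i: the initial condition of the reference trajectory."""
        x = self.baseline_state.copy()
        x[self.input_species] += self.input_magnitude
        return x

    @property
    def window(self) -> tuple[float, float]:
        return (self.t0, self.t_end)

    def with_thresholds(self, delta_y: float | None = None, delta_x: float | None = None):
        return replace(
            self,
            delta_y=self.delta_y if delta_y is None else delta_y,
            delta_x=self.delta_x if delta_x is None else delta_x,
        )
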