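"""Probe time series produced by a simulation run."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Recording"]


@dataclass
class Recording:
    """Membrane-potential traces at probe elements plus run metadata.

    ``V`` is shaped (n_samples, n_probes); ``times`` strictly increasing (s);
    ``probes`` the recorded element indices; ``positions`` their centre arc
    distances from element 0 (m).  ``metadata`` echoes the resolved run
    configuration (scheme, eta, dt, dtc, n_elements, seed, ...).
    """

    times: np.ndarray
    V: np.ndarray
    probes: list[int]
    positions: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.V = np.asarray(self.V, float)
        if self.V.ndim == 1:
            self.V = self.V[:, None]
        if self.V.shape != (self.times.size, len(self.probes)):
            raise ValueError(
                f"trace array shape {self.V.shape} does not match "
                f"{self.times.size} samples x {len(self.probes)} probes")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def trace(self, probe: int) -> np.ndarray:
        """Potential series (V) at one probe element index."""
        try:
            j = self.probes.index(probe)
        except ValueError:
            raise KeyError(f"no trace recorded for element {probe}") from None
        return self.V[:, j]

    def position(self, probe: int) -> float:
        return float(self.positions[self.probes.index(probe)])

    @property
    def n_samples(self) -> int:
        return int(self.times.size)
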