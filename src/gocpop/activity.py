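"""Population-activity container and generic raster utilities."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PopulationActivity"]


@dataclass
class PopulationActivity:
    """Neurons x time activity matrix.

    Parameters
    ----------
    rates : ndarray, shape (n_neurons, n_bins)
        Event rates in Hz (``kind="events"``) or dimensionless dF/F
        (``kind="dff"``).
    bin : float
        Temporal bin width in seconds.
    positions : ndarray, shape (n_neurons, 3), optional
        Somatic positions in micrometres. ``None`` when the source carries
        no geometry (e.g. fluorescence without registration).
    kind : {"events", "dff"}
    """

    rates: np.ndarray
    bin: float
    positions: np.ndarray | None = None
    kind: str = "events"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.ndim != 2:
            raise ValueError("rates must be a 2-D neurons x time matrix")
        if not np.all(np.isfinite(self.rates)):
            raise ValueError("rates must be finite")
        if self.bin <= 0:
            raise ValueError("bin must be positive")
        if self.kind not in ("events", "dff"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=float)
            if self.positions.shape != (self.rates.shape[0], 3):
                raise ValueError("positions must be (n_neurons, 3)")

    @property
    def n_neurons(self) -> int:
        return self.rates.shape[0]

    @property
    def n_bins(self) -> int:
        return self.rates.shape[1]

    @property
    def duration(self) -> float:
        """Total covered time in seconds."""
        return self.n_bins * self.bin

    def select(self, idx: np.ndarray) -> "PopulationActivity":
        """Return the sub-population given by neuron indices `idx`."""
        pos = None if self.positions is None else self.positions[idx]
        return PopulationActivity(
            rates=self.rates[idx], bin=self.bin, positions=pos, kind=self.kind,
            meta=dict(self.meta),
        )
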