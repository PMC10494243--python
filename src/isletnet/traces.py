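"""In-memory container for multicellular fluorescence recordings."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .protocol import Protocol


@dataclass
class TraceSet:
    """A time x cells fluorescence matrix with acquisition metadata.

    Attributes
    ----------
    F : ndarray, shape (n_samples, n_cells)
        Fluorescence (arbitrary units, or dimensionless after F/F0).
    fs : float
        Sampling frequency in Hz.
    positions : ndarray, shape (n_cells, 2)
        Cell centroid coordinates in micrometers.
    protocol : Protocol
        Stimulation timeline the recording was acquired under.
    islet_id : str
    t0 : float
        Acquisition start time in seconds (protocol clock).
    cell_ids : list of str
    """

    F: np.ndarray
    fs: float
    positions: np.ndarray
    protocol: Protocol
    islet_id: str = "islet"
    t0: float = 0.0
    cell_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        if self.F.ndim != 2:
            raise ValueError("F must be a 2-D (time x cells) matrix")
        if not np.isfinite(self.F).all():
            raise ValueError("F contains missing or non-finite samples")
        if self.fs <= 0:
            raise ValueError("sampling frequency must be positive")
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (self.F.shape[1], 2):
            raise ValueError("positions must be (n_cells, 2)")
        if not self.cell_ids:
            self.cell_ids = [f"cell{i:03d}" for i in range(self.n_cells)]
        if len(self.cell_ids) != self.n_cells:
            raise ValueError("cell_ids length must equal the number of cells")

    @property
    def n_samples(self) -> int:
        return self.F.shape[0]

    @property
    def n_cells(self) -> int:
        return self.F.shape[1]

    @property
    def time(self) -> np.ndarray:
        """Sample times in seconds on the protocol clock."""
        return self.t0 + np.arange(self.n_samples) / self.fs

    @property
    def t_end(self) -> float:
        return self.t0 + (self.n_samples - 1) / self.fs

    def with_matrix(self, F: np.ndarray) -> "TraceSet":
        """Copy of this trace set with a replaced fluorescence matrix."""
        return replace(self, F=np.asarray(F, dtype=float))

    def subset(self, keep: np.ndarray | list[int]) -> "TraceSet":
        keep = np.asarray(keep, dtype=int)
        return replace(
            self,
            F=self.F[:, keep],
            positions=self.positions[keep],
            cell_ids=[self.cell_ids[i] for i in keep],
        )

    def index_at(self, t: float) -> int:
        """Index of the sample nearest to protocol time ``t``."""
        i = int(round((t - self.t0) * self.fs))
        return min(max(i, 0), self.n_samples - 1)

    def slice_interval(self, interval: tuple[float, float]) -> np.ndarray:
        """View of F restricted to a [start, end) interval in seconds."""
        a, b = interval
        if b <= a:
            raise ValueError("interval end must exceed its start")
        i0 = self.index_at(a)
        i1 = self.index_at(b)
        if i1 <= i0:
            raise ValueError("interval does not cover any samples")
        return self.F[i0:i1]
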