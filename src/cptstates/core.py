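"""Core in-memory containers shared across the analysis stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class CalciumTraceSet:
    """Per-session fluorescence traces with spatial metadata.

    Parameters
    ----------
    traces : ndarray, shape (n_neurons, n_frames)
        Extracted single-cell fluorescence (arbitrary units, e.g. ΔF/F or
        z-scored), sampled at ``frame_rate_hz``.
    frame_rate_hz : float
        Acquisition rate; the recordings this models are 10 Hz miniscope data.
    centroids_um : ndarray or None, shape (n_neurons, 2)
        Cell-centroid coordinates in micrometres, used for spatial analyses.
    neuron_ids : ndarray or None
        Stable per-cell identifiers; defaults to ``cell_0000 ...``.
    """

    traces: np.ndarray
    frame_rate_hz: float = 10.0
    centroids_um: np.ndarray | None = None
    neuron_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces, dtype=float)
        if self.traces.ndim != 2:
            raise ValueError("traces must be a 2-D (n_neurons, n_frames) array")
        if not np.isfinite(self.traces).all():
            raise ValueError("traces contain non-finite values")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if self.centroids_um is not None:
            self.centroids_um = np.asarray(self.centroids_um, dtype=float)
            if self.centroids_um.shape != (self.n_neurons, 2):
                raise ValueError(
                    "centroids_um must have shape (n_neurons, 2); got "
                    f"{self.centroids_um.shape}"
                )
        if self.neuron_ids is None:
            self.neuron_ids = np.array(
                [f"cell_{i:04d}" for i in range(self.n_neurons)], dtype=object
            )
        else:
            self.neuron_ids = np.asarray(self.neuron_ids, dtype=object)
            if self.neuron_ids.shape[0] != self.n_neurons:
                raise ValueError("neuron_ids length must equal n_neurons")

    @property
    def n_neurons(self) -> int:
        return self.traces.shape[0]

    @property
    def n_frames(self) -> int:
        return self.traces.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz

    def subset(self, idx: np.ndarray) -> "CalciumTraceSet":
        """Return a new trace set restricted to the given neuron indices."""
        idx = np.asarray(idx)
        return CalciumTraceSet(
            traces=self.traces[idx],
            frame_rate_hz=self.frame_rate_hz,
            centroids_um=None if self.centroids_um is None else self.centroids_um[idx],
            neuron_ids=self.neuron_ids[idx],
        )

    def pairwise_distances_um(self) -> np.ndarray:
        """Euclidean distance matrix between cell centroids (µm)."""
        if self.centroids_um is None:
            raise ValueError("trace set has no centroid coordinates")
        diff = self.centroids_um[:, None, :] - self.centroids_um[None, :, :]
        return np.sqrt((diff**2).sum(axis=-1))


def time_to_frame(times_s, frame_rate_hz: float) -> np.ndarray:
    """Convert event times (s) to frame indices by flooring at the frame rate."""
    return np.floor(np.asarray(times_s, dtype=float) * frame_rate_hz).astype(int)
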