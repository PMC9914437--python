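"""In-memory container for a multi-channel EEG recording with event markers.

Marker positions are 0-based sample indices here; the BrainVision file
layer converts to the format's 1-based convention at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MARKER_LABELS", "Marker", "EEGRecording"]

#: Stimulus/response annotations used by the hearing test:
#: S1/S3 left/right tone onset, S2/S4 heard response, S5 pause midpoint.
MARKER_LABELS: frozenset[str] = frozenset({"S1", "S2", "S3", "S4", "S5"})


@dataclass(frozen=True)
class Marker:
    label: str
    position: int  # 0-based sample index

    def __post_init__(self) -> None:
        if self.label not in MARKER_LABELS:
            raise ValueError(f"unknown marker label {self.label!r}")
        if self.position < 0:
            raise ValueError("marker position must be non-negative")


@dataclass
class EEGRecording:
    """channels x samples array in microvolts plus an ordered marker stream."""

    data: np.ndarray
    fs_hz: float
    channel_labels: list[str] = field(default_factory=list)
    markers: list[Marker] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if not self.channel_labels:
            self.channel_labels = [f"Ch{i + 1}" for i in range(self.n_channels)]
        if len(self.channel_labels) != self.n_channels:
            raise ValueError("channel_labels length must match channel count")
        positions = [m.position for m in self.markers]
        if positions != sorted(positions):
            raise ValueError("markers must be sorted by position")
        if positions and (positions[0] < 0 or positions[-1] >= self.n_samples):
            raise ValueError("marker positions must lie within the recording")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def copy_with(self, data: np.ndarray) -> "EEGRecording":
        """Same metadata and markers, new sample array."""
        return EEGRecording(
            data=data,
            fs_hz=self.fs_hz,
            channel_labels=list(self.channel_labels),
            markers=list(self.markers),
        )
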