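"""From the marker stream to labeled heard/unheard epochs.

Every stimulus marker (S1 left, S3 right) opens a segment that runs to the
next S1/S3/S5 marker.  A matching response marker (S2 for S1, S4 for S3)
inside that segment labels the trial *heard*; otherwise *unheard*.  Every
pause marker (S5) yields a silence event, always labeled unheard — no tone
was playing, so nothing was heard by construction.

Epochs are fixed-length windows cut forward from each event's sample, over
a channel subset (the full 16 channels, or the 1-13 / 1-8 subsets used for
ablation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .recording import EEGRecording, Marker

__all__ = [
    "CHANNEL_SUBSETS",
    "MalformedStreamError",
    "LabeledEvent",
    "Epoch",
    "label_events",
    "extract_epochs",
]

logger = logging.getLogger(__name__)

#: Ablation presets, as 0-based channel indices.
CHANNEL_SUBSETS: dict[str, tuple[int, ...]] = {
    "1-16": tuple(range(16)),
    "1-13": tuple(range(13)),
    "1-8": tuple(range(8)),
}

_STIMULUS = {"S1": "left_stimulus", "S3": "right_stimulus"}
_RESPONSE_FOR = {"S1": "S2", "S3": "S4"}
_SEGMENT_BREAK = {"S1", "S3", "S5"}


class MalformedStreamError(ValueError):
    """A response marker has no preceding matching stimulus marker."""


@dataclass(frozen=True)
class LabeledEvent:
    kind: str  # left_stimulus | right_stimulus | silence
    position: int  # 0-based sample index
    label: str  # heard | unheard

    def __post_init__(self) -> None:
        if self.kind == "silence" and self.label != "unheard":
            raise ValueError("silence events are unheard by construction")


@dataclass
class Epoch:
    data: np.ndarray  # channels x window samples
    label: str
    event: LabeledEvent
    window_s: float


def label_events(markers: Sequence[Marker]) -> list[LabeledEvent]:
    """Fold the S1-S5 stream into labeled stimulus and silence events."""
    events: list[LabeledEvent] = []
    open_stimulus: Marker | None = None  # stimulus whose segment is still open
    responded = False

    def close_segment() -> None:
        nonlocal open_stimulus, responded
        if open_stimulus is not None:
            events.append(
                LabeledEvent(
                    kind=_STIMULUS[open_stimulus.label],
                    position=open_stimulus.position,
                    label="heard" if responded else "unheard",
                )
            )
        open_stimulus = None
        responded = False

    for marker in markers:
        if marker.label in _STIMULUS:
            close_segment()
            open_stimulus = marker
        elif marker.label == "S5":
            close_segment()
            events.append(
                LabeledEvent(kind="silence", position=marker.position, label="unheard")
            )
        else:  # S2 / S4 response
            if open_stimulus is None or _RESPONSE_FOR[open_stimulus.label] != marker.label:
                raise MalformedStreamError(
                    f"{marker.label} at sample {marker.position} has no matching "
                    "open stimulus marker"
                )
            responded = True
    close_segment()
    return events


def extract_epochs(
    rec: EEGRecording,
    events: Sequence[LabeledEvent],
    window_s: float = 0.7,
    channel_subset: str | Sequence[int] | None = None,
) -> list[Epoch]:
    """Cut a forward window per event from the (preprocessed) recording.

    ``channel_subset`` may be a preset name ("1-16", "1-13", "1-8") or an
    explicit sequence of 0-based channel indices; default is all channels.
    Events whose window would run past the end of the recording are
    dropped with a logged warning.
    """
    if isinstance(channel_subset, str):
        try:
            channels: Sequence[int] = CHANNEL_SUBSETS[channel_subset]
        except KeyError:
            raise ValueError(
                f"unknown channel subset {channel_subset!r}; presets: "
                f"{sorted(CHANNEL_SUBSETS)}"
            ) from None
    elif channel_subset is None:
        channels = tuple(range(rec.n_channels))
    else:
        channels = tuple(int(c) for c in channel_subset)
    if any(c < 0 or c >= rec.n_channels for c in channels):
        raise ValueError("channel index outside the recording")

    n_win = int(round(window_s * rec.fs_hz))
    idx = np.asarray(channels)
    epochs: list[Epoch] = []
    dropped = 0
    for event in events:
        stop = event.position + n_win
        if stop > rec.n_samples:
            dropped += 1
            continue
        epochs.append(
            Epoch(
                data=rec.data[idx, event.position : stop],
                label=event.label,
                event=event,
                window_s=window_s,
            )
        )
    if dropped:
        logger.warning("dropped %d event(s) whose window ran past the recording end", dropped)
    return epochs
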