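"""Adaptive random pure-tone audiometry protocol.

Classic clinical audiometry walks a staircase (Hughson-Westlake: down 10 dB
after a heard tone, up 5 dB after a missed one).  The protocol implemented
here instead draws tones *randomly* from a fixed frequency x intensity grid
and prunes the grid after every response:

* a **heard** tone removes all louder tones at the same frequency and ear
  (the listener would hear those too);
* an **unheard** tone removes all quieter tones at the same frequency and
  ear (the listener would miss those too).

Random presentation keeps the auditory stimulus unpredictable (a stronger
cortical response), while pruning keeps the session short.  For a
deterministic listener the pruning rules guarantee that the minimum heard
intensity per frequency equals the true hearing threshold, whatever order
the tones happen to be drawn in.

The grid is 8 frequencies x 12 intensities = 96 tones per ear, 192 for a
both-ear session; the left ear is always tested to exhaustion before the
right.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "FREQUENCIES_HZ",
    "INTENSITIES_DB",
    "EARS",
    "NEVER_HEARS_DB",
    "NO_RESPONSE",
    "Stimulus",
    "TrialRecord",
    "TestState",
    "ListenerModel",
    "Audiogram",
    "ProtocolViolationError",
    "ConfigurationError",
    "build_grid",
    "next_stimulus",
    "apply_response",
    "simulate_listener",
    "run_session",
    "compute_audiogram",
    "save_session",
    "load_session",
    "save_audiogram",
]

#: Test frequencies in Hz (standard audiometric octaves plus 12 kHz).
FREQUENCIES_HZ: tuple[int, ...] = (125, 250, 500, 1000, 2000, 4000, 8000, 12000)

#: Intensity grid in dB HL, 10 dB steps.
INTENSITIES_DB: tuple[int, ...] = tuple(range(10, 121, 10))

EARS: tuple[str, str] = ("left", "right")

#: Listener threshold encoding "never hears" (above the loudest grid tone).
NEVER_HEARS_DB: float = 130.0

#: Audiogram sentinel for a frequency with no heard trial.
NO_RESPONSE = None


class ProtocolViolationError(RuntimeError):
    """A response was applied to a stimulus the protocol no longer offers."""


class ConfigurationError(ValueError):
    """A listener or session configuration is incomplete or inconsistent."""


@dataclass(frozen=True, order=True)
class Stimulus:
    """One pure tone: which ear, which frequency, how loud."""

    ear: str
    frequency_hz: int
    intensity_db: int

    def __post_init__(self) -> None:
        if self.ear not in EARS:
            raise ValueError(f"ear must be one of {EARS}, got {self.ear!r}")
        if self.frequency_hz <= 0 or self.intensity_db <= 0:
            raise ValueError("frequency and intensity must be positive")


@dataclass(frozen=True)
class TrialRecord:
    """One presented tone and its outcome.

    ``response_s`` is the absolute session time of the button press and is
    present exactly when the tone was heard.
    """

    stimulus: Stimulus
    heard: bool
    onset_s: float
    response_s: float | None = None

    def __post_init__(self) -> None:
        if self.heard and self.response_s is None:
            raise ValueError("heard trial requires a response time")
        if not self.heard and self.response_s is not None:
            raise ValueError("unheard trial must not carry a response time")
        if self.response_s is not None and self.response_s <= self.onset_s:
            raise ValueError("response must come after the stimulus onset")


@dataclass
class TestState:
    """Mutable session state: what is left to present, what has been."""

    remaining: dict[str, set[Stimulus]]
    trials: list[TrialRecord] = field(default_factory=list)
    ear_order: tuple[str, ...] = EARS

    @property
    def current_ear(self) -> str | None:
        """The ear currently under test; the left ear is exhausted first."""
        for ear in self.ear_order:
            if self.remaining.get(ear):
                return ear
        return None

    @property
    def done(self) -> bool:
        return self.current_ear is None

    def n_remaining(self, ear: str | None = None) -> int:
        if ear is not None:
            return len(self.remaining.get(ear, ()))
        return sum(len(s) for s in self.remaining.values())


@dataclass
class ListenerModel:
    """Simulated respondent with one hearing threshold per (ear, frequency).

    ``slope_db == 0`` gives a deterministic listener (heard iff the tone is
    at or above threshold); a positive slope gives a logistic psychometric
    function with P(heard) = 0.5 exactly at threshold.
    """

    thresholds: dict[tuple[str, int], float]
    slope_db: float = 0.0

    def __post_init__(self) -> None:
        if self.slope_db < 0:
            raise ConfigurationError("psychometric slope must be >= 0")
        for key, thr in self.thresholds.items():
            if not (INTENSITIES_DB[0] <= thr <= NEVER_HEARS_DB):
                raise ConfigurationError(
                    f"threshold {thr} dB for {key} outside "
                    f"[{INTENSITIES_DB[0]}, {NEVER_HEARS_DB}]"
                )

    @classmethod
    def flat(
        cls,
        threshold_db: float,
        ears: Iterable[str] = EARS,
        frequencies: Iterable[int] = FREQUENCIES_HZ,
        slope_db: float = 0.0,
    ) -> "ListenerModel":
        """Same threshold at every ear and frequency."""
        thr = {(e, f): float(threshold_db) for e in ears for f in frequencies}
        return cls(thresholds=thr, slope_db=slope_db)


@dataclass
class Audiogram:
    """Per-ear map frequency -> lowest heard intensity (dB HL) or ``None``."""

    thresholds: dict[str, dict[int, int | None]]

    def threshold(self, ear: str, frequency_hz: int) -> int | None:
        return self.thresholds[ear][frequency_hz]


def build_grid(
    ears: Iterable[str],
    frequencies: Sequence[int] = FREQUENCIES_HZ,
    intensities: Sequence[int] = INTENSITIES_DB,
) -> TestState:
    """Construct the full Cartesian stimulus grid for the requested ears.

    A reduced grid (fewer frequencies/intensities) may be passed for
    screening-style sessions; the defaults give 96 tones per ear.
    """
    ears = tuple(dict.fromkeys(ears))  # dedupe, keep order of first mention
    if not ears:
        raise ValueError("at least one ear must be requested")
    for ear in ears:
        if ear not in EARS:
            raise ValueError(f"unknown ear {ear!r}")
    # left before right regardless of argument order
    ear_order = tuple(e for e in EARS if e in ears)
    remaining = {
        ear: {
            Stimulus(ear=ear, frequency_hz=int(f), intensity_db=int(i))
            for f in frequencies
            for i in intensities
        }
        for ear in ear_order
    }
    return TestState(remaining=remaining, ear_order=ear_order)


def next_stimulus(state: TestState, rng: np.random.Generator) -> Stimulus | None:
    """Uniform random draw from the current ear's remaining tones.

    Returns ``None`` when every requested ear is exhausted.  The draw is a
    pure function of the RNG state and the remaining set (candidates are
    sorted before drawing so set iteration order cannot leak in).
    """
    ear = state.current_ear
    if ear is None:
        return None
    candidates = sorted(state.remaining[ear])
    return candidates[int(rng.integers(len(candidates)))]


def apply_response(
    state: TestState,
    stimulus: Stimulus,
    heard: bool,
    onset_s: float,
    response_s: float | None = None,
) -> TestState:
    """Record a response and prune the grid (in place; returns ``state``).

    Heard: every louder tone at the same ear/frequency is removed.
    Unheard: every quieter tone at the same ear/frequency is removed.
    """
    pool = state.remaining.get(stimulus.ear, set())
    if stimulus not in pool:
        raise ProtocolViolationError(
            f"{stimulus} is not available (already presented or pruned)"
        )
    pool.remove(stimulus)
    if heard:
        pruned = {
            s
            for s in pool
            if s.frequency_hz == stimulus.frequency_hz
            and s.intensity_db > stimulus.intensity_db
        }
    else:
        pruned = {
            s
            for s in pool
            if s.frequency_hz == stimulus.frequency_hz
            and s.intensity_db < stimulus.intensity_db
        }
    pool -= pruned
    state.trials.append(
        TrialRecord(stimulus=stimulus, heard=heard, onset_s=onset_s, response_s=response_s)
    )
    return state


def simulate_listener(
    model: ListenerModel, stimulus: Stimulus, rng: np.random.Generator
) -> bool:
    """Does this listener hear this tone?

    Deterministic (slope 0): heard iff intensity >= threshold.  With a
    positive slope the probability is logistic in (intensity - threshold) /
    slope, so it is exactly 0.5 at threshold.
    """
    key = (stimulus.ear, stimulus.frequency_hz)
    try:
        thr = model.thresholds[key]
    except KeyError as exc:
        raise ConfigurationError(f"listener has no threshold for {key}") from exc
    if model.slope_db == 0:
        return stimulus.intensity_db >= thr
    p = expit((stimulus.intensity_db - thr) / model.slope_db)
    return bool(rng.random() < p)


def _sample_response_latency(
    rng: np.random.Generator, mean_s: float, sd_s: float, max_s: float
) -> float:
    """Truncated-normal button-press delay, bounded away from 0 and ``max_s``."""
    for _ in range(1000):
        lat = rng.normal(mean_s, sd_s)
        if 0.05 <= lat < max_s:
            return float(lat)
    return float(min(max(mean_s, 0.05), max_s * 0.99))


def run_session(
    model: ListenerModel,
    ears: Iterable[str] = EARS,
    seed: int = 0,
    isi_s: float = 2.0,
    frequencies: Sequence[int] = FREQUENCIES_HZ,
    intensities: Sequence[int] = INTENSITIES_DB,
    response_latency_mean_s: float = 0.45,
    response_latency_sd_s: float = 0.08,
    response_latency_max_s: float = 0.65,
) -> list[TrialRecord]:
    """Run a full adaptive session against a simulated listener.

    Tones are spaced ``isi_s`` apart, first onset at ``isi_s``.  Heard
    trials get a button-press time drawn from a truncated normal so the
    response always falls inside the analysis window of the recording.
    """
    rng = np.random.default_rng(seed)
    state = build_grid(ears, frequencies=frequencies, intensities=intensities)
    k = 0
    while not state.done:
        stim = next_stimulus(state, rng)
        assert stim is not None
        heard = simulate_listener(model, stim, rng)
        onset = isi_s * (k + 1)
        response = None
        if heard:
            response = onset + _sample_response_latency(
                rng, response_latency_mean_s, response_latency_sd_s, response_latency_max_s
            )
        apply_response(state, stim, heard, onset, response)
        k += 1
    return state.trials


def compute_audiogram(
    trials: Sequence[TrialRecord],
    ears: Iterable[str] | None = None,
    frequencies: Iterable[int] | None = None,
) -> Audiogram:
    """Lowest heard intensity per ear and frequency.

    Frequencies with no heard trial get the ``NO_RESPONSE`` sentinel
    (``None``).  By default the ear/frequency grid is inferred from the
    presented trials (every grid frequency receives at least one trial in a
    completed session).
    """
    if ears is None:
        ears = sorted({t.stimulus.ear for t in trials}, key=EARS.index)
    if frequencies is None:
        frequencies = sorted({t.stimulus.frequency_hz for t in trials})
    result: dict[str, dict[int, int | None]] = {
        ear: {f: NO_RESPONSE for f in frequencies} for ear in ears
    }
    for t in trials:
        if not t.heard:
            continue
        row = result[t.stimulus.ear]
        prev = row[t.stimulus.frequency_hz]
        if prev is None or t.stimulus.intensity_db < prev:
            row[t.stimulus.frequency_hz] = t.stimulus.intensity_db
    return Audiogram(thresholds=result)


# ---------------------------------------------------------------------------
# session / audiogram persistence

_SESSION_COLUMNS = ["ear", "frequency_hz", "intensity_db", "heard", "onset_s", "response_s"]


def session_frame(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "ear": t.stimulus.ear,
                "frequency_hz": t.stimulus.frequency_hz,
                "intensity_db": t.stimulus.intensity_db,
                "heard": t.heard,
                "onset_s": t.onset_s,
                "response_s": t.response_s,
            }
            for t in trials
        ],
        columns=_SESSION_COLUMNS,
    )


def save_session(trials: Sequence[TrialRecord], path: str | Path) -> None:
    """Write a session log as CSV, or JSON when the suffix is ``.json``."""
    path = Path(path)
    frame = session_frame(trials)
    if path.suffix.lower() == ".json":
        records = frame.to_dict(orient="records")  # json round-trips full doubles
        path.write_text(json.dumps(records, indent=2, default=float))
    else:
        frame.to_csv(path, index=False, float_format="%.17g")


def load_session(path: str | Path) -> list[TrialRecord]:
    path = Path(path)
    if path.suffix.lower() == ".json":
        frame = pd.DataFrame(json.loads(path.read_text()), columns=_SESSION_COLUMNS)
    else:
        frame = pd.read_csv(path, float_precision="round_trip")
    trials = []
    for row in frame.itertuples(index=False):
        response = None if pd.isna(row.response_s) else float(row.response_s)
        trials.append(
            TrialRecord(
                stimulus=Stimulus(
                    ear=str(row.ear),
                    frequency_hz=int(row.frequency_hz),
                    intensity_db=int(row.intensity_db),
                ),
                heard=bool(row.heard),
                onset_s=float(row.onset_s),
                response_s=response,
            )
        )
    return trials


def save_audiogram(audiogram: Audiogram, path: str | Path) -> None:
    """Write per-ear thresholds; unheard frequencies render as ``NR``."""
    path = Path(path)
    records = [
        {
            "ear": ear,
            "frequency_hz": freq,
            "threshold_db": "NR" if thr is None else thr,
        }
        for ear, row in audiogram.thresholds.items()
        for freq, thr in sorted(row.items())
    ]
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(records, indent=2))
    else:
        pd.DataFrame(records).to_csv(path, index=False)
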