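"""Synthetic 16-channel EEG with P300-like responses to heard tones.

The generator turns a hearing-test session log into a recording that
carries the information the downstream decoder is supposed to find: on
every *heard* trial a positive Gaussian deflection (peak ~300 ms after
tone onset, the P300 surrogate) is added on top of background noise;
unheard trials and inter-trial pauses are noise only.  The deflection has
a channel-dependent amplitude profile — full strength on channels 1-8,
half on 9-13, absent on 14-16 — so channel-ablation experiments have a
ground truth to recover.

The marker stream follows the hearing-test convention: S1/S3 at each
left/right tone onset, S2/S4 at the button press of a heard trial, and S5
at the midpoint of every inter-trial pause (a known-silent period, labeled
"unheard" downstream).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .protocol import TrialRecord
from .recording import EEGRecording, Marker

__all__ = [
    "DEFAULT_CHANNEL_PROFILE",
    "SynthConfig",
    "ErpTemplate",
    "make_erp_template",
    "generate_recording",
]

#: Per-channel ERP amplitude multipliers: strong on channels 1-8, attenuated
#: on 9-13, absent on 14-16.
DEFAULT_CHANNEL_PROFILE: tuple[float, ...] = (1.0,) * 8 + (0.5,) * 5 + (0.0,) * 3


class SynthConfigError(ValueError):
    """Inconsistent synthetic-recording configuration."""


@dataclass
class SynthConfig:
    """Knobs of the synthetic recording.

    Amplitudes and noise are in microvolts.  ``epoch_window_s`` is the
    post-event analysis window the downstream pipeline will cut; the
    generator uses it to place pause (S5) markers after the window and to
    reject sessions whose tones are packed tighter than the window.
    """

    n_channels: int = 16
    fs_hz: float = 2000.0
    noise_sigma_uv: float = 10.0
    noise_kind: str = "white"  # "white" | "pink"
    erp_amplitude_uv: float = 8.0
    erp_latency_s: float = 0.300
    erp_width_s: float = 0.060
    channel_profile: tuple[float, ...] = DEFAULT_CHANNEL_PROFILE
    response_latency_mean_s: float = 0.45
    response_latency_sd_s: float = 0.08
    epoch_window_s: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs_hz <= 100.0:
            raise SynthConfigError("sampling rate must exceed 100 Hz (50 Hz notch target)")
        if len(self.channel_profile) != self.n_channels:
            raise SynthConfigError("channel_profile length must equal n_channels")
        if any(m < 0 for m in self.channel_profile):
            raise SynthConfigError("channel multipliers must be >= 0")
        if self.noise_kind not in ("white", "pink"):
            raise SynthConfigError(f"unknown noise kind {self.noise_kind!r}")
        if self.noise_sigma_uv < 0:
            raise SynthConfigError("noise sigma must be >= 0")


@dataclass
class ErpTemplate:
    """Gaussian-bump event-related potential, one amplitude per channel."""

    latency_s: float
    width_s: float
    amplitudes_uv: np.ndarray
    duration_s: float
    fs_hz: float

    def __post_init__(self) -> None:
        if self.latency_s <= 0 or self.width_s <= 0:
            raise ValueError("latency and width must be positive")
        self.amplitudes_uv = np.asarray(self.amplitudes_uv, dtype=float)

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs_hz))

    def waveform(self) -> np.ndarray:
        """channels x samples template, peak at ``latency_s`` after onset."""
        t = np.arange(self.n_samples) / self.fs_hz
        bump = np.exp(-0.5 * ((t - self.latency_s) / self.width_s) ** 2)
        return self.amplitudes_uv[:, None] * bump[None, :]


def make_erp_template(config: SynthConfig) -> ErpTemplate:
    """Template with per-channel peak = amplitude x channel multiplier."""
    return ErpTemplate(
        latency_s=config.erp_latency_s,
        width_s=config.erp_width_s,
        amplitudes_uv=config.erp_amplitude_uv * np.asarray(config.channel_profile),
        duration_s=config.epoch_window_s,
        fs_hz=config.fs_hz,
    )


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """1/f-shaped Gaussian noise, scaled to per-channel RMS ``sigma``."""
    n_ch, n_samp = shape
    white = rng.standard_normal(shape)
    spectrum = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samp)
    scale = np.ones_like(freqs)
    nonzero = freqs > 0
    scale[nonzero] = 1.0 / np.sqrt(freqs[nonzero])
    scale[0] = 0.0  # no DC offset
    shaped = np.fft.irfft(spectrum * scale[None, :], n=n_samp, axis=1)
    rms = shaped.std(axis=1, keepdims=True)
    rms[rms == 0] = 1.0
    return sigma * shaped / rms


def generate_recording(
    trials: Sequence[TrialRecord], config: SynthConfig | None = None
) -> EEGRecording:
    """Render a session log as a marker-annotated synthetic EEG recording.

    Heard trials receive the ERP template starting at their onset sample
    and an S2/S4 marker at their logged button-press time (sampled from
    the config's truncated normal if the log carries none).  Identical
    config and trial list give a bit-identical recording.
    """
    if config is None:
        config = SynthConfig()
    if not trials:
        raise ValueError("need at least one trial")
    trials = sorted(trials, key=lambda t: t.onset_s)
    fs = config.fs_hz
    window = config.epoch_window_s
    onsets = np.array([t.onset_s for t in trials])
    if np.any(np.diff(onsets) < window):
        raise SynthConfigError(
            "inter-stimulus interval shorter than the epoch window: epochs would overlap"
        )
    isi = float(np.min(np.diff(onsets))) if len(onsets) > 1 else 2.0 * window
    duration_s = float(onsets[-1]) + isi
    n_samples = int(round(duration_s * fs))

    rng = np.random.default_rng(config.seed)
    if config.noise_sigma_uv == 0:
        data = np.zeros((config.n_channels, n_samples))
    elif config.noise_kind == "pink":
        data = _pink_noise(rng, (config.n_channels, n_samples), config.noise_sigma_uv)
    else:
        data = rng.normal(0.0, config.noise_sigma_uv, (config.n_channels, n_samples))

    template = make_erp_template(config).waveform()
    n_t = template.shape[1]

    markers: list[Marker] = []
    for i, trial in enumerate(trials):
        pos = int(round(trial.onset_s * fs))
        if pos + n_t > n_samples:
            raise SynthConfigError("trial onset too close to the end of the recording")
        stim_label = "S1" if trial.stimulus.ear == "left" else "S3"
        markers.append(Marker(stim_label, pos))
        if trial.heard:
            data[:, pos : pos + n_t] += template
            response_s = trial.response_s
            if response_s is None:
                lat = abs(rng.normal(config.response_latency_mean_s, config.response_latency_sd_s))
                response_s = trial.onset_s + min(max(lat, 0.05), window - 2.0 / fs)
            resp_label = "S2" if trial.stimulus.ear == "left" else "S4"
            markers.append(Marker(resp_label, int(round(response_s * fs))))
        # pause midpoint between this trial's window end and the next onset
        next_onset = trials[i + 1].onset_s if i + 1 < len(trials) else duration_s
        pause_mid = ((trial.onset_s + window) + next_onset) / 2.0
        markers.append(Marker("S5", min(int(round(pause_mid * fs)), n_samples - 1)))

    markers.sort(key=lambda m: m.position)
    return EEGRecording(data=data, fs_hz=fs, markers=markers)
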