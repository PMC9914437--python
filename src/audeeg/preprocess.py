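"""Signal conditioning ahead of tokenization.

Fixed pipeline order: 50 Hz notch -> 1-12 Hz band-pass -> per-channel
min-max normalization to [0, 1] -> round to 3 decimals.  The 1-12 Hz band
is the conventional passband for P300 detection; the min-max + rounding
pair matters because the tokenizer downstream treats each rounded sample
value as a word, and bounding values to the 0.000..1.000 grid caps the
vocabulary at 1001 distinct tokens.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .recording import EEGRecording

__all__ = [
    "FilterSpec",
    "notch",
    "bandpass",
    "normalize",
    "round3",
    "preprocess_recording",
]


@dataclass
class FilterSpec:
    """Notch + band-pass design parameters.

    The filter family and order are design choices (the passband edges and
    notch frequency are the protocol's): a Q=30 second-order IIR notch and
    a 4th-order Butterworth band-pass, both applied forward-backward
    (zero phase) by default so ERP latencies are not shifted.
    """

    notch_freq_hz: float = 50.0
    notch_q: float = 30.0
    band_lo_hz: float = 1.0
    band_hi_hz: float = 12.0
    order: int = 4
    zero_phase: bool = True

    def validate(self, fs_hz: float) -> None:
        nyquist = fs_hz / 2.0
        if not (0 < self.band_lo_hz < self.band_hi_hz < nyquist):
            raise ValueError(
                f"band edges ({self.band_lo_hz}, {self.band_hi_hz}) must satisfy "
                f"0 < lo < hi < fs/2 = {nyquist}"
            )
        if not (0 < self.notch_freq_hz < nyquist):
            raise ValueError(f"notch frequency {self.notch_freq_hz} outside (0, fs/2)")
        if self.notch_q <= 0 or self.order < 1:
            raise ValueError("notch Q must be > 0 and order >= 1")


def notch(rec: EEGRecording, spec: FilterSpec | None = None) -> EEGRecording:
    """Second-order IIR notch at the mains frequency, per channel."""
    spec = spec or FilterSpec()
    spec.validate(rec.fs_hz)
    b, a = signal.iirnotch(spec.notch_freq_hz, spec.notch_q, fs=rec.fs_hz)
    if spec.zero_phase:
        filtered = signal.filtfilt(b, a, rec.data, axis=1)
    else:
        filtered = signal.lfilter(b, a, rec.data, axis=1)
    return rec.copy_with(filtered)


def bandpass(rec: EEGRecording, spec: FilterSpec | None = None) -> EEGRecording:
    """Butterworth band-pass (default 1-12 Hz, order 4), per channel."""
    spec = spec or FilterSpec()
    spec.validate(rec.fs_hz)
    sos = signal.butter(
        spec.order,
        (spec.band_lo_hz, spec.band_hi_hz),
        btype="bandpass",
        fs=rec.fs_hz,
        output="sos",
    )
    if spec.zero_phase:
        filtered = signal.sosfiltfilt(sos, rec.data, axis=1)
    else:
        filtered = signal.sosfilt(sos, rec.data, axis=1)
    return rec.copy_with(filtered)


def normalize(rec: EEGRecording) -> EEGRecording:
    """Per-channel min-max scaling of the whole recording into [0, 1].

    A constant channel has no scale; it maps to all zeros.
    """
    data = rec.data
    lo = data.min(axis=1, keepdims=True)
    hi = data.max(axis=1, keepdims=True)
    span = hi - lo
    out = np.zeros_like(data)
    np.divide(data - lo, span, out=out, where=span != 0)
    return rec.copy_with(out)


def round3(rec: EEGRecording) -> EEGRecording:
    """Round to 3 decimals (half-even, numpy's rule).

    On normalized input the result lies on the 1001-value grid
    0.000, 0.001, ..., 1.000 — the token alphabet of the featurizer.
    """
    return rec.copy_with(np.round(rec.data, 3))


def preprocess_recording(rec: EEGRecording, spec: FilterSpec | None = None) -> EEGRecording:
    """The full conditioning chain in its fixed order."""
    return round3(normalize(bandpass(notch(rec, spec), spec)))
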