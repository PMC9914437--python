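"""BrainVision triplet (.vhdr / .vmrk / .eeg) reader and writer.

The writer emits the dialect produced by Brain Products Recorder software:
an INI-style header, a marker file with 1-based ``Mk<n>=Stimulus,S<k>,<pos>,
1,0`` lines, and raw binary samples.  Written files are IEEE_FLOAT_32
multiplexed (lossless for this pipeline); the reader additionally accepts
INT_16 data with per-channel resolution scaling, VECTORIZED orientation,
and the blank-padded marker descriptions ("S  1") some recorders write.

Marker positions are 1-based in the files per the BrainVision convention
and 0-based in :class:`~audeeg.recording.EEGRecording`.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .recording import EEGRecording, Marker

__all__ = ["BrainVisionFormatError", "write_recording", "read_recording", "export_markers"]


class BrainVisionFormatError(ValueError):
    """A file of the triplet is missing, malformed, or inconsistent."""


def write_recording(
    rec: EEGRecording,
    basepath: str | Path,
    orientation: str = "MULTIPLEXED",
) -> tuple[Path, Path, Path]:
    """Write ``basepath``.vhdr/.vmrk/.eeg; returns the three paths.

    Data are written as IEEE_FLOAT_32 in the requested orientation
    (``MULTIPLEXED`` = sample-major, ``VECTORIZED`` = channel-major).
    """
    if orientation not in ("MULTIPLEXED", "VECTORIZED"):
        raise BrainVisionFormatError(f"unknown orientation {orientation!r}")
    basepath = Path(basepath)
    basepath.parent.mkdir(parents=True, exist_ok=True)
    vhdr, vmrk, eeg = (basepath.with_suffix(s) for s in (".vhdr", ".vmrk", ".eeg"))

    sampling_interval_us = 1e6 / rec.fs_hz
    # drop a trailing ".0" so integer intervals match recorder output
    si = f"{sampling_interval_us:.6f}".rstrip("0").rstrip(".")

    header = [
        "BrainVision Data Exchange Header File Version 1.0",
        "; Written by audeeg",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        f"MarkerFile={vmrk.name}",
        "DataFormat=BINARY",
        f"DataOrientation={orientation}",
        f"NumberOfChannels={rec.n_channels}",
        f"SamplingInterval={si}",
        "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "",
        "[Channel Infos]",
        "; Ch<n>=<name>,<reference>,<resolution in unit>,<unit>",
    ]
    header += [
        f"Ch{i + 1}={label},,1,µV" for i, label in enumerate(rec.channel_labels)
    ]
    vhdr.write_text("\n".join(header) + "\n", encoding="utf-8")

    marker_lines = [
        "BrainVision Data Exchange Marker File Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        "",
        "[Marker Infos]",
        "; Mk<n>=<type>,<description>,<position in data points>,<size>,<channel>",
    ]
    marker_lines += [
        f"Mk{i + 1}=Stimulus,{m.label},{m.position + 1},1,0"
        for i, m in enumerate(rec.markers)
    ]
    vmrk.write_text("\n".join(marker_lines) + "\n", encoding="utf-8")

    samples = np.asarray(rec.data, dtype=np.float32)
    if orientation == "MULTIPLEXED":
        samples = samples.T  # sample-major on disk
    samples.tofile(eeg)
    return vhdr, vmrk, eeg


_SECTION_RE = re.compile(r"^\[(?P<name>[^\]]+)\]\s*$")


def _parse_ini(text: str) -> dict[str, dict[str, str]]:
    """Minimal INI parse of the BrainVision dialect (``;`` comments)."""
    sections: dict[str, dict[str, str]] = {}
    current: dict[str, str] | None = None
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith(";"):
            continue
        m = _SECTION_RE.match(line)
        if m:
            current = sections.setdefault(m.group("name"), {})
            continue
        if current is not None and "=" in line:
            key, value = line.split("=", 1)
            current[key.strip()] = value.strip()
    return sections


def _normalize_marker_label(description: str) -> str:
    """"S  1" (blank-padded recorder dialect) and "S1" both map to S1."""
    return description.replace(" ", "")


def _read_markers(vmrk: Path) -> list[Marker]:
    sections = _parse_ini(vmrk.read_text(encoding="utf-8"))
    info = sections.get("Marker Infos", {})
    markers: list[Marker] = []
    for key in sorted(info, key=lambda k: int(k[2:]) if k[2:].isdigit() else 0):
        if not key.startswith("Mk"):
            continue
        fields = info[key].split(",")
        if len(fields) < 3:
            raise BrainVisionFormatError(f"malformed marker line {key}={info[key]!r}")
        mtype, description, position = fields[0], fields[1], fields[2]
        if mtype != "Stimulus":
            continue  # New Segment etc. carry no protocol information
        markers.append(
            Marker(_normalize_marker_label(description), int(position) - 1)
        )
    markers.sort(key=lambda m: m.position)
    return markers


def read_recording(basepath: str | Path) -> EEGRecording:
    """Read a BrainVision triplet into an :class:`EEGRecording`.

    Supports IEEE_FLOAT_32 and INT_16 binary formats (the latter scaled by
    each channel's resolution field) and both data orientations.
    """
    basepath = Path(basepath)
    vhdr = basepath.with_suffix(".vhdr")
    if not vhdr.exists():
        raise BrainVisionFormatError(f"header file not found: {vhdr}")
    sections = _parse_ini(vhdr.read_text(encoding="utf-8"))
    common = sections.get("Common Infos", {})
    binary = sections.get("Binary Infos", {})
    channels = sections.get("Channel Infos", {})

    try:
        n_channels = int(common["NumberOfChannels"])
        sampling_interval_us = float(common["SamplingInterval"])
    except KeyError as exc:
        raise BrainVisionFormatError(f"header missing required field: {exc}") from exc
    fs_hz = 1e6 / sampling_interval_us
    orientation = common.get("DataOrientation", "MULTIPLEXED").upper()
    if orientation not in ("MULTIPLEXED", "VECTORIZED"):
        raise BrainVisionFormatError(f"unknown orientation {orientation!r}")
    binary_format = binary.get("BinaryFormat", "IEEE_FLOAT_32").upper()

    labels: list[str] = []
    resolutions: list[float] = []
    for i in range(n_channels):
        entry = channels.get(f"Ch{i + 1}", f"Ch{i + 1},,1,µV")
        fields = entry.split(",")
        labels.append(fields[0] or f"Ch{i + 1}")
        res_str = fields[2].strip() if len(fields) > 2 else ""
        resolutions.append(float(res_str) if res_str else 1.0)

    eeg = basepath.parent / common.get("DataFile", basepath.with_suffix(".eeg").name)
    if not eeg.exists():
        raise BrainVisionFormatError(f"data file not found: {eeg}")
    if binary_format == "IEEE_FLOAT_32":
        raw = np.fromfile(eeg, dtype=np.float32)
    elif binary_format == "INT_16":
        raw = np.fromfile(eeg, dtype=np.int16)
    else:
        raise BrainVisionFormatError(f"unsupported binary format {binary_format!r}")
    if raw.size % n_channels:
        raise BrainVisionFormatError(
            f"data size {raw.size} not divisible by channel count {n_channels}"
        )
    n_samples = raw.size // n_channels
    if orientation == "MULTIPLEXED":
        data = raw.reshape(n_samples, n_channels).T.astype(float)
    else:
        data = raw.reshape(n_channels, n_samples).astype(float)
    data = data * np.asarray(resolutions)[:, None]

    vmrk = basepath.parent / common.get("MarkerFile", basepath.with_suffix(".vmrk").name)
    markers = _read_markers(vmrk) if vmrk.exists() else []

    return EEGRecording(data=data, fs_hz=fs_hz, channel_labels=labels, markers=markers)


def export_markers(rec: EEGRecording, path: str | Path) -> None:
    """CSV export of the marker stream (label, 0-based sample, seconds)."""
    pd.DataFrame(
        [
            {"label": m.label, "position": m.position, "time_s": m.position / rec.fs_hz}
            for m in rec.markers
        ]
    ).to_csv(path, index=False)
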