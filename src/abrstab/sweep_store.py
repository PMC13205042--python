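"""Containers and on-disk formats for ABR sweep data and averaged waveforms.

This module owns the package's unit and timebase conventions: amplitudes are
microvolts (μV), time is milliseconds relative to stimulus onset (negative =
prestimulus), and the ms ↔ sample-index conversion is floor-based and lives
here.  A sweep buffer is stored as a plain delimited matrix (one row per
sweep) next to a JSON sidecar carrying all metadata; no vendor binary formats
are read or written.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

FORMAT_VERSION = "abrstab-1"
UNIT = "uV"

CHANNELS = ("A", "B")
POLARITIES = ("condensation", "rarefaction")
STIMULI = ("click", "da40")

#: epoch extents in ms relative to stimulus onset, (t0, t_end)
EPOCHS_MS = {"click": (-5.0, 20.0), "da40": (-5.0, 55.0)}

_SIDE_CAR_FIELDS = (
    "format_version",
    "unit",
    "n_sweeps",
    "n_samples",
    "sampling_rate_hz",
    "t0_ms",
    "window_ms",
    "channel",
    "polarity",
    "stimulus_kind",
    "participant_id",
    "collection_index",
)


class SweepStoreError(ValueError):
    """Raised on malformed files or inconsistent buffer metadata."""


def time_to_index(t_ms: float, t0_ms: float, sampling_rate_hz: float) -> int:
    """Floor-based conversion of a time in ms to a sample index.

    Sample ``i`` covers the half-open interval ``[t0 + i·dt, t0 + (i+1)·dt)``;
    the small epsilon absorbs float error so exact grid times map to their
    own sample.
    """
    return int(math.floor((t_ms - t0_ms) * sampling_rate_hz / 1000.0 + 1e-9))


def expected_samples(window_ms: float, sampling_rate_hz: float) -> int:
    """Number of samples spanning ``window_ms`` at the given rate."""
    return int(round(window_ms * sampling_rate_hz / 1000.0))


@dataclass
class SweepBuffer:
    """Stimulus-locked single-trial epochs for one (channel, polarity) buffer.

    ``data`` is an (n_sweeps, n_samples) float array in μV.  ``t0_ms`` is the
    time of the first sample relative to stimulus onset.
    """

    data: np.ndarray
    sampling_rate_hz: float
    t0_ms: float
    channel: str
    polarity: str
    stimulus_kind: str
    participant_id: str
    collection_index: int = 1
    processing: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise SweepStoreError("sweep data must be a 2-D (n_sweeps, n_samples) matrix")
        if not np.all(np.isfinite(self.data)):
            raise SweepStoreError("sweep data contains non-finite values")
        if self.channel not in CHANNELS:
            raise SweepStoreError(f"channel must be one of {CHANNELS}, got {self.channel!r}")
        if self.polarity not in POLARITIES:
            raise SweepStoreError(f"polarity must be one of {POLARITIES}, got {self.polarity!r}")
        if self.stimulus_kind not in STIMULI:
            raise SweepStoreError(f"stimulus_kind must be one of {STIMULI}, got {self.stimulus_kind!r}")
        if self.collection_index not in (1, 2):
            raise SweepStoreError("collection_index must be 1 or 2")

    @property
    def n_sweeps(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def window_ms(self) -> float:
        return self.n_samples * 1000.0 / self.sampling_rate_hz

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_ms + np.arange(self.n_samples) * 1000.0 / self.sampling_rate_hz

    def with_data(self, data: np.ndarray, note: str | None = None) -> "SweepBuffer":
        out = replace(self, data=np.asarray(data, dtype=float))
        out.processing = list(self.processing) + ([note] if note else [])
        return out

    def key(self) -> tuple:
        return (self.participant_id, self.stimulus_kind, self.channel, self.polarity)


@dataclass
class AveragedResponse:
    """One averaged waveform with exact composition bookkeeping.

    ``composition`` maps ``(channel, polarity)`` to the number of sweeps that
    channel/polarity contributed; ``provenance`` lists the source buffer
    identifiers in contribution order.
    """

    amplitude: np.ndarray
    sampling_rate_hz: float
    t0_ms: float
    stimulus_kind: str
    participant_id: str
    composition: dict = field(default_factory=dict)
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=float).ravel()
        if not np.all(np.isfinite(self.amplitude)):
            raise SweepStoreError("averaged amplitude contains non-finite values")
        if any(v < 0 for v in self.composition.values()):
            raise SweepStoreError("composition counts must be nonnegative")

    @property
    def n_samples(self) -> int:
        return self.amplitude.size

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_ms + np.arange(self.n_samples) * 1000.0 / self.sampling_rate_hz

    @property
    def n_sweeps_total(self) -> int:
        return int(sum(self.composition.values()))


# ---------------------------------------------------------------------------
# sweep buffer I/O: <id>_<stim>_<channel>_<polarity>.csv + .json sidecar
# ---------------------------------------------------------------------------

def buffer_basename(buffer: SweepBuffer) -> str:
    return f"{buffer.participant_id}_{buffer.stimulus_kind}_{buffer.channel}_{buffer.polarity}"


def write_sweeps(buffer: SweepBuffer, path: str | Path) -> Path:
    """Write a sweep buffer as a delimited matrix plus JSON metadata sidecar.

    ``path`` is the matrix file (.csv); the sidecar takes the same stem with
    a .json suffix.  Round-trips losslessly to ~1e-12 μV (17 sig. digits).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, buffer.data, delimiter=",", fmt="%.17g")
    meta = {
        "format_version": FORMAT_VERSION,
        "unit": UNIT,
        "n_sweeps": buffer.n_sweeps,
        "n_samples": buffer.n_samples,
        "sampling_rate_hz": buffer.sampling_rate_hz,
        "t0_ms": buffer.t0_ms,
        "window_ms": buffer.window_ms,
        "channel": buffer.channel,
        "polarity": buffer.polarity,
        "stimulus_kind": buffer.stimulus_kind,
        "participant_id": buffer.participant_id,
        "collection_index": buffer.collection_index,
        "processing": buffer.processing,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return path


def read_sweeps(path: str | Path) -> SweepBuffer:
    """Read a sweep buffer, validating the sidecar schema.

    Raises :class:`SweepStoreError` naming the offending field when metadata
    is missing, the unit is not μV, or the declared (window_ms, rate,
    n_samples) triple is internally inconsistent.
    """
    path = Path(path)
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise SweepStoreError(f"missing metadata sidecar: {sidecar}")
    meta = json.loads(sidecar.read_text())
    for fname in _SIDE_CAR_FIELDS:
        if fname not in meta:
            raise SweepStoreError(f"metadata sidecar missing required field {fname!r}")
    if meta["format_version"] != FORMAT_VERSION:
        raise SweepStoreError(f"unsupported format_version {meta['format_version']!r}")
    if meta["unit"] != UNIT:
        raise SweepStoreError(f"unit must be {UNIT!r}, got {meta['unit']!r}")
    data = np.loadtxt(path, delimiter=",", ndmin=2)
    n_expected = expected_samples(meta["window_ms"], meta["sampling_rate_hz"])
    if n_expected != meta["n_samples"]:
        raise SweepStoreError(
            f"sample-count mismatch: declared window {meta['window_ms']} ms at "
            f"{meta['sampling_rate_hz']} Hz implies {n_expected} samples, "
            f"sidecar declares n_samples={meta['n_samples']}"
        )
    if data.shape != (meta["n_sweeps"], meta["n_samples"]):
        raise SweepStoreError(
            f"matrix shape {data.shape} disagrees with declared "
            f"({meta['n_sweeps']}, {meta['n_samples']})"
        )
    buf = SweepBuffer(
        data=data,
        sampling_rate_hz=meta["sampling_rate_hz"],
        t0_ms=meta["t0_ms"],
        channel=meta["channel"],
        polarity=meta["polarity"],
        stimulus_kind=meta["stimulus_kind"],
        participant_id=str(meta["participant_id"]),
        collection_index=meta["collection_index"],
    )
    buf.processing = list(meta.get("processing", []))
    return buf


def write_buffer_set(buffers: Sequence[SweepBuffer], directory: str | Path) -> list[Path]:
    """Write each buffer under its canonical filename in ``directory``."""
    directory = Path(directory)
    paths = []
    for buf in buffers:
        paths.append(write_sweeps(buf, directory / f"{buffer_basename(buf)}.csv"))
    return paths


def read_buffer_set(directory: str | Path) -> list[SweepBuffer]:
    """Read every canonical sweep-buffer file in ``directory`` (sorted)."""
    directory = Path(directory)
    return [read_sweeps(p) for p in sorted(directory.glob("*.csv")) if p.with_suffix(".json").exists()]


# ---------------------------------------------------------------------------
# averaged-waveform export
# ---------------------------------------------------------------------------

def export_waveform(avg: AveragedResponse, path: str | Path) -> Path:
    """Write a two-column text file (time_ms, amplitude_uV), 6 sig. digits."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("time_ms,amplitude_uV\n")
        for t, a in zip(avg.times_ms, avg.amplitude):
            fh.write(f"{t:.6g},{a:.6g}\n")
    return path


def read_waveform(path: str | Path) -> np.ndarray:
    """Read an exported waveform back as an (n, 2) array."""
    return np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)


def write_table(df, path: str | Path) -> Path:
    """Write a result table as comma-delimited text with header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path
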