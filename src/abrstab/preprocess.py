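"""Offline recording-time processing: bandpass filtering, artifact rejection,
and low-noise sweep accumulation.

Defaults mirror standard evoked-potential acquisition: a 100–3000 Hz
zero-phase band (4th-order Butterworth applied forward–backward so peak
latencies are preserved), a ±35 μV rejection criterion applied per sweep
("exceeding" is strict: a sweep peaking at exactly 35.0 μV is kept), and
accumulation of the first 1500 accepted sweeps per buffer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy import signal

from .sweep_store import SweepBuffer

FILTER_LOW_HZ = 100.0
FILTER_HIGH_HZ = 3000.0
REJECT_THRESHOLD_UV = 35.0
ACCUMULATE_TARGET = 1500


class PreprocessError(ValueError):
    pass


@dataclass
class RejectionReport:
    n_in: int
    n_rejected: int
    n_kept: int
    threshold_uv: float
    rejected_indices: list

    def __post_init__(self) -> None:
        assert self.n_in == self.n_kept + self.n_rejected


def _design_bandpass(low_hz: float, high_hz: float, sampling_rate_hz: float) -> np.ndarray:
    nyq = sampling_rate_hz / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise PreprocessError(
            f"band ({low_hz}, {high_hz}) Hz must satisfy 0 < low < high < Nyquist ({nyq} Hz)"
        )
    return signal.butter(4, [low_hz / nyq, high_hz / nyq], btype="band", output="sos")


def bandpass(buffer: SweepBuffer, low_hz: float = FILTER_LOW_HZ,
             high_hz: float = FILTER_HIGH_HZ) -> SweepBuffer:
    """Zero-phase bandpass of every sweep; DC is rejected by the high-pass edge."""
    sos = _design_bandpass(low_hz, high_hz, buffer.sampling_rate_hz)
    filtered = signal.sosfiltfilt(sos, buffer.data, axis=1)
    return buffer.with_data(filtered, note=f"bandpass {low_hz}-{high_hz} Hz butter4 zero-phase")


def reject_artifacts(buffer: SweepBuffer,
                     threshold_uv: float = REJECT_THRESHOLD_UV) -> tuple[SweepBuffer, RejectionReport]:
    """Drop sweeps whose absolute amplitude exceeds ``threshold_uv`` anywhere.

    Rejection is per-sweep on the per-sample absolute maximum, so the kept
    set is independent of sweep order.  Raises when every sweep is rejected.
    """
    if threshold_uv <= 0:
        raise PreprocessError("threshold_uv must be positive")
    peak = np.max(np.abs(buffer.data), axis=1)
    keep = peak <= threshold_uv
    rejected = np.flatnonzero(~keep)
    if not keep.any():
        raise PreprocessError(
            f"all {buffer.n_sweeps} sweeps exceed ±{threshold_uv} μV; nothing to average"
        )
    report = RejectionReport(
        n_in=buffer.n_sweeps,
        n_rejected=int(rejected.size),
        n_kept=int(keep.sum()),
        threshold_uv=threshold_uv,
        rejected_indices=rejected.tolist(),
    )
    kept = buffer.with_data(buffer.data[keep], note=f"rejected {rejected.size} sweeps > ±{threshold_uv} μV")
    return kept, report


def accumulate_lownoise(sweeps: Iterable[np.ndarray], target: int = ACCUMULATE_TARGET,
                        threshold_uv: float = REJECT_THRESHOLD_UV) -> np.ndarray:
    """Collect the first ``target`` below-threshold sweeps from a stream.

    Mirrors online averaging: sweeps arrive one at a time, super-threshold
    trials are discarded, and acquisition stops once ``target`` accepted
    sweeps are in hand.  Raises with the shortfall if the stream runs dry.
    """
    if target < 1:
        raise PreprocessError("target must be at least 1")
    kept: list[np.ndarray] = []
    for sweep in sweeps:
        sweep = np.asarray(sweep, dtype=float)
        if np.max(np.abs(sweep)) <= threshold_uv:
            kept.append(sweep)
            if len(kept) == target:
                return np.vstack(kept)
    raise PreprocessError(
        f"sweep stream exhausted: {len(kept)} accepted of {target} required "
        f"(shortfall {target - len(kept)})"
    )


def preprocess_buffer(buffer: SweepBuffer,
                      low_hz: float = FILTER_LOW_HZ,
                      high_hz: float = FILTER_HIGH_HZ,
                      threshold_uv: float = REJECT_THRESHOLD_UV,
                      target: int | None = ACCUMULATE_TARGET,
                      reject_on: str = "filtered") -> tuple[SweepBuffer, RejectionReport]:
    """Filter, reject, and truncate one buffer to the accumulation target.

    ``reject_on`` selects whether the ±threshold criterion is tested on the
    filtered ("filtered", default — the online system filters before
    averaging) or raw sweeps.
    """
    if reject_on not in ("filtered", "raw"):
        raise PreprocessError("reject_on must be 'filtered' or 'raw'")
    if reject_on == "raw":
        kept_raw, report = reject_artifacts(buffer, threshold_uv)
        out = bandpass(kept_raw, low_hz, high_hz)
    else:
        out, report = reject_artifacts(bandpass(buffer, low_hz, high_hz), threshold_uv)
    if target is not None:
        if out.n_sweeps < target:
            raise PreprocessError(
                f"buffer {out.key()} has {out.n_sweeps} clean sweeps, "
                f"short of the accumulation target {target}"
            )
        out = out.with_data(out.data[:target], note=f"truncated to first {target} accepted sweeps")
    return out, report
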