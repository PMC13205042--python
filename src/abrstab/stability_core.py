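"""Balanced subaveraging and component-windowed waveform-correlation stability.

The stability statistic: split a recording's sweeps into two disjoint
subaverages that are balanced across stimulus polarity, recording channel,
and collection order, then correlate the two averaged waveforms (Pearson r)
over component-specific time windows and Fisher-transform the result
(Zr = atanh r).  Because each balanced subaverage contains equal numbers of
condensation and rarefaction sweeps, any component that flips sign with
stimulus polarity (cochlear microphonic, stimulus artifact) cancels, so the
correlation reflects neural repeatability rather than artifact overlap.

Windows are half-open [start, end) with floor-based ms→index conversion, so
adjacent windows never share samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .sweep_store import AveragedResponse, SweepBuffer, time_to_index

#: canonical analysis windows, ms post stimulus onset (half-open)
DEFAULT_WINDOWS = {
    "click": (1.0, 8.0),
    "full_sabr": (0.0, 55.0),
    "onset": (5.0, 10.0),
    "ffr": (22.0, 40.0),
    "offset": (45.0, 50.0),
}

SABR_COMPONENTS = ("full_sabr", "onset", "ffr", "offset")

R_CLAMP = 1.0 - 1e-7


class StabilityError(ValueError):
    pass


@dataclass(frozen=True)
class ComponentWindow:
    name: str
    start_ms: float
    end_ms: float

    def __post_init__(self) -> None:
        if not self.start_ms < self.end_ms:
            raise StabilityError(f"window {self.name}: start must precede end")


def component_windows(overrides: Mapping[str, tuple] | None = None) -> dict[str, ComponentWindow]:
    table = dict(DEFAULT_WINDOWS)
    if overrides:
        table.update({k: tuple(v) for k, v in overrides.items()})
    return {name: ComponentWindow(name, a, b) for name, (a, b) in table.items()}


def _check_compatible(buffers: Sequence[SweepBuffer]) -> None:
    ref = buffers[0]
    for b in buffers[1:]:
        if b.participant_id != ref.participant_id or b.stimulus_kind != ref.stimulus_kind:
            raise StabilityError("buffers must share participant and stimulus")
        if (b.sampling_rate_hz != ref.sampling_rate_hz or b.t0_ms != ref.t0_ms
                or b.n_samples != ref.n_samples):
            raise StabilityError("buffers must share an identical timebase")


def _mean_response(stacks: Sequence[SweepBuffer], composition: dict) -> AveragedResponse:
    data = np.vstack([b.data for b in stacks])
    ref = stacks[0]
    return AveragedResponse(
        amplitude=data.mean(axis=0),
        sampling_rate_hz=ref.sampling_rate_hz,
        t0_ms=ref.t0_ms,
        stimulus_kind=ref.stimulus_kind,
        participant_id=ref.participant_id,
        composition=composition,
        provenance=["{}:{}:{}".format(b.channel, b.polarity, b.collection_index) for b in stacks],
    )


def build_subaverages(
    buf_a_cond: SweepBuffer,
    buf_a_rare: SweepBuffer,
    buf_b_cond: SweepBuffer,
    buf_b_rare: SweepBuffer,
    on_unequal: str = "error",
) -> tuple[AveragedResponse, AveragedResponse]:
    """Cross-channel, cross-polarity balanced subaverages for alternating-polarity recordings.

    Subaverage 1 averages channel-A condensation with channel-B rarefaction
    sweeps; subaverage 2 averages channel-B condensation with channel-A
    rarefaction.  The two draw on disjoint sweep sets and each contains
    equal numbers of sweeps per polarity and per channel, so polarity-locked
    and channel-specific components cancel identically in both.

    ``on_unequal``: 'error' (default) rejects unequal buffer sizes;
    'truncate' trims every buffer to the smallest count.
    """
    bufs = [buf_a_cond, buf_a_rare, buf_b_cond, buf_b_rare]
    _check_compatible(bufs)
    expected = {("A", "condensation"), ("A", "rarefaction"), ("B", "condensation"), ("B", "rarefaction")}
    got = {(b.channel, b.polarity) for b in bufs}
    if got != expected:
        raise StabilityError(f"need the four (channel, polarity) buffers, got {sorted(got)}")
    counts = {b.n_sweeps for b in bufs}
    if len(counts) > 1:
        if on_unequal == "truncate":
            m = min(counts)
            bufs = [b.with_data(b.data[:m]) for b in bufs]
            buf_a_cond, buf_a_rare, buf_b_cond, buf_b_rare = bufs
        else:
            raise StabilityError(f"unequal buffer sizes {sorted(counts)}; pass on_unequal='truncate' to trim")
    sub1 = _mean_response(
        [buf_a_cond, buf_b_rare],
        {("A", "condensation"): buf_a_cond.n_sweeps, ("B", "rarefaction"): buf_b_rare.n_sweeps},
    )
    sub2 = _mean_response(
        [buf_b_cond, buf_a_rare],
        {("B", "condensation"): buf_b_cond.n_sweeps, ("A", "rarefaction"): buf_a_rare.n_sweeps},
    )
    return sub1, sub2


def build_click_subaverages(
    buf_a: SweepBuffer, buf_b: SweepBuffer, on_unequal: str = "error",
) -> tuple[AveragedResponse, AveragedResponse]:
    """Cross-channel subaverages for single-polarity (click) recordings.

    With only one polarity, the collection-order halves of each channel's
    buffer substitute for the polarity split: subaverage 1 = first half of
    channel A + second half of channel B; subaverage 2 = first half of B +
    second half of A.  This preserves disjointness and balances channel and
    collection order exactly as in the alternating-polarity case.
    """
    _check_compatible([buf_a, buf_b])
    if {buf_a.channel, buf_b.channel} != {"A", "B"}:
        raise StabilityError("need one channel-A and one channel-B buffer")
    if buf_a.channel == "B":
        buf_a, buf_b = buf_b, buf_a
    if buf_a.n_sweeps != buf_b.n_sweeps:
        if on_unequal == "truncate":
            m = min(buf_a.n_sweeps, buf_b.n_sweeps)
            buf_a, buf_b = buf_a.with_data(buf_a.data[:m]), buf_b.with_data(buf_b.data[:m])
        else:
            raise StabilityError("unequal click buffer sizes; pass on_unequal='truncate' to trim")
    h = buf_a.n_sweeps // 2
    a1, a2 = buf_a.with_data(buf_a.data[:h]), buf_a.with_data(buf_a.data[h:2 * h])
    b1, b2 = buf_b.with_data(buf_b.data[:h]), buf_b.with_data(buf_b.data[h:2 * h])
    pol = buf_a.polarity
    sub1 = _mean_response([a1, b2], {("A", pol): h, ("B", pol): h})
    sub2 = _mean_response([b1, a2], {("B", pol): h, ("A", pol): h})
    return sub1, sub2


def window_slice(avg: AveragedResponse, window: ComponentWindow) -> np.ndarray:
    """Samples of ``avg`` with ``start_ms ≤ t < end_ms`` (floor indexing)."""
    i0 = time_to_index(window.start_ms, avg.t0_ms, avg.sampling_rate_hz)
    i1 = time_to_index(window.end_ms, avg.t0_ms, avg.sampling_rate_hz)
    if i0 < 0 or i1 > avg.n_samples or i1 <= i0:
        raise StabilityError(
            f"window {window.name} [{window.start_ms}, {window.end_ms}) ms lies outside "
            f"the epoch [{avg.t0_ms}, {avg.t0_ms + avg.n_samples * 1000.0 / avg.sampling_rate_hz}) ms"
        )
    return avg.amplitude[i0:i1]


def stability_r(avg1: AveragedResponse, avg2: AveragedResponse, window: ComponentWindow) -> float:
    """Pearson correlation of the two subaverages over one component window."""
    if (avg1.sampling_rate_hz != avg2.sampling_rate_hz or avg1.t0_ms != avg2.t0_ms
            or avg1.n_samples != avg2.n_samples):
        raise StabilityError("subaverages must share a timebase")
    x = window_slice(avg1, window)
    y = window_slice(avg2, window)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise StabilityError(f"constant waveform in window {window.name}: correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


def fisher_z(r: float) -> float:
    """Variance-stabilizing transform Zr = atanh(r), clamping |r| to 1 − 1e-7.

    The clamp (rather than an error) lets noiseless simulations that reach
    r = 1 exactly map to a large finite Zr.
    """
    if abs(r) > 1.0:
        raise StabilityError(f"|r| = {abs(r)} exceeds 1")
    return float(np.arctanh(np.clip(r, -R_CLAMP, R_CLAMP)))


def stability_records(
    sub1: AveragedResponse,
    sub2: AveragedResponse,
    windows: Mapping[str, ComponentWindow],
    components: Sequence[str],
) -> list[dict]:
    rows = []
    for comp in components:
        w = windows[comp]
        r = stability_r(sub1, sub2, w)
        rows.append({
            "participant_id": sub1.participant_id,
            "stimulus": sub1.stimulus_kind,
            "component": comp,
            "r": r,
            "Zr": fisher_z(r),
            "n_samples_in_window": int(window_slice(sub1, w).size),
            "n_sweeps_sub1": sub1.n_sweeps_total,
            "n_sweeps_sub2": sub2.n_sweeps_total,
        })
    return rows


def participant_stability(
    buffers: Sequence[SweepBuffer],
    windows: Mapping[str, ComponentWindow] | None = None,
    on_unequal: str = "error",
) -> pd.DataFrame:
    """Stability records for one participant from their preprocessed buffers.

    Groups the buffers by stimulus: a /da/ set needs the four
    (channel × polarity) buffers and yields the four speech components; a
    click set needs the two single-polarity channel buffers and yields the
    click component.  A participant may contribute either or both stimuli
    (usable click recordings without a usable speech recording still yield
    a click record).
    """
    windows = windows or component_windows()
    rows: list[dict] = []
    da = [b for b in buffers if b.stimulus_kind == "da40"]
    click = [b for b in buffers if b.stimulus_kind == "click"]
    if da:
        by_key = {(b.channel, b.polarity): b for b in da}
        if len(by_key) != 4:
            raise StabilityError(f"da40 requires 4 (channel, polarity) buffers, got {len(by_key)}")
        sub1, sub2 = build_subaverages(
            by_key[("A", "condensation")], by_key[("A", "rarefaction")],
            by_key[("B", "condensation")], by_key[("B", "rarefaction")],
            on_unequal=on_unequal,
        )
        rows += stability_records(sub1, sub2, windows, SABR_COMPONENTS)
    if click:
        if len(click) != 2:
            raise StabilityError(f"click requires the two channel buffers, got {len(click)}")
        sub1, sub2 = build_click_subaverages(click[0], click[1], on_unequal=on_unequal)
        rows += stability_records(sub1, sub2, windows, ("click",))
    if not rows:
        raise StabilityError("no usable buffers supplied")
    return pd.DataFrame(rows)


def stability_table(
    participant_buffers: Mapping[str, Sequence[SweepBuffer]],
    windows: Mapping[str, ComponentWindow] | None = None,
    on_unequal: str = "error",
) -> pd.DataFrame:
    """Concatenate per-participant stability records into one long table."""
    frames = [participant_stability(bufs, windows, on_unequal) for bufs in participant_buffers.values()]
    return pd.concat(frames, ignore_index=True)
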