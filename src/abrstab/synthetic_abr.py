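"""Synthetic ABR sweep and cohort generator.

Every downstream stage of the pipeline (filtering, rejection, balanced
subaveraging, windowed correlation, mixed-model inference) is verified
against data produced here, where the ground truth is known by construction:

* a deterministic response template with the canonical waveform anatomy —
  click waves I/III/V; /da/-evoked waves V, A, C, D, E, F, O with a
  sustained frequency-following portion phase-locked to the fundamental
  frequency f0 (inter-peak spacing of D–E–F equals 1/f0);
* trial-level degradation mechanisms (latency jitter, multiplicative
  amplitude variability, additive band-limited noise) that control the
  expected waveform-correlation stability in closed form;
* a polarity-sign-flipping sinusoid mimicking cochlear-microphonic /
  stimulus artifact, which balanced condensation/rarefaction subaveraging
  must cancel;
* cohort-level Fisher-z stability values generated directly from the
  random-intercept linear model used for inference, with configurable
  component offsets and a linear autistic-trait effect.

Peak latencies and amplitudes are canonical literature values exposed as
module constants; they are conventions of the generator, not fitted
quantities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .sweep_store import EPOCHS_MS, POLARITIES, SweepBuffer

DEFAULT_SAMPLING_RATE_HZ = 20_000.0
DEFAULT_F0_HZ = 100.0

#: canonical click-ABR peak registry: (label, latency ms, amplitude μV, width ms)
CLICK_PEAKS = (
    ("I", 1.7, 0.20, 0.45),
    ("III", 3.9, 0.30, 0.50),
    ("V", 5.7, 0.50, 0.60),
)

#: canonical /da/-evoked transient peaks (sustained D/E/F are built from f0)
DA40_TRANSIENT_PEAKS = (
    ("V", 6.6, 0.40, 0.70),
    ("A", 7.5, -0.45, 0.80),
    ("C", 18.5, -0.15, 1.00),
    ("O", 48.0, -0.35, 1.00),
)

#: sustained-portion parameters: first trough latency, envelope extent (ms)
DA40_SUSTAIN_FIRST_TROUGH_MS = 22.5
DA40_SUSTAIN_SPAN_MS = (18.0, 44.0)
DA40_SUSTAIN_AMP_UV = 0.30
DA40_SUSTAIN_H2_RELATIVE = 0.30  # second harmonic relative amplitude

COMPONENTS = ("click", "full_sabr", "onset", "ffr", "offset")


@dataclass
class ResponseTemplate:
    """Deterministic evoked-response waveform with a labelled peak registry."""

    stimulus_kind: str
    times_ms: np.ndarray
    amplitude: np.ndarray
    peak_registry: list
    sampling_rate_hz: float
    f0_hz: float | None = None

    def __post_init__(self) -> None:
        dt = np.diff(self.times_ms)
        if not (np.all(dt > 0) and np.allclose(dt, dt[0], rtol=1e-9)):
            raise ValueError("template timebase must be strictly increasing and uniform")
        t0, t1 = self.times_ms[0], self.times_ms[-1]
        for label, lat, *_ in self.peak_registry:
            if not (t0 <= lat <= t1):
                raise ValueError(f"peak {label} latency {lat} ms outside timebase")
        if self.stimulus_kind == "da40" and not (self.f0_hz and self.f0_hz > 0):
            raise ValueError("da40 template requires f0 > 0")

    @property
    def t0_ms(self) -> float:
        return float(self.times_ms[0])


def _gaussian_peak(t: np.ndarray, latency: float, amp: float, width: float) -> np.ndarray:
    # width is interpreted as the Gaussian FWHM
    sigma = width / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    return amp * np.exp(-0.5 * ((t - latency) / sigma) ** 2)


def make_template(
    stimulus_kind: str,
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ,
    f0_hz: float | None = None,
) -> ResponseTemplate:
    """Build the deterministic click or /da/ response template.

    The click template spans −5…20 ms with Gaussian waves I/III/V.  The
    /da/ template spans −5…55 ms: a V/A onset complex, a small C trough, a
    sustained portion at ``f0_hz`` (plus one harmonic) whose troughs D–E–F
    are spaced exactly 1/f0 apart, and an offset trough O near 48 ms.
    """
    if sampling_rate_hz < 8000:
        raise ValueError("sampling_rate_hz must be at least 8000 Hz")
    if stimulus_kind not in EPOCHS_MS:
        raise ValueError(f"unknown stimulus_kind {stimulus_kind!r}")
    if stimulus_kind == "click" and f0_hz is not None:
        raise ValueError("f0_hz is only meaningful for the da40 stimulus")

    t0, t1 = EPOCHS_MS[stimulus_kind]
    n = int(round((t1 - t0) * sampling_rate_hz / 1000.0))
    t = t0 + np.arange(n) * 1000.0 / sampling_rate_hz
    amp = np.zeros(n)

    if stimulus_kind == "click":
        registry = [list(p) for p in CLICK_PEAKS]
        for label, lat, a, w in registry:
            amp += _gaussian_peak(t, lat, a, w)
        return ResponseTemplate("click", t, amp, registry, sampling_rate_hz, None)

    f0 = DEFAULT_F0_HZ if f0_hz is None else float(f0_hz)
    if f0 <= 0:
        raise ValueError("f0_hz must be positive")
    registry = [list(p) for p in DA40_TRANSIENT_PEAKS]
    for label, lat, a, w in registry:
        amp += _gaussian_peak(t, lat, a, w)

    # sustained portion: −cos so troughs fall at first_trough + k/f0
    lo, hi = DA40_SUSTAIN_SPAN_MS
    env = np.clip((t - lo) / 2.0, 0, 1) * np.clip((hi - t) / 2.0, 0, 1)  # 2 ms raised ramps
    phase = 2 * np.pi * f0 * (t - DA40_SUSTAIN_FIRST_TROUGH_MS) / 1000.0
    sustained = -DA40_SUSTAIN_AMP_UV * (np.cos(phase) + DA40_SUSTAIN_H2_RELATIVE * np.cos(2 * phase))
    amp += env * sustained

    period_ms = 1000.0 / f0
    for i, label in enumerate(("D", "E", "F")):
        lat = DA40_SUSTAIN_FIRST_TROUGH_MS + i * period_ms
        registry.append([label, lat, -DA40_SUSTAIN_AMP_UV * (1 + DA40_SUSTAIN_H2_RELATIVE), period_ms / 2.0])
    registry.sort(key=lambda p: p[1])
    return ResponseTemplate("da40", t, amp, registry, sampling_rate_hz, f0)


# ---------------------------------------------------------------------------
# trial-level noise model and sweep simulation
# ---------------------------------------------------------------------------

@dataclass
class NoiseModel:
    """Trial-level degradation parameters (all amplitudes in μV, times ms).

    ``noise_band`` limits the additive Gaussian noise to a frequency band
    (Hz); the noise is rescaled so its stationary standard deviation equals
    ``noise_sd`` after band-limiting.  ``None`` yields white noise.
    """

    noise_sd: float = 2.5
    jitter_sd: float = 0.05
    amp_cv: float = 0.05
    artifact_rate: float = 0.0
    polarity_component_amp: float = 0.0
    polarity_component_hz: float = 100.0
    noise_band: tuple | None = (100.0, 3000.0)

    def __post_init__(self) -> None:
        for name in ("noise_sd", "jitter_sd", "amp_cv", "polarity_component_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise ValueError("artifact_rate must lie in [0, 1]")


def _bandlimit_gain(sos: np.ndarray) -> float:
    """RMS gain of forward-backward filtering applied to unit white noise."""
    _, h = signal.sosfreqz(sos, worN=8192)
    return float(np.sqrt(np.mean(np.abs(h) ** 4)))


def simulate_sweeps(
    template: ResponseTemplate,
    noise_model: NoiseModel,
    n_sweeps: int,
    channel: str,
    polarity: str,
    seed: int = 0,
    participant_id: str = "sim",
    collection_index: int = 1,
) -> SweepBuffer:
    """Simulate one (channel, polarity) buffer of stimulus-locked sweeps.

    Each sweep is ``a_i · template(t − j_i) + s_pol · cm(t) + noise_i`` with
    amplitude factor ``a_i ~ N(1, amp_cv²)``, latency jitter
    ``j_i ~ N(0, jitter_sd²)`` applied by linear-interpolation resampling,
    a polarity-signed sinusoid active over the stimulus duration, and
    additive (optionally band-limited) Gaussian noise.  A fraction
    ``artifact_rate`` of sweeps additionally receives a large-amplitude
    excursion guaranteed to exceed the ±35 μV rejection threshold.
    """
    if n_sweeps < 1:
        raise ValueError("n_sweeps must be at least 1")
    if polarity not in POLARITIES:
        raise ValueError(f"invalid polarity {polarity!r}")
    nm = noise_model
    t = template.times_ms
    window_ms = t[-1] - t[0]
    if nm.jitter_sd > window_ms / 10.0:
        raise ValueError("jitter_sd is too large relative to the epoch length")

    rng = np.random.default_rng(seed)
    n = t.size
    sweeps = np.empty((n_sweeps, n))

    amps = 1.0 + nm.amp_cv * rng.standard_normal(n_sweeps) if nm.amp_cv > 0 else np.ones(n_sweeps)
    jitters = nm.jitter_sd * rng.standard_normal(n_sweeps) if nm.jitter_sd > 0 else np.zeros(n_sweeps)
    if nm.jitter_sd > 0 or nm.amp_cv > 0:
        for i in range(n_sweeps):
            sweeps[i] = amps[i] * np.interp(t - jitters[i], t, template.amplitude, left=0.0, right=0.0)
    else:
        sweeps[:] = template.amplitude

    if nm.polarity_component_amp > 0:
        sign = 1.0 if polarity == "condensation" else -1.0
        dur = 40.0 if template.stimulus_kind == "da40" else 1.0
        gate = (t >= 0.0) & (t <= dur)
        cm = nm.polarity_component_amp * np.sin(2 * np.pi * nm.polarity_component_hz * t / 1000.0) * gate
        sweeps += sign * cm

    if nm.noise_sd > 0:
        if nm.noise_band is not None:
            # pad before filtering so filtfilt edge transients stay outside the epoch
            pad = max(64, int(4 * template.sampling_rate_hz / nm.noise_band[0]))
            noise = rng.standard_normal((n_sweeps, n + 2 * pad))
            nyq = template.sampling_rate_hz / 2.0
            sos = signal.butter(4, [nm.noise_band[0] / nyq, nm.noise_band[1] / nyq], btype="band", output="sos")
            noise = signal.sosfiltfilt(sos, noise, axis=1)[:, pad:pad + n]
            noise /= _bandlimit_gain(sos)
        else:
            noise = rng.standard_normal((n_sweeps, n))
        sweeps += nm.noise_sd * noise

    if nm.artifact_rate > 0:
        hit = rng.random(n_sweeps) < nm.artifact_rate
        for i in np.flatnonzero(hit):
            center = rng.integers(0, n)
            width = max(3, int(0.5e-3 * template.sampling_rate_hz))
            blip = _gaussian_peak(np.arange(n, dtype=float), float(center), 1.0, float(width))
            amp_uv = rng.uniform(45.0, 90.0) * rng.choice([-1.0, 1.0])
            sweeps[i] += amp_uv * blip

    return SweepBuffer(
        data=sweeps,
        sampling_rate_hz=template.sampling_rate_hz,
        t0_ms=template.t0_ms,
        channel=channel,
        polarity=polarity,
        stimulus_kind=template.stimulus_kind,
        participant_id=participant_id,
        collection_index=collection_index,
    )


def simulate_participant(
    participant_id: str,
    noise_model: NoiseModel,
    n_per_buffer: int = 1500,
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ,
    f0_hz: float = DEFAULT_F0_HZ,
    seed: int = 0,
) -> list[SweepBuffer]:
    """Simulate one participant's full recording session.

    Returns six buffers: four /da/ buffers (channels A/B × condensation/
    rarefaction) and two single-polarity click buffers (channels A/B,
    condensation), each with ``n_per_buffer`` sweeps.
    """
    da = make_template("da40", sampling_rate_hz, f0_hz)
    click = make_template("click", sampling_rate_hz)
    rng = np.random.default_rng(seed)
    buffers = []
    for ch in ("A", "B"):
        for pol in POLARITIES:
            buffers.append(
                simulate_sweeps(da, noise_model, n_per_buffer, ch, pol,
                                seed=int(rng.integers(2**31)), participant_id=participant_id)
            )
    for ch in ("A", "B"):
        buffers.append(
            simulate_sweeps(click, noise_model, n_per_buffer, ch, "condensation",
                            seed=int(rng.integers(2**31)), participant_id=participant_id)
        )
    return buffers


# ---------------------------------------------------------------------------
# cohort-level generator: Fisher-z stability from the random-intercept model
# ---------------------------------------------------------------------------

#: component deviations from the grand mean (Fisher-z units); sum to zero
DEFAULT_COMPONENT_OFFSETS = {
    "click": 0.76,
    "full_sabr": -0.38,
    "onset": 0.24,
    "ffr": -0.15,
    "offset": -0.47,
}


@dataclass
class CohortSpec:
    """Ground-truth parameters for a simulated stability × trait cohort.

    ``Zr_ij = intercept + offset_j + beta_trait·AQ_i + b_i + e_ij`` with
    ``b_i ~ N(0, participant_sd²)`` and ``e_ij ~ N(0, residual_sd²)``.
    The trait scale is AQ points (0–50); ``beta_trait`` is the change in
    Fisher-z stability per AQ point.
    """

    n_participants: int
    seed: int
    trait_mean: float = 21.56
    trait_sd: float = 12.53
    beta_trait: float = -0.023
    intercept: float = 0.43
    component_offsets: dict = field(default_factory=lambda: dict(DEFAULT_COMPONENT_OFFSETS))
    participant_sd: float = 0.54
    residual_sd: float = 0.65
    srs_aq_correlation: float = 0.88

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("n_participants must be at least 2")
        if self.participant_sd < 0 or self.residual_sd < 0 or self.trait_sd < 0:
            raise ValueError("standard deviations must be nonnegative")
        if abs(sum(self.component_offsets.values())) > 1e-8:
            raise ValueError("component_offsets must sum to zero (effects coding)")


def _split_subscales(total: float, rng: np.random.Generator) -> np.ndarray:
    """Split an AQ total into five subscale scores in [0, 10] summing to total."""
    total = int(round(total))  # ≤ 50, so the 5 × 10 ceiling is always feasible
    props = rng.dirichlet(np.full(5, 2.0))
    sub = np.minimum(np.floor(props * total).astype(int), 10)
    # distribute the remainder, respecting the per-subscale ceiling of 10
    while sub.sum() < total:
        room = np.flatnonzero(sub < 10)
        sub[rng.choice(room)] += 1
    return sub


AQ_SUBSCALES = ("attention_switching", "attention_to_detail", "communication",
                "social_skills", "imagination")


def simulate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (stability table, trait table) for a synthetic cohort.

    The stability table is long format (participant_id, component, r, Zr);
    ``r = tanh(Zr)``.  The trait table carries AQ total and subscales, an
    SRS-2 T-score correlated with AQ, age, VCI, and a group label.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_participants
    ids = [f"P{i:03d}" for i in range(1, n + 1)]

    z_aq = rng.standard_normal(n)
    aq = np.clip(np.round(spec.trait_mean + spec.trait_sd * z_aq), 0, 50)
    rho = spec.srs_aq_correlation
    srs = np.round(50 + 10 * (rho * z_aq + math.sqrt(1 - rho**2) * rng.standard_normal(n)), 1)
    srs = np.clip(srs, 30, 100)
    age = np.round(rng.uniform(6.0, 16.9, n), 1)
    vci = np.round(np.clip(rng.normal(109.0, 14.0, n), 70, 145))

    b = spec.participant_sd * rng.standard_normal(n)
    rows = []
    for i, pid in enumerate(ids):
        for comp, off in spec.component_offsets.items():
            e = spec.residual_sd * rng.standard_normal()
            zr = spec.intercept + off + spec.beta_trait * aq[i] + b[i] + e
            rows.append((pid, comp, math.tanh(zr), zr))
    stability = pd.DataFrame(rows, columns=["participant_id", "component", "r", "Zr"])

    sub_cols = {f"aq_{s}": np.zeros(n, dtype=int) for s in AQ_SUBSCALES}
    for i in range(n):
        parts = _split_subscales(aq[i], rng)
        for j, s in enumerate(AQ_SUBSCALES):
            sub_cols[f"aq_{s}"][i] = parts[j]
    traits = pd.DataFrame({
        "participant_id": ids,
        "aq_total": aq.astype(int),
        **sub_cols,
        "aq_form": np.where(age >= 16, "adult_self", np.where(age >= 12, "adolescent", "child")),
        "srs2_t": srs,
        "age": age,
        "vci": vci,
        "group": np.where(aq >= 32, "autistic", "neurotypical"),
    })
    return stability, traits
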