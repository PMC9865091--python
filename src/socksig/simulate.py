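"""Synthetic two-site EDA, PPG, and ancillary channels with known ground truth.

The study conditions these generators emulate: 300 s recordings at 1 kHz, a
hand (reference) and a foot (test) electrodermal channel that share a fraction
of their skin-conductance responses, foot responses lagging shared drivers,
low foot conductance that saturates at the sensor floor, and a
photoplethysmogram with known systolic-peak times.  Every generated recording
carries a :class:`GroundTruth` so downstream statistics (consensus, lag,
detection metrics, HR error) can be checked against planted values.

Sudomotor responses are modeled as a Bateman impulse response
``exp(-t/tau_decay) - exp(-t/tau_rise)`` normalized to unit peak; event times
follow a homogeneous Poisson process with a 1 s refractory period.  The PPG
pulse is a two-lobe (systolic + delayed diastolic Gaussian) template, which is
the simplest shape producing the systolic peak / dicrotic notch / diastolic
peak morphology of a reflective-mode sensor.

One top-level seed drives everything; per-channel substreams are derived
deterministically with ``numpy.random.SeedSequence.spawn``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import CalibrationParams, SignalRecord

_MAX_SAMPLES = 200_000_000  # overflow guard for duration * rate


@dataclass(frozen=True)
class EdaSimConfig:
    """Conditions for the dual-site electrodermal simulation.

    Defaults mirror the validation protocol: 300 s at 1 kHz, hand tonic level
    in the typical palmar range, foot tonic level much lower (the medial arch
    runs below the hand), ~6 responses/min of which 70% are shared between
    sites, shared foot responses lagging the hand by 0.41 +/- 0.70 s, and a
    25 uS sensor ceiling.
    """

    duration: float = 300.0          # s
    sampling_rate: float = 1000.0    # Hz
    event_rate: float = 6.0          # events/min
    p_shared: float = 0.7
    hand_tonic_level: float = 5.0    # uS
    foot_tonic_level: float = 1.0    # uS
    tonic_drift_sd: float = 0.3      # uS drift over the whole recording
    amplitude_mean: float = 0.5      # uS
    amplitude_sd: float = 0.15       # uS
    foot_lag_mean: float = 0.41      # s
    foot_lag_sd: float = 0.70        # s
    kernel_tau_rise: float = 0.7     # s
    kernel_tau_decay: float = 2.0    # s
    noise_sd: float = 0.01           # uS
    sensor_floor: float = 0.0        # uS; values below clip to 0
    sensor_ceiling: float = 25.0     # uS
    all_zero_foot: bool = False      # open-circuit contact: foot channel all 0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "duration", "sampling_rate", "event_rate", "p_shared",
            "hand_tonic_level", "foot_tonic_level", "tonic_drift_sd",
            "amplitude_mean", "amplitude_sd", "foot_lag_mean", "foot_lag_sd",
            "kernel_tau_rise", "kernel_tau_decay", "noise_sd",
            "sensor_floor", "sensor_ceiling",
        ):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite config value: {name}")
        if self.duration <= 0 or self.sampling_rate <= 0:
            raise ValueError("duration and sampling_rate must be positive")
        if self.duration * self.sampling_rate > _MAX_SAMPLES:
            raise ValueError("duration * sampling_rate exceeds the sample guard")
        if not 0.0 <= self.p_shared <= 1.0:
            raise ValueError("p_shared must lie in [0, 1]")
        if not (self.kernel_tau_decay > self.kernel_tau_rise > 0):
            raise ValueError("need kernel_tau_decay > kernel_tau_rise > 0")
        if not (self.sensor_ceiling > self.sensor_floor >= 0):
            raise ValueError("need sensor_ceiling > sensor_floor >= 0")


@dataclass(frozen=True)
class PpgSimConfig:
    """Conditions for the photoplethysmogram simulation.

    The two-lobe template reproduces the systolic peak, dicrotic notch and
    diastolic peak; inter-beat intervals are ``60 / N(mean_hr, hr_sd)``
    truncated positive.
    """

    duration: float = 300.0
    sampling_rate: float = 1000.0
    mean_hr: float = 70.0            # BPM
    hr_sd: float = 3.0               # BPM beat-to-beat
    systolic_width: float = 0.08     # s (Gaussian sigma of the systolic lobe)
    diastolic_width: float = 0.12    # s
    diastolic_relative_amplitude: float = 0.45
    dicrotic_delay: float = 0.35     # s between systolic and diastolic apex
    baseline_wander_amp: float = 0.1  # a.u.
    baseline_wander_freq: float = 0.25  # Hz (respiratory)
    noise_sd: float = 0.02           # a.u.
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.sampling_rate <= 0:
            raise ValueError("duration and sampling_rate must be positive")
        if self.duration * self.sampling_rate > _MAX_SAMPLES:
            raise ValueError("duration * sampling_rate exceeds the sample guard")
        if not 20.0 <= self.mean_hr <= 240.0:
            raise ValueError("mean_hr outside the sane 20-240 BPM range")
        if self.systolic_width <= 0 or self.diastolic_width <= 0:
            raise ValueError("lobe widths must be positive")
        if not 0.0 <= self.diastolic_relative_amplitude < 1.0:
            raise ValueError("diastolic_relative_amplitude must lie in [0, 1)")
        if self.dicrotic_delay >= 60.0 / self.mean_hr:
            raise ValueError("dicrotic_delay must be shorter than a mean beat")


@dataclass
class GroundTruth:
    """Planted events for a synthetic recording (the oracle for statistics)."""

    hand_scr_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    foot_scr_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    shared_flags: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))
    planted_lags: np.ndarray = field(default_factory=lambda: np.empty(0))
    beat_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    saturation_intervals: list = field(default_factory=list)

    def validate(self) -> None:
        for times in (self.hand_scr_times, self.foot_scr_times, self.beat_times):
            if times.size > 1 and not np.all(np.diff(times) > 0):
                raise ValueError("event times must be strictly increasing")
        if self.planted_lags.size and self.planted_lags.size != int(
            np.sum(self.shared_flags)
        ):
            raise ValueError("planted_lags must cover exactly the shared events")
        ivs = sorted(self.saturation_intervals)
        for (a0, a1), (b0, b1) in zip(ivs, ivs[1:]):
            if b0 < a1:
                raise ValueError("saturation intervals must not overlap")


def bateman_kernel(t: np.ndarray, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Difference-of-exponentials SCR impulse response, unit peak, 0 for t < 0."""
    if not tau_decay > tau_rise > 0:
        raise ValueError("need tau_decay > tau_rise > 0")
    t = np.asarray(t, dtype=float)
    out = np.where(t >= 0, np.exp(-t / tau_decay) - np.exp(-t / tau_rise), 0.0)
    # analytic peak location/height of the difference of exponentials
    t_peak = (
        tau_rise * tau_decay / (tau_decay - tau_rise)
        * math.log(tau_decay / tau_rise)
    )
    peak = math.exp(-t_peak / tau_decay) - math.exp(-t_peak / tau_rise)
    return out / peak


def _poisson_events(
    rng: np.random.Generator, duration: float, rate_per_min: float,
    refractory: float = 1.0,
) -> np.ndarray:
    """Homogeneous Poisson event times with a refractory period, within [0, T)."""
    if rate_per_min <= 0:
        return np.empty(0)
    rate = rate_per_min / 60.0
    times = []
    t = 0.0
    while True:
        gap = rng.exponential(1.0 / rate) + refractory
        t += gap
        if t >= duration:
            break
        times.append(t)
    return np.asarray(times)


def _zero_runs(x: np.ndarray, fs: float) -> list:
    """Half-open [start, end) intervals (s) over which x == 0."""
    z = x == 0
    if not z.any():
        return []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], z.view(np.int8), [0]))))
    starts, ends = edges[::2], edges[1::2]
    return [(s / fs, e / fs) for s, e in zip(starts, ends)]


def simulate_dual_site_eda(
    config: EdaSimConfig,
) -> tuple[SignalRecord, SignalRecord, GroundTruth]:
    """Generate hand and foot skin-conductance channels with shared responses.

    Each site is tonic level + slow drift + sum of Bateman pulses + Gaussian
    noise, clipped to [0, sensor_ceiling] with values below ``sensor_floor``
    set to 0 (sensor saturation at the low end).  A fraction ``p_shared`` of
    hand events re-occur at the foot after a planted lag drawn from
    ``N(foot_lag_mean, foot_lag_sd)``; the remaining events are site-specific.
    """
    fs = config.sampling_rate
    n = int(round(config.duration * fs))
    ss = np.random.SeedSequence(config.seed)
    (s_events, s_amps, s_lags, s_drift_h, s_drift_f,
     s_noise_h, s_noise_f) = [np.random.default_rng(c) for c in ss.spawn(7)]

    hand_times = _poisson_events(s_events, config.duration, config.event_rate)
    shared = s_events.random(hand_times.size) < config.p_shared
    lags = s_lags.normal(config.foot_lag_mean, config.foot_lag_sd, int(shared.sum()))
    foot_from_shared = hand_times[shared] + lags
    # independent foot-only events at the complementary rate
    foot_only_rate = config.event_rate * (1.0 - config.p_shared)
    foot_only = _poisson_events(s_events, config.duration, foot_only_rate)
    foot_times = np.sort(np.concatenate([foot_from_shared, foot_only]))
    foot_times = foot_times[(foot_times >= 0) & (foot_times < config.duration)]

    t = np.arange(n) / fs
    tail = 10.0 * config.kernel_tau_decay
    kt = np.arange(0, min(tail, config.duration), 1.0 / fs)
    kernel = bateman_kernel(kt, config.kernel_tau_rise, config.kernel_tau_decay)

    def site_signal(times, amp_rng, drift_rng, noise_rng, tonic_level):
        driver = np.zeros(n)
        for ev in times:
            idx = int(round(ev * fs))
            if 0 <= idx < n:
                driver[idx] += max(
                    amp_rng.normal(config.amplitude_mean, config.amplitude_sd), 0.0
                )
        phasic = np.convolve(driver, kernel)[:n]
        # slow drift: random walk on a 20 s knot grid interpolated to the
        # sample grid, rescaled to the target sd — keeps second-scale
        # fluctuations far below SCR amplitudes, as real tonic level does
        if config.tonic_drift_sd > 0:
            knot_dt = 20.0
            nk = max(int(np.ceil(config.duration / knot_dt)) + 2, 4)
            w = np.cumsum(drift_rng.standard_normal(nk))
            w = w - w.mean()
            sd = w.std()
            w = config.tonic_drift_sd * w / sd if sd > 0 else w * 0.0
            drift = np.interp(t, np.arange(nk) * knot_dt, w)
        else:
            drift = np.zeros(n)
        x = tonic_level + drift + phasic
        if config.noise_sd > 0:
            x = x + noise_rng.normal(0.0, config.noise_sd, n)
        x = np.where(x < config.sensor_floor, 0.0, x)
        return np.clip(x, 0.0, config.sensor_ceiling)

    foot_amp_rng = np.random.default_rng(ss.spawn(1)[0])
    hand = site_signal(hand_times, s_amps, s_drift_h, s_noise_h,
                       config.hand_tonic_level)
    foot = site_signal(foot_times, foot_amp_rng, s_drift_f, s_noise_f,
                       config.foot_tonic_level)
    if config.all_zero_foot:
        foot = np.zeros(n)

    truth = GroundTruth(
        hand_scr_times=hand_times,
        foot_scr_times=foot_times,
        shared_flags=shared,
        planted_lags=lags,
        beat_times=np.empty(0),
        saturation_intervals=_zero_runs(foot, fs),
    )
    truth.validate()
    hand_rec = SignalRecord(hand, fs, units="uS", name="eda_hand")
    foot_rec = SignalRecord(foot, fs, units="uS", name="eda_foot")
    return hand_rec, foot_rec, truth


def simulate_ppg(config: PpgSimConfig) -> tuple[SignalRecord, GroundTruth]:
    """Generate a PPG channel; ``truth.beat_times`` are the systolic apexes."""
    fs = config.sampling_rate
    n = int(round(config.duration * fs))
    ss = np.random.SeedSequence(config.seed)
    s_ibi, s_noise = [np.random.default_rng(c) for c in ss.spawn(2)]

    beats = []
    t = 60.0 / config.mean_hr  # first apex one mean beat in
    while t < config.duration:
        beats.append(t)
        hr = config.mean_hr + (s_ibi.normal(0.0, config.hr_sd) if config.hr_sd > 0 else 0.0)
        hr = max(hr, 1.0)
        t += 60.0 / hr
    beat_times = np.asarray(beats)

    time = np.arange(n) / fs
    x = np.zeros(n)
    half = 4.0 * max(config.systolic_width, config.diastolic_width) + config.dicrotic_delay
    for b in beat_times:
        i0 = max(0, int((b - half) * fs))
        i1 = min(n, int((b + half) * fs) + 1)
        seg = time[i0:i1]
        x[i0:i1] += np.exp(-0.5 * ((seg - b) / config.systolic_width) ** 2)
        if config.diastolic_relative_amplitude > 0:
            x[i0:i1] += config.diastolic_relative_amplitude * np.exp(
                -0.5 * ((seg - b - config.dicrotic_delay) / config.diastolic_width) ** 2
            )
    if config.baseline_wander_amp > 0:
        x = x + config.baseline_wander_amp * np.sin(
            2.0 * np.pi * config.baseline_wander_freq * time
        )
    if config.noise_sd > 0:
        x = x + s_noise.normal(0.0, config.noise_sd, n)

    truth = GroundTruth(beat_times=beat_times)
    truth.validate()
    return SignalRecord(x, fs, units="a.u.", name="ppg"), truth


def simulate_ancillary(
    duration: float, sampling_rate: float, seed: int = 0,
    acc_jitter_sd: float = 0.01, temp_start: float = 31.0,
    temp_drift: float = 1.0,
) -> tuple[list[SignalRecord], SignalRecord]:
    """Near-still triaxial acceleration (g) and slowly drifting skin temperature.

    Acceleration jitters around a gravity-aligned rest vector (0, 0, 1) g;
    temperature drifts smoothly within the ~29-34 degC skin range.
    """
    if duration <= 0 or sampling_rate <= 0:
        raise ValueError("duration and sampling_rate must be positive")
    n = int(round(duration * sampling_rate))
    ss = np.random.SeedSequence(seed)
    s_acc, s_temp = [np.random.default_rng(c) for c in ss.spawn(2)]
    rest = np.array([0.0, 0.0, 1.0])
    acc = []
    for axis, g0 in zip("xyz", rest):
        x = np.full(n, g0)
        if acc_jitter_sd > 0:
            x = x + s_acc.normal(0.0, acc_jitter_sd, n)
        acc.append(SignalRecord(x, sampling_rate, units="g", name=f"acc_{axis}"))
    w = np.cumsum(s_temp.standard_normal(n))
    w = w - w[0]
    sd = w.std()
    drift = temp_drift * w / sd if sd > 0 else w
    temp = np.clip(temp_start + drift, 29.0, 34.0)
    return acc, SignalRecord(temp, sampling_rate, units="degC", name="temperature")


# ---------------------------------------------------------------------------
# ADC encoding (inverse sensor transfers) and optical sync embedding
# ---------------------------------------------------------------------------

def encode_adc(
    record: SignalRecord,
    cal: CalibrationParams = CalibrationParams(),
    kind: str = "acc",
    gain: float = 1.0,
    offset: float = 0.0,
) -> SignalRecord:
    """Encode physical values to integer ADC counts (inverse transfer).

    ``kind`` selects the forward transfer being inverted: ``"acc"`` (counts ->
    g), ``"temp"`` (counts -> degC) or ``"affine"`` (counts*gain + offset,
    e.g. a user-supplied EDA transfer).  Counts round to nearest and clamp to
    [0, 2^n - 1]; applying the forward transfer recovers the physical values
    to within one quantization step.
    """
    x = np.asarray(record.samples, dtype=float)
    if kind == "acc":
        counts = (x + 1.0) / 2.0 * (cal.adc_max - cal.adc_min) + cal.adc_min
    elif kind == "temp":
        volts = x / cal.temp_scale + cal.temp_offset
        counts = volts * 2 ** cal.resolution_bits / cal.vcc
    elif kind == "affine":
        if gain == 0:
            raise ValueError("affine transfer with zero gain is not invertible")
        counts = (x - offset) / gain
    else:
        raise ValueError(f"unknown transfer kind: {kind!r}")
    hi = 2 ** cal.resolution_bits - 1
    counts = np.clip(np.rint(counts), 0, hi).astype(np.int64)
    return record.copy_with(samples=counts, units="adc")


def embed_sync_events(
    a: SignalRecord,
    b: SignalRecord,
    offset: float,
    pulse_times: Sequence[float],
    pulse_width: float = 0.2,
    smoothing: float = 0.01,
) -> tuple[SignalRecord, SignalRecord]:
    """Build the optical sync channels for two devices.

    Device B drives the LED: its sync channel holds rectangular pulses at
    ``pulse_times`` (device-B clock).  Device A records the light sensor: the
    same pulses appear shifted by ``offset`` seconds (positive = A started
    earlier, so pulses land later in A's record) and low-pass smoothed to
    emulate the analog sensor response.
    """
    if abs(offset) >= min(a.duration, b.duration):
        raise ValueError("offset exceeds the record duration")
    pulse_times = np.asarray(pulse_times, dtype=float)
    if pulse_times.size == 0:
        raise ValueError("need at least one sync pulse")
    if np.any(pulse_times + pulse_width > b.duration) or np.any(pulse_times < 0):
        raise ValueError("pulse_times fall outside device B's record")
    if np.any(pulse_times + offset < 0) or np.any(
        pulse_times + offset + pulse_width > a.duration
    ):
        raise ValueError("offset pulses fall outside device A's record")

    def rect(n, fs, times):
        x = np.zeros(n)
        for t0 in times:
            i0 = int(round(t0 * fs))
            i1 = min(n, i0 + max(1, int(round(pulse_width * fs))))
            x[i0:i1] = 1.0
        return x

    sync_b = rect(b.n, b.sampling_rate, pulse_times)
    sync_a = rect(a.n, a.sampling_rate, pulse_times + offset)
    if smoothing > 0:
        w = max(1, int(round(smoothing * a.sampling_rate)))
        # centered moving average: preserves pulse centers, softens edges
        sync_a = np.convolve(sync_a, np.ones(w) / w, mode="same")
    rec_a = SignalRecord(sync_a, a.sampling_rate, start_time=a.start_time,
                         units="a.u.", name="sync_light")
    rec_b = SignalRecord(sync_b, b.sampling_rate, start_time=b.start_time,
                         units="bool", name="sync_led")
    return rec_a, rec_b
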