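"""Signal containers, delimited-text file I/O, sensor calibration and two-device sync.

Signals are uniformly sampled single channels stored in :class:`SignalRecord`.
Files are UTF-8 tab-separated text with one or more ``#``-prefixed JSON header
lines declaring the sampling rate and the channel names/units; one column per
channel.  The format is deliberately close to common biosignal-logger exports
and is human-inspectable.

Calibration covers the accelerometer and temperature transfer functions of the
acquisition hardware (12-bit ADC, 3.3 V supply by default) and their inverses,
plus the electrode-resistance summary arithmetic used to validate textile EDA
electrodes on the bench.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import signal as sps


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero at ``ndigits`` decimals, decimal-exactly.

    Matches how values are conventionally rounded for printing (0.005 -> 0.01),
    unlike banker's rounding.  Uses the shortest decimal repr of ``x`` so that
    e.g. 32.355 rounds to 32.36 rather than falling on a binary artefact.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class SignalRecord:
    """One uniformly sampled channel.

    Parameters
    ----------
    samples : array-like
        Sample values, physical units or raw ADC counts.
    sampling_rate : float
        Sampling rate in Hz; must be positive.
    start_time : float
        Time of the first sample in seconds (offset after synchronization).
    units : str
        Unit string, e.g. ``"uS"``, ``"g"``, ``"degC"``, ``"adc"``.
    name : str
        Channel name, e.g. ``"eda_hand"``.
    """

    samples: np.ndarray
    sampling_rate: float
    start_time: float = 0.0
    units: str = ""
    name: str = "signal"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D sequence")

    @property
    def n(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Record duration in seconds (half-open convention, n / fs)."""
        return self.n / self.sampling_rate

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration

    def times(self) -> np.ndarray:
        """Sample times in seconds (0-based indexing from ``start_time``)."""
        return self.start_time + np.arange(self.n) / self.sampling_rate

    def copy_with(self, **kw) -> "SignalRecord":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# Delimited-text signal files
# ---------------------------------------------------------------------------

def write_signal_file(records: Sequence[SignalRecord], path) -> None:
    """Write one or more equal-length, equal-rate channels to a text file.

    Header is a single ``#``-prefixed JSON line with ``rate_hz``,
    ``start_time_s``, ``channels`` (name/units per column) and any extra keys
    found in the first record's ``meta`` (preserved across round-trips).
    Integer channels are written as integers, floats at full precision.
    """
    records = list(records)
    if not records:
        raise ValueError("no records to write")
    rate = records[0].sampling_rate
    n = records[0].n
    for r in records:
        if r.sampling_rate != rate:
            raise ValueError("all channels must share one sampling rate")
        if r.n != n:
            raise ValueError("all channels must have equal length")
    header = dict(records[0].meta)
    header.update(
        {
            "rate_hz": rate,
            "start_time_s": records[0].start_time,
            "channels": [{"name": r.name, "units": r.units} for r in records],
        }
    )
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("# " + json.dumps(header) + "\n")
        cols = [r.samples for r in records]
        fmts = [
            "%d" if np.issubdtype(c.dtype, np.integer) else "%.17g" for c in cols
        ]
        for i in range(n):
            fh.write("\t".join(f % c[i] for f, c in zip(fmts, cols)) + "\n")


def read_signal_file(path) -> list[SignalRecord]:
    """Read a delimited-text signal file; one record per declared channel.

    Raises
    ------
    ValueError
        If the JSON header is missing/garbled or column counts are
        inconsistent with the declared channels.
    """
    path = Path(path)
    header = None
    data_lines: list[str] = []
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if header is None:
                    try:
                        header = json.loads(line.lstrip("#").strip())
                    except json.JSONDecodeError as exc:
                        raise ValueError(f"garbled signal-file header: {exc}") from exc
                continue
            data_lines.append(line)
    if header is None or "rate_hz" not in header or "channels" not in header:
        raise ValueError("missing or incomplete signal-file header")
    channels = header["channels"]
    ncol = len(channels)
    rows = []
    for ln, line in enumerate(data_lines, 1):
        parts = line.split("\t")
        if len(parts) != ncol:
            raise ValueError(
                f"row {ln}: expected {ncol} columns, found {len(parts)}"
            )
        rows.append(parts)
    if not rows:
        raise ValueError("signal file contains no samples")
    extra = {
        k: v for k, v in header.items() if k not in ("rate_hz", "start_time_s", "channels")
    }
    records = []
    for j, ch in enumerate(channels):
        col = [r[j] for r in rows]
        try:
            arr = np.array([int(v) for v in col], dtype=np.int64)
        except ValueError:
            arr = np.array([float(v) for v in col], dtype=np.float64)
        records.append(
            SignalRecord(
                samples=arr,
                sampling_rate=float(header["rate_hz"]),
                start_time=float(header.get("start_time_s", 0.0)),
                units=ch.get("units", ""),
                name=ch.get("name", f"ch{j}"),
                meta=dict(extra),
            )
        )
    return records


def write_events_csv(path, rows: Iterable[Mapping], columns: Sequence[str]) -> None:
    """Tiny CSV writer for annotation/event tables (no quoting needed)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(",".join(columns) + "\n")
        for row in rows:
            fh.write(",".join(str(row[c]) for c in columns) + "\n")


# ---------------------------------------------------------------------------
# Sensor calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationParams:
    """ADC calibration constants for the acquisition hardware.

    ``adc_min``/``adc_max`` are the accelerometer counts observed at -1 g and
    +1 g during a full revolution of the sensor.  ``vcc`` is the supply
    voltage; ``temp_offset`` (0.5 V) and ``temp_scale`` (100 mV/degC) are the
    temperature-sensor datasheet constants.
    """

    adc_min: int = 541
    adc_max: int = 965
    resolution_bits: int = 12
    vcc: float = 3.3
    temp_offset: float = 0.5
    temp_scale: float = 100.0

    def __post_init__(self) -> None:
        if self.adc_max <= self.adc_min:
            raise ValueError("degenerate calibration: adc_max must exceed adc_min")
        if not (8 <= self.resolution_bits <= 16):
            raise ValueError("resolution_bits must be within 8..16")
        if self.vcc <= 0:
            raise ValueError("vcc must be positive")


def acc_transfer(adc, cal: CalibrationParams = CalibrationParams()):
    """ADC counts -> acceleration in g: ``2*(ADC - ADCmin)/(ADCmax - ADCmin) - 1``.

    Values outside [adc_min, adc_max] extrapolate (and a warning is issued).
    """
    adc = np.asarray(adc, dtype=float)
    if np.any((adc < cal.adc_min) | (adc > cal.adc_max)):
        warnings.warn("ADC counts outside calibration range; extrapolating", stacklevel=2)
    return 2.0 * (adc - cal.adc_min) / (cal.adc_max - cal.adc_min) - 1.0


def temperature_transfer(adc, cal: CalibrationParams = CalibrationParams()):
    """ADC counts -> temperature in degC: ``(ADC*Vcc/2^n - 0.5) * 100``."""
    adc = np.asarray(adc, dtype=float)
    volts = adc * cal.vcc / 2 ** cal.resolution_bits
    return (volts - cal.temp_offset) * cal.temp_scale


def affine_transfer(adc, gain: float, offset: float = 0.0):
    """Generic ADC->physical affine map (e.g. a user-supplied EDA transfer)."""
    return np.asarray(adc, dtype=float) * gain + offset


# ---------------------------------------------------------------------------
# Two-device synchronization via the optical trigger channel
# ---------------------------------------------------------------------------

class SyncError(RuntimeError):
    """Raised when the optical sync channels cannot be aligned."""


def _binarize(x: np.ndarray) -> np.ndarray:
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi <= lo:
        raise SyncError("sync channel is constant; no pulses detected")
    return (x > (lo + hi) / 2.0).astype(float)


def estimate_sync_offset(sync_a: SignalRecord, sync_b: SignalRecord) -> float:
    """Offset (s) of device A's sync pulses relative to device B's.

    Both channels are binarized at half-range and the lag maximizing their
    normalized cross-correlation is returned: positive means the pulse pattern
    appears later in A than in B.  A secondary correlation peak within 1% of
    the maximum and more than 100 ms away triggers an ambiguity warning.
    """
    if sync_a.sampling_rate != sync_b.sampling_rate:
        raise SyncError("sync channels must share a sampling rate")
    fs = sync_a.sampling_rate
    a = _binarize(np.asarray(sync_a.samples, dtype=float))
    b = _binarize(np.asarray(sync_b.samples, dtype=float))
    if a.sum() == 0 or b.sum() == 0:
        raise SyncError("no pulses detected in a sync channel")
    a0, b0 = a - a.mean(), b - b.mean()
    cc = sps.correlate(a0, b0, mode="full", method="fft")
    norm = np.sqrt(np.sum(a0 ** 2) * np.sum(b0 ** 2))
    if norm > 0:
        cc = cc / norm
    lags = sps.correlation_lags(a.size, b.size, mode="full")
    best = int(np.argmax(cc))
    guard = max(1, int(round(0.1 * fs)))
    far = np.abs(lags - lags[best]) > guard
    if np.any(far) and np.max(cc[far]) >= 0.99 * cc[best]:
        warnings.warn(
            "ambiguous sync correlation: secondary peak within 1% of maximum",
            stacklevel=2,
        )
    return float(lags[best]) / fs


def synchronize(
    records_a: Sequence[SignalRecord],
    records_b: Sequence[SignalRecord],
    sync_a: SignalRecord,
    sync_b: SignalRecord,
) -> tuple[float, list[SignalRecord], list[SignalRecord]]:
    """Align two devices' record sets using their optical sync channels.

    Returns ``(offset, aligned_a, aligned_b)`` where ``offset`` is A relative
    to B in seconds.  The lagging device's records are shifted onto the common
    clock and both sets are trimmed to the overlapping interval.
    """
    offset = estimate_sync_offset(sync_a, sync_b)
    # Put both devices on B's clock: events at t in B occur at t + offset in A.
    shifted_a = [r.copy_with(start_time=r.start_time - offset) for r in records_a]
    shifted_b = list(records_b)
    lo = max([r.start_time for r in shifted_a + shifted_b])
    hi = min([r.end_time for r in shifted_a + shifted_b])
    if hi <= lo:
        raise SyncError("no overlapping interval after alignment")

    def trim(r: SignalRecord) -> SignalRecord:
        i0 = int(np.ceil(round((lo - r.start_time) * r.sampling_rate, 9)))
        i1 = int(np.floor(round((hi - r.start_time) * r.sampling_rate, 9)))
        i0 = max(i0, 0)
        i1 = min(i1, r.n)
        return r.copy_with(
            samples=r.samples[i0:i1], start_time=r.start_time + i0 / r.sampling_rate
        )

    return offset, [trim(r) for r in shifted_a], [trim(r) for r in shifted_b]


# ---------------------------------------------------------------------------
# Electrode-resistance bench summary
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResistanceSummary:
    per_segment_mean: dict
    per_segment_sd: dict
    per_segment_min: dict
    per_segment_max: dict
    overall_mean: float            # mean of per-segment means, ohm
    max_difference: float          # overall max - overall min, ohm
    max_difference_pct_of_mean: float
    mean_conductance: float        # mS, from the overall mean at printed precision

    def to_dict(self) -> dict:
        return {
            "per_segment_mean": self.per_segment_mean,
            "per_segment_sd": self.per_segment_sd,
            "per_segment_min": self.per_segment_min,
            "per_segment_max": self.per_segment_max,
            "overall_mean_ohm": self.overall_mean,
            "max_difference_ohm": self.max_difference,
            "max_difference_pct_of_mean": self.max_difference_pct_of_mean,
            "mean_conductance_mS": self.mean_conductance,
        }


def _summary_from_parts(means, sds, mins, maxs) -> ResistanceSummary:
    overall_mean = float(np.mean(list(means.values())))
    max_difference = float(max(maxs.values()) - min(mins.values()))
    if max_difference < 0:
        raise ValueError("inconsistent min/max statistics")
    # Conductance and percentage are quoted against the mean at printed (2 dp)
    # precision, the convention used when reporting bench values.
    mean_2dp = round_half_away(overall_mean, 2)
    return ResistanceSummary(
        per_segment_mean=means,
        per_segment_sd=sds,
        per_segment_min=mins,
        per_segment_max=maxs,
        overall_mean=overall_mean,
        max_difference=max_difference,
        max_difference_pct_of_mean=100.0 * max_difference / mean_2dp,
        mean_conductance=1000.0 / mean_2dp,
    )


def resistance_summary(measurements: Mapping[str, Sequence[float]]) -> ResistanceSummary:
    """Summarize raw per-segment resistance measurements (ohm).

    Per-segment mean and sample sd, overall mean of per-segment means, the
    max-min spread over all measurements, that spread as % of the overall
    mean, and the overall mean converted to conductance in mS.
    """
    if not measurements or any(len(v) == 0 for v in measurements.values()):
        raise ValueError("need at least one measurement per segment")
    means = {k: float(np.mean(v)) for k, v in measurements.items()}
    sds = {
        k: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
        for k, v in measurements.items()
    }
    mins = {k: float(np.min(v)) for k, v in measurements.items()}
    maxs = {k: float(np.max(v)) for k, v in measurements.items()}
    return _summary_from_parts(means, sds, mins, maxs)


def resistance_summary_from_stats(
    stats: Mapping[str, Mapping[str, float]]
) -> ResistanceSummary:
    """Summary arithmetic from per-segment statistics ``{mean, sd, min, max}``.

    Used when only the bench report's printed statistics are available rather
    than the raw measurement lists.
    """
    if not stats:
        raise ValueError("empty statistics table")
    means = {k: float(v["mean"]) for k, v in stats.items()}
    sds = {k: float(v.get("sd", 0.0)) for k, v in stats.items()}
    mins = {k: float(v["min"]) for k, v in stats.items()}
    maxs = {k: float(v["max"]) for k, v in stats.items()}
    return _summary_from_parts(means, sds, mins, maxs)
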