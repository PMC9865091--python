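"""Hand-foot agreement statistics for dual-site electrodermal recordings.

The central object is the consensus of peaks: with hand SCR peaks as the
reference events, each foot peak may co-occur with at most one reference peak
inside a +/-2 s window, and the consensus is the fraction of reference peaks
with a co-occurring foot peak.  Matching is an exclusive one-to-one
assignment that maximizes the number of pairs and, among those, minimizes the
total absolute lag; equidistant ties go to the earlier reference peak.  A
stricter historical rule that discards a reference peak whenever two
unassigned test peaks fall in its window is available behind ``rule="strict"``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import linear_sum_assignment

from .io import SignalRecord

_BIG = 1e9  # cost of an out-of-window pairing; >> any feasible total lag


@dataclass
class PeakMatchResult:
    """Exclusive pairing of reference (hand) and test (foot) event times."""

    pairs: list          # (ref_time, test_time, lag = test - ref)
    unmatched_ref: list
    unmatched_test: list
    consensus: float     # len(pairs) / n_ref
    n_ref: int


@dataclass(frozen=True)
class WindowCorrelation:
    ref_peak_time: float
    window: tuple
    pearson_r: float     # NaN flags a constant segment


@dataclass(frozen=True)
class AssociationResult:
    candidate_name: str
    test_name: str
    statistic: float
    p_value: float


@dataclass
class LagStatistics:
    mean: float
    sd: float
    lags: np.ndarray = field(default_factory=lambda: np.empty(0))
    defined: bool = True


def _check_sorted(times: np.ndarray, label: str) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.size > 1 and np.any(np.diff(times) < 0):
        raise ValueError(f"{label} event times must be sorted ascending")
    return times


def match_peaks(
    ref_times: Sequence[float],
    test_times: Sequence[float],
    half_window: float = 2.0,
    rule: str = "closest",
) -> PeakMatchResult:
    """Pair test events to reference events within ``+/-half_window`` seconds.

    The assignment is exclusive (each test event in at most one pair),
    maximizes the number of in-window pairs, and among maximal assignments
    minimizes the total |lag|; equidistant ties resolve to the earlier
    reference peak.  ``rule="strict"`` additionally drops any pair whose
    reference window still contains two or more unassigned test peaks (the
    no-double-counting convention of earlier dual-site work).
    ``consensus = pairs / n_ref``.
    """
    if half_window < 0:
        raise ValueError("half_window must be nonnegative")
    if rule not in ("closest", "strict"):
        raise ValueError(f"unknown matching rule: {rule!r}")
    ref = _check_sorted(ref_times, "reference")
    test = _check_sorted(test_times, "test")
    n_ref, n_test = ref.size, test.size
    if n_ref == 0 or n_test == 0:
        return PeakMatchResult(
            pairs=[], unmatched_ref=list(ref), unmatched_test=list(test),
            consensus=0.0, n_ref=n_ref,
        )
    lag = test[None, :] - ref[:, None]
    feasible = np.abs(lag) <= half_window
    cost = np.where(feasible, np.abs(lag), _BIG)
    # tiny rank penalty: among equal-|lag| optima prefer earlier references
    cost = cost + 1e-9 * np.arange(n_ref)[:, None] * feasible
    rows, cols = linear_sum_assignment(cost)
    pairs = [
        (float(ref[i]), float(test[j]), float(test[j] - ref[i]))
        for i, j in zip(rows, cols)
        if feasible[i, j]
    ]
    if rule == "strict" and pairs:
        matched_test = {p[1] for p in pairs}
        free_test = np.array([t for t in test if t not in matched_test])
        kept = []
        for r, t, l in pairs:
            n_free_in_window = (
                int(np.sum(np.abs(free_test - r) <= half_window))
                if free_test.size
                else 0
            )
            if n_free_in_window >= 2:
                continue
            kept.append((r, t, l))
        pairs = kept
    matched_ref = {p[0] for p in pairs}
    matched_test = {p[1] for p in pairs}
    return PeakMatchResult(
        pairs=pairs,
        unmatched_ref=[float(t) for t in ref if t not in matched_ref],
        unmatched_test=[float(t) for t in test if t not in matched_test],
        consensus=len(pairs) / n_ref,
        n_ref=n_ref,
    )


def lag_statistics(result: PeakMatchResult) -> LagStatistics:
    """Mean and sample sd of matched lags (test minus reference, seconds).

    Positive mean means the reference (hand) peaks lead.  With no pairs the
    statistics are flagged undefined (NaN).
    """
    lags = np.asarray([p[2] for p in result.pairs], dtype=float)
    if lags.size == 0:
        return LagStatistics(mean=math.nan, sd=math.nan, lags=lags, defined=False)
    sd = float(np.std(lags, ddof=1)) if lags.size > 1 else 0.0
    return LagStatistics(mean=float(np.mean(lags)), sd=sd, lags=lags)


def full_signal_correlation(a: SignalRecord, b: SignalRecord) -> float:
    """Pearson r between two aligned equal-length channels; NaN if constant."""
    xa = np.asarray(a.samples, dtype=float)
    xb = np.asarray(b.samples, dtype=float)
    if xa.size != xb.size:
        raise ValueError("records must have equal length")
    if np.ptp(xa) == 0 or np.ptp(xb) == 0:
        warnings.warn("constant input: correlation undefined", stacklevel=2)
        return math.nan
    return float(stats.pearsonr(xa, xb).statistic)


def windowed_scr_correlations(
    hand_phasic: SignalRecord,
    foot_phasic: SignalRecord,
    match: PeakMatchResult,
    window: tuple = (-2.0, 2.2),
) -> list[WindowCorrelation]:
    """Pearson r between phasic segments around each matched reference peak.

    Segments span ``[peak + window[0], peak + window[1]]`` on both channels;
    windows clipped by a record edge are dropped rather than zero-padded.
    """
    lo, hi = window
    if hi <= lo:
        raise ValueError("window upper bound must exceed the lower bound")
    fs = hand_phasic.sampling_rate
    if foot_phasic.sampling_rate != fs:
        raise ValueError("phasic channels must share a sampling rate")
    xh = np.asarray(hand_phasic.samples, dtype=float)
    xf = np.asarray(foot_phasic.samples, dtype=float)
    nwin = int(round((hi - lo) * fs))
    out: list[WindowCorrelation] = []
    for ref_t, _, _ in match.pairs:
        i0 = int(round((ref_t + lo - hand_phasic.start_time) * fs))
        i1 = i0 + nwin
        if i0 < 0 or i1 > min(xh.size, xf.size):
            continue  # clipped at a record edge: drop
        seg_h, seg_f = xh[i0:i1], xf[i0:i1]
        if np.ptp(seg_h) == 0 or np.ptp(seg_f) == 0:
            r = math.nan
        else:
            r = float(stats.pearsonr(seg_h, seg_f).statistic)
        out.append(WindowCorrelation(ref_peak_time=ref_t, window=window, pearson_r=r))
    if not out and match.pairs:
        warnings.warn("all windows clipped by record edges", stacklevel=2)
    return out


def extra_event_count(
    ref_events: Sequence[float],
    test_events: Sequence[float],
    half_window: float = 2.0,
) -> int:
    """Number of test events with no reference event within ``+/-half_window``."""
    ref = _check_sorted(ref_events, "reference")
    test = _check_sorted(test_events, "test")
    if ref.size == 0:
        return int(test.size)
    count = 0
    for t in test:
        if np.min(np.abs(ref - t)) > half_window:
            count += 1
    return count


def association_screen(
    candidates: Mapping[str, Sequence],
    candidate_types: Mapping[str, str],
    target: Sequence[float],
    alpha: float = 0.05,
) -> list[AssociationResult]:
    """Screen per-subject candidate variables against a target variable.

    Continuous candidates use Pearson correlation, ordinal ones (e.g. age
    range) Spearman, and binary-group candidates a two-group comparison:
    one-way ANOVA when the target is normal within each group (Shapiro-Wilk
    at 0.05), Mann-Whitney U otherwise.  No multiplicity correction is
    applied; p-values are reported per candidate as-is.
    """
    y = np.asarray(target, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 subjects")
    out: list[AssociationResult] = []
    for name, values in candidates.items():
        kind = candidate_types[name]
        x = np.asarray(values)
        if x.size != y.size:
            raise ValueError(f"candidate {name!r} length mismatch")
        if kind in ("continuous", "ordinal") and np.ptp(x.astype(float)) == 0:
            out.append(AssociationResult(name, "undefined", math.nan, math.nan))
            continue
        if kind == "continuous":
            res = stats.pearsonr(x.astype(float), y)
            out.append(AssociationResult(name, "Pearson", float(res.statistic),
                                         float(res.pvalue)))
        elif kind == "ordinal":
            res = stats.spearmanr(x.astype(float), y)
            out.append(AssociationResult(name, "Spearman", float(res.statistic),
                                         float(res.pvalue)))
        elif kind == "binary-group":
            levels = np.unique(x)
            if levels.size != 2:
                out.append(AssociationResult(name, "undefined", math.nan, math.nan))
                continue
            g0, g1 = (y[x == lv] for lv in levels)
            normal = all(
                g.size >= 3 and stats.shapiro(g).pvalue > 0.05 for g in (g0, g1)
            )
            if normal:
                res = stats.f_oneway(g0, g1)
                out.append(AssociationResult(name, "ANOVA", float(res.statistic),
                                             float(res.pvalue)))
            else:
                res = stats.mannwhitneyu(g0, g1, alternative="two-sided")
                out.append(
                    AssociationResult(name, "Mann-Whitney U", float(res.statistic),
                                      float(res.pvalue))
                )
        else:
            raise ValueError(f"unknown candidate type: {kind!r}")
    return out
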