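"""Fluorescence-trace processing: ΔF/F, burst detection, bursting rates.

The unit of analysis is the network burst: a near-synchronous activation of
a large part of a cultured population, visible as a stereotyped calcium
transient. Baselines are estimated with a rolling low-percentile, which is
robust as long as bursts occupy well under half of the recording.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .config import Compartment
from .errors import EmptyDataError, ParameterError
from .recording import LineScanRecording


@dataclass
class BurstEvent:
    """One detected network burst."""

    onset_ms: float
    peak_ms: float
    peak_dff: float
    duration_ms: float

    def __post_init__(self) -> None:
        if self.onset_ms > self.peak_ms:
            raise ValueError("onset must not be after the peak")
        if self.duration_ms <= 0 or self.peak_dff <= 0:
            raise ValueError("duration and peak amplitude must be positive")


# ---------------------------------------------------------------------------
# ΔF/F
# ---------------------------------------------------------------------------

def rolling_percentile_baseline(
    trace: np.ndarray, window_samples: int, percentile: float = 10.0
) -> np.ndarray:
    """Centered rolling percentile of the unmasked (finite) samples."""
    s = pd.Series(trace)
    base = s.rolling(window_samples, center=True, min_periods=1).quantile(percentile / 100.0)
    # propagate through fully-masked stretches
    return base.ffill().bfill().to_numpy()


def compute_dff(
    recording: LineScanRecording,
    compartment: Compartment,
    baseline_window_ms: float = 10_000.0,
    baseline_percentile: float = 10.0,
) -> np.ndarray:
    """ΔF/F trace of one compartment.

    The baseline F0 is a rolling low percentile (default 10th over 10 s
    windows) of the unmasked samples; output is (F - F0) / F0 with masked
    samples kept as NaN.
    """
    trace = recording.trace(compartment)
    if not np.isfinite(trace).any():
        raise EmptyDataError(f"compartment {compartment}: all samples are masked")
    window = max(1, int(round(baseline_window_ms / recording.sample_interval_ms)))
    f0 = rolling_percentile_baseline(trace, window, baseline_percentile)
    return (trace - f0) / f0


# ---------------------------------------------------------------------------
# burst detection
# ---------------------------------------------------------------------------

def default_burst_threshold(dff: np.ndarray, n_mad: float = 5.0) -> float:
    """Detection threshold from the noise floor: ``n_mad`` robust SDs.

    The noise floor is estimated from the median absolute successive
    difference of the unmasked ΔF/F samples (scaled by 1.4826/sqrt(2) to a
    Gaussian SD). Differencing removes the slow calcium transients, so the
    estimate stays a *noise* measure even when bursts occupy a large
    fraction of the recording, as they do under repeated stimulation.
    """
    x = dff[np.isfinite(dff)]
    if x.size < 2:
        raise EmptyDataError("cannot estimate a threshold from an all-masked trace")
    sigma = 1.4826 * np.median(np.abs(np.diff(x))) / math.sqrt(2.0)
    return float(n_mad * sigma)


def _bridge_masked_gaps(dff: np.ndarray, max_gap_samples: int) -> np.ndarray:
    """Linearly interpolate masked gaps up to ``max_gap_samples`` long."""
    out = dff.copy()
    isnan = ~np.isfinite(out)
    if not isnan.any():
        return out
    idx = np.arange(len(out))
    # find contiguous NaN runs
    edges = np.flatnonzero(np.diff(np.concatenate(([False], isnan, [False]))))
    for start, end in zip(edges[::2], edges[1::2]):
        if end - start <= max_gap_samples and start > 0 and end < len(out):
            out[start:end] = np.interp(idx[start:end], [start - 1, end], [out[start - 1], out[end]])
    return out


def detect_bursts(
    dff: np.ndarray,
    sampling_rate: float,
    threshold_dff: Optional[float] = None,
    min_separation_ms: float = 500.0,
    max_bridged_gap_ms: float = 1024.0,
    min_duration_ms: float = 10.0,
) -> List[BurstEvent]:
    """Detect network bursts as upward threshold crossings of ΔF/F.

    Onset is the crossing sample, the peak is the maximum before the trace
    re-crosses downward; events closer than ``min_separation_ms`` are
    merged. Masked gaps up to ``max_bridged_gap_ms`` (the longest stimulus)
    are bridged by linear interpolation first, so a transient split by a
    stimulation mask is still one event; longer gaps split the trace.
    Supra-threshold excursions shorter than ``min_duration_ms`` are
    discarded: a network-burst calcium transient lasts hundreds of
    milliseconds, while isolated single-sample exceedances are noise.
    """
    if threshold_dff is None:
        threshold_dff = default_burst_threshold(dff)
    if threshold_dff <= 0:
        raise ParameterError("threshold_dff must be positive")
    dt = 1000.0 / sampling_rate
    x = _bridge_masked_gaps(np.asarray(dff, dtype=float), int(round(max_bridged_gap_ms / dt)))

    above = np.isfinite(x) & (x > threshold_dff)
    edges = np.flatnonzero(np.diff(np.concatenate(([False], above, [False]))))
    events: List[BurstEvent] = []
    min_samples = max(1, int(round(min_duration_ms / dt)))
    for start, end in zip(edges[::2], edges[1::2]):
        if end - start < min_samples:
            continue
        seg = x[start:end]
        peak_i = int(np.nanargmax(seg))
        if events and (start * dt - (events[-1].onset_ms + events[-1].duration_ms)) < min_separation_ms:
            prev = events[-1]
            new_end_ms = end * dt
            peak_dff = max(prev.peak_dff, float(seg[peak_i]))
            peak_ms = prev.peak_ms if prev.peak_dff >= seg[peak_i] else (start + peak_i) * dt
            events[-1] = BurstEvent(
                onset_ms=prev.onset_ms,
                peak_ms=peak_ms,
                peak_dff=peak_dff,
                duration_ms=new_end_ms - prev.onset_ms,
            )
        else:
            events.append(
                BurstEvent(
                    onset_ms=start * dt,
                    peak_ms=(start + peak_i) * dt,
                    peak_dff=float(seg[peak_i]),
                    duration_ms=(end - start) * dt,
                )
            )
    return events


def bursting_rate(events: Sequence[BurstEvent], duration_min: float) -> float:
    """Bursting rate in bursts per minute."""
    if duration_min <= 0:
        raise ParameterError("duration_min must be positive")
    return len(events) / duration_min


# ---------------------------------------------------------------------------
# rate tables
# ---------------------------------------------------------------------------

def normalize_rates(
    rates: Mapping[str, Mapping[str, float]], reference_condition: str
) -> pd.DataFrame:
    """Per-culture rate table normalized by each culture's reference condition.

    ``rates`` maps culture -> condition -> bursts/min. Each culture's rates
    are divided by its own rate in ``reference_condition``, removing
    inter-culture variability in baseline activity. Cultures with a zero
    (or missing) reference rate are degenerate: they are excluded and
    reported in the table attribute ``excluded_cultures``.
    """
    rows = []
    excluded: List[str] = []
    for culture, conds in rates.items():
        ref = conds.get(reference_condition, 0.0)
        if ref <= 0:
            excluded.append(culture)
            continue
        for cond, rate in conds.items():
            rows.append(
                {
                    "culture": culture,
                    "condition": cond,
                    "rate_bpm": rate,
                    "normalized_rate": rate / ref,
                }
            )
    table = pd.DataFrame(rows, columns=["culture", "condition", "rate_bpm", "normalized_rate"])
    table.attrs["excluded_cultures"] = excluded
    table.attrs["reference_condition"] = reference_condition
    return table


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

def bin_trace(trace: np.ndarray, bin_ms: float, sampling_rate: float) -> np.ndarray:
    """Mean of unmasked samples per ``bin_ms`` bin; empty bins stay masked."""
    dt = 1000.0 / sampling_rate
    ratio = bin_ms / dt
    if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
        raise ParameterError(
            f"bin width {bin_ms} ms is not a multiple of the {dt} ms sample interval"
        )
    k = int(round(ratio))
    n = (len(trace) // k) * k
    blocks = np.asarray(trace, dtype=float)[:n].reshape(-1, k)
    with np.errstate(invalid="ignore"):
        counts = np.isfinite(blocks).sum(axis=1)
        sums = np.nansum(np.where(np.isfinite(blocks), blocks, 0.0), axis=1)
    out = np.full(len(blocks), np.nan)
    nonempty = counts > 0
    out[nonempty] = sums[nonempty] / counts[nonempty]
    return out
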