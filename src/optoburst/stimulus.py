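"""Peristimulus alignment, evoked-response scoring and duration curves.

Traces are aligned to 470 nm stimulation onsets and averaged over
repetitions; averaging over many repetitions suppresses spontaneous bursts
that happen to fall in a peristimulus window. Samples masked in the
recording (detector saturation during the pulse) stay masked in the aligned
matrix, and means/SDs are computed over the unmasked entries only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .config import Compartment
from .errors import ParameterError
from .recording import LineScanRecording

logger = logging.getLogger(__name__)

#: pre-stimulus span over which the per-trial baseline is averaged (ms)
BASELINE_SPAN_MS = 200.0


@dataclass
class PeristimulusSet:
    """Stimulus-aligned ΔF/F segments for one compartment.

    ``matrix`` is (n_stimuli, n_samples) with NaN for masked entries;
    ``time_ms`` is relative to stimulus onset (negative = pre-stimulus).
    """

    window_pre_ms: float
    window_post_ms: float
    time_ms: np.ndarray
    matrix: np.ndarray
    stimulus_durations_ms: np.ndarray
    sampling_rate: float
    compartment: Optional[Compartment] = None

    def __post_init__(self) -> None:
        if self.matrix.ndim != 2 or self.matrix.shape[0] < 1:
            raise ParameterError("need at least one aligned stimulus")
        if self.matrix.shape[1] != len(self.time_ms):
            raise ParameterError("matrix width must match the time axis")

    @property
    def n_stimuli(self) -> int:
        return self.matrix.shape[0]

    @property
    def mean(self) -> np.ndarray:
        """Mean over unmasked entries per time point."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            return np.nanmean(self.matrix, axis=0)

    @property
    def sd(self) -> np.ndarray:
        """Standard deviation over unmasked entries per time point."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            return np.nanstd(self.matrix, axis=0)

    def baselines(self) -> np.ndarray:
        """Per-trial mean ΔF/F over the 200 ms pre-stimulus span."""
        sel = (self.time_ms >= -BASELINE_SPAN_MS) & (self.time_ms < 0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            base = np.nanmean(self.matrix[:, sel], axis=1)
        return np.where(np.isfinite(base), base, 0.0)

    def response_amplitudes(self, latency_window_ms: Optional[float] = None) -> np.ndarray:
        """Per-trial peak post-stimulus ΔF/F minus the pre-stimulus baseline.

        The peak is searched from stimulus onset to ``latency_window_ms``
        after the stimulus *end* (default: the whole post window).
        """
        if latency_window_ms is None:
            sel = self.time_ms >= 0
            post = np.broadcast_to(sel, self.matrix.shape)
        else:
            ends = self.stimulus_durations_ms[:, None] + latency_window_ms
            post = (self.time_ms[None, :] >= 0) & (self.time_ms[None, :] <= ends)
        vals = np.where(post & np.isfinite(self.matrix), self.matrix, -np.inf)
        peaks = vals.max(axis=1)
        peaks = np.where(np.isfinite(peaks), peaks, np.nan)
        return peaks - self.baselines()


def extract_peristimulus(
    dff: np.ndarray,
    recording: LineScanRecording,
    target_compartment: Optional[Compartment] = None,
    window_pre_ms: float = 1000.0,
    window_post_ms: float = 3000.0,
    response_compartment: Optional[Compartment] = None,
) -> PeristimulusSet:
    """Align a ΔF/F trace to the 470 nm stimulations of one compartment.

    One row per selected stimulation event; events whose window extends
    beyond the recording are skipped with a logged warning. The mask of the
    recording is carried into the rows.
    """
    dt = recording.sample_interval_ms
    n_pre = int(round(window_pre_ms / dt))
    n_post = int(round(window_post_ms / dt))
    events = recording.protocol.stimulations(target_compartment)
    if not events:
        raise ParameterError("no matching 470 nm stimulation events in the protocol")
    rows, durations = [], []
    n = len(dff)
    for ev in events:
        center = int(round(ev.onset / dt))
        lo, hi = center - n_pre, center + n_post
        if lo < 0 or hi > n:
            logger.warning(
                "skipping stimulation at %.1f ms: window [%d, %d) outside the recording",
                ev.onset, lo, hi,
            )
            continue
        rows.append(dff[lo:hi])
        durations.append(ev.duration)
    if not rows:
        raise ParameterError("no stimulation window fits inside the recording")
    return PeristimulusSet(
        window_pre_ms=window_pre_ms,
        window_post_ms=window_post_ms,
        time_ms=(np.arange(-n_pre, n_post) + 0.5) * dt,
        matrix=np.vstack(rows),
        stimulus_durations_ms=np.asarray(durations, dtype=float),
        sampling_rate=recording.sampling_rate,
        compartment=response_compartment,
    )


@dataclass
class EvokedScore:
    """Per-stimulus evoked flags and the overall success fraction."""

    flags: np.ndarray
    success_rate: float
    amplitudes: np.ndarray = field(repr=False, default=None)


def score_evoked(
    pset: PeristimulusSet,
    amplitude_threshold: float,
    latency_window_ms: float = 500.0,
) -> EvokedScore:
    """Score each stimulus as evoked-successful or not.

    A stimulus succeeds when the post-stimulus ΔF/F (relative to its 200 ms
    pre-stimulus baseline) exceeds ``amplitude_threshold`` within
    ``latency_window_ms`` of the stimulus end.
    """
    if latency_window_ms > pset.window_post_ms:
        raise ParameterError("latency window exceeds the post-stimulus window")
    amplitudes = pset.response_amplitudes(latency_window_ms)
    flags = np.where(np.isfinite(amplitudes), amplitudes > amplitude_threshold, False)
    return EvokedScore(
        flags=flags.astype(bool),
        success_rate=float(flags.mean()) if len(flags) else 0.0,
        amplitudes=amplitudes,
    )


def response_amplitude_curve(
    psets_by_duration: Mapping[float, PeristimulusSet],
    latency_window_ms: Optional[float] = None,
) -> pd.DataFrame:
    """Mean ± SD response amplitude as a function of stimulus duration."""
    durations = sorted(psets_by_duration)
    if len(set(durations)) != len(durations):
        raise ParameterError("stimulus durations must be distinct")
    rows = []
    for d in durations:
        amps = psets_by_duration[d].response_amplitudes(latency_window_ms)
        amps = amps[np.isfinite(amps)]
        rows.append(
            {
                "duration_ms": d,
                "mean_amplitude": float(np.mean(amps)) if amps.size else np.nan,
                "sd_amplitude": float(np.std(amps)) if amps.size else np.nan,
                "n": int(amps.size),
            }
        )
    return pd.DataFrame(rows)
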