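"""End-to-end analysis pipelines and canonical experiment scenarios."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .config import (
    SimulationConfig,
    StimulationProtocol,
    alternating_protocol,
    duration_series_protocol,
    imaging_protocol,
)
from .connectivity import ConnectivityReport, analyze_device
from .recording import LineScanRecording
from .simulate import simulate_experiment
from .traces import BurstEvent, bursting_rate, compute_dff, default_burst_threshold, detect_bursts

#: fraction of reverse axons relative to forward in an axon-diode device
DIODE_REVERSE_FRACTION = 0.03


def diode_config(base: Optional[SimulationConfig] = None, **overrides) -> SimulationConfig:
    """An axon-diode device: ~3% of the forward axon count in reverse."""
    base = base if base is not None else SimulationConfig()
    forward = overrides.pop("n_axons_forward", base.n_axons_forward)
    reverse = overrides.pop(
        "n_axons_reverse", max(1, round(DIODE_REVERSE_FRACTION * forward))
    )
    return base.model_copy(
        update={"n_axons_forward": forward, "n_axons_reverse": reverse, **overrides}
    )


@dataclass
class CompartmentAnalysis:
    dff: np.ndarray
    threshold_dff: float
    bursts: List[BurstEvent]
    rate_bpm: float


def analyze_recording(
    recording: LineScanRecording,
    threshold_dff: Optional[float] = None,
) -> Dict[str, CompartmentAnalysis]:
    """ΔF/F, burst detection and bursting rate for both compartments."""
    out: Dict[str, CompartmentAnalysis] = {}
    for comp in ("A", "B"):
        dff = compute_dff(recording, comp)
        thr = threshold_dff if threshold_dff is not None else default_burst_threshold(dff)
        bursts = detect_bursts(dff, recording.sampling_rate, thr)
        out[comp] = CompartmentAnalysis(
            dff=dff,
            threshold_dff=thr,
            bursts=bursts,
            rate_bpm=bursting_rate(bursts, recording.duration_min),
        )
    return out


def spontaneous_rate(
    config: SimulationConfig, duration_min: float = 10.0, seed: Optional[int] = None
) -> Tuple[float, List[BurstEvent]]:
    """Simulate an unstimulated, isolated culture and measure its bursting rate.

    Models a single-well culture (the setting in which reference bursting
    rates are measured): inter-compartment coupling is removed so the rate
    reflects one population's spontaneous dynamics only. The rate is
    measured on compartment A through the full pipeline (rendering, ΔF/F,
    burst detection).
    """
    config = config.model_copy(update={"n_axons_forward": 0, "n_axons_reverse": 0})
    _, rec = simulate_experiment(
        config, StimulationProtocol(), duration_ms=duration_min * 60_000.0, seed=seed
    )
    analysis = analyze_recording(rec)["A"]
    return analysis.rate_bpm, analysis.bursts


def device_connectivity(
    recording: LineScanRecording,
    amplitude_threshold: Optional[float] = None,
    max_lag_ms: float = 50.0,
    window_post_ms: float = 3000.0,
) -> ConnectivityReport:
    """Directional connectivity report of one alternating-stimulation recording."""
    dff = {c: compute_dff(recording, c) for c in ("A", "B")}
    if amplitude_threshold is None:
        amplitude_threshold = max(
            default_burst_threshold(dff["A"]), default_burst_threshold(dff["B"])
        )
    return analyze_device(
        dff["A"],
        dff["B"],
        recording,
        amplitude_threshold=amplitude_threshold,
        max_lag_ms=max_lag_ms,
        window_post_ms=window_post_ms,
    )


def run_connectivity_experiment(
    config: SimulationConfig,
    n_per_side: int = 30,
    period_ms: float = 10_000.0,
    pulse_ms: float = 5.0,
    seed: Optional[int] = None,
) -> Tuple[LineScanRecording, ConnectivityReport]:
    """Simulate an alternating-stimulation experiment and analyze it."""
    protocol = alternating_protocol(n_per_side=n_per_side, period_ms=period_ms, pulse_ms=pulse_ms)
    duration = protocol.end + 5_000.0
    _, rec = simulate_experiment(config, protocol, duration_ms=duration, seed=seed)
    return rec, device_connectivity(rec)


# ---------------------------------------------------------------------------
# packaged example scenarios (regenerated by `optoburst fixtures`)
# ---------------------------------------------------------------------------

def fixture_scenarios(scale: float = 1.0) -> Dict[str, Tuple[SimulationConfig, StimulationProtocol, float]]:
    """The canonical example scenarios: (config, protocol, duration_ms).

    ``scale`` < 1 shrinks repetition counts/durations proportionally (the
    designs are otherwise at the study conditions).
    """
    n_alt = max(2, round(30 * scale))
    base = SimulationConfig()
    scenarios: Dict[str, Tuple[SimulationConfig, StimulationProtocol, float]] = {}

    # imaging-intensity series (1x / 2x / 4x 549 nm light, no crosstalk)
    minutes = max(1.0, 10.0 * scale)
    for intensity in (1, 2, 4):
        dur = minutes * 60_000.0
        scenarios[f"intensity_{intensity}x"] = (
            base,
            imaging_protocol(float(intensity), dur),
            dur,
        )

    # stimulus-duration series, with and without saturating CNQX
    durations = (1, 2, 4, 8, 16, 32, 64, 128, 256, 512, 1024)
    proto = duration_series_protocol(durations)
    for label, cnqx in (("duration_series", 0.0), ("duration_series_cnqx10", 10.0)):
        scenarios[label] = (
            base.model_copy(update={"cnqx_concentration": cnqx}),
            proto,
            proto.end + 5_000.0,
        )

    # one-sided transduction, straight channels (propagation design)
    proto = alternating_protocol(n_per_side=n_alt)
    scenarios["one_sided_straight"] = (
        base.model_copy(update={"transduced_compartments": "A"}),
        proto,
        proto.end + 5_000.0,
    )

    # straight vs diode, both sides transduced
    scenarios["straight_device"] = (base, proto, proto.end + 5_000.0)
    scenarios["diode_device"] = (diode_config(base), proto, proto.end + 5_000.0)
    scenarios["diode_device_cnqx5"] = (
        diode_config(base, cnqx_concentration=5.0),
        proto,
        proto.end + 5_000.0,
    )
    return scenarios
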