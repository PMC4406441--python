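"""Synthetic two-compartment optogenetics experiment.

The simulator reproduces the structure of a compartmentalized-culture
experiment: two neuronal populations connected through a bundle of axons
(symmetric counts for straight micro-channels, strongly asymmetric counts
for axon-diodes), ChR2 photo-activation of transduced excitatory neurons by
470 nm pulses, quorum-percolation burst ignition, CNQX block of excitatory
synapses, calcium-indicator read-out and line-scan acquisition with
saturation masking during stimulation.

Model of within-burst firing
----------------------------
Once recruited into a network burst, a neuron fires an initial high-rate
volley (``burst_volley_ms``) and then keeps firing at
``burst_sustain_level`` of the volley rate for
``burst_firing_duration_ms`` (default 1.5 s). The volley gives the
fluorescence transient its sharp onset — which carries the
inter-compartment timing information — while the sustained tail holds the
signal at a recruitment-determined plateau independent of the stimulus
duration (long stimulations hide the onset behind the saturation mask but
not the plateau). When percolation fails (saturating CNQX), only the
directly photo-activated neurons fire, and they keep firing while the light
is on (plus a short tail), so the response grows with both the activated
count and the pulse duration. The calcium drive is the active excitatory
fraction minus ``inhibition_strength`` times the active inhibitory fraction
(floored at zero): with synapses blocked the inhibitory population is
silent, which dis-inhibits the direct response.
"""

from __future__ import annotations

import heapq
import math
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.signal import fftconvolve

from .config import (
    Compartment,
    SimulationConfig,
    StimulationProtocol,
    StimulusEvent,
    config_hash,
)
from .errors import ParameterError, ProtocolError
from .network import QuorumNetwork
from .recording import GroundTruthBurst, LineScanRecording, PopulationActivity

_OTHER: Dict[Compartment, Compartment] = {"A": "B", "B": "A"}

#: dead time (ms) for cross-compartment synaptic seeding after a full burst
#: in the target: suppresses the immediate A->B->A echo (which arrives within
#: a few ms, while the target population is still firing its onset volley)
#: without blocking genuine re-ignition hundreds of ms later — stimulation
#: and afferent bursts override the slow post-burst refractory period.
ECHO_DEAD_TIME_MS = 100.0


# ---------------------------------------------------------------------------
# optics
# ---------------------------------------------------------------------------

def compute_spot_diameter(fiber_diameter: float, distance: float, half_angle: float) -> float:
    """Diameter (mm) of the light spot from a fiber above the sample.

    The cone widens from the fiber face with the fiber's acceptance
    half-angle: ``fiber_diameter + 2 * distance * tan(half_angle)``.

    Parameters are the fiber core diameter (mm), the fiber-to-sample
    distance (mm) and the acceptance half-angle (degrees, < 90).
    """
    if fiber_diameter < 0 or distance < 0 or half_angle < 0:
        raise ParameterError("fiber_diameter, distance and half_angle must be >= 0")
    if half_angle >= 90.0:
        raise ParameterError("half_angle must be below 90 degrees")
    return fiber_diameter + 2.0 * distance * math.tan(math.radians(half_angle))


# ---------------------------------------------------------------------------
# photo-activation
# ---------------------------------------------------------------------------

def _activation_probability(pulse: StimulusEvent, config: SimulationConfig) -> float:
    if pulse.role == "stimulation_470":
        rate = config.photoactivation_rate * pulse.intensity
    elif pulse.role == "imaging_549":
        rate = config.crosstalk_549_activation * pulse.intensity
    else:  # pragma: no cover - pydantic enforces the literal
        raise ProtocolError(f"unknown stimulus role {pulse.role!r}")
    return 1.0 - math.exp(-rate * pulse.duration)


def photo_activate(
    pulse: StimulusEvent, config: SimulationConfig, rng: np.random.Generator
) -> int:
    """Number of neurons directly activated by one light pulse.

    Drawn as Binomial(n_transduced, 1 - exp(-rate * duration * intensity)).
    Only ChR2-transduced (excitatory) neurons of the target compartment are
    eligible; 549 nm imaging light acts through the (default zero)
    crosstalk rate instead of the ChR2 activation rate.
    """
    n_eligible = config.n_transduced(pulse.target_compartment)
    return int(rng.binomial(n_eligible, _activation_probability(pulse, config)))


def _draw_photoactivation_times(
    pulse: StimulusEvent,
    config: SimulationConfig,
    network: QuorumNetwork,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray]:
    """Directly activated neuron indices and their activation times (ms).

    Activation times within the pulse follow the first-success time of the
    exponential photo-activation process, truncated at the pulse duration.
    """
    n_act = photo_activate(pulse, config, rng)
    if n_act == 0:
        return np.array([], dtype=int), np.array([])
    exc = network.excitatory_indices()
    n_eligible = config.n_transduced(pulse.target_compartment)
    eligible = exc[:n_eligible]  # transduced subset of the excitatory pool
    neurons = rng.choice(eligible, size=min(n_act, len(eligible)), replace=False)
    rate = (
        config.photoactivation_rate
        if pulse.role == "stimulation_470"
        else config.crosstalk_549_activation
    ) * pulse.intensity
    if rate <= 0:
        times = np.zeros(len(neurons))
    else:
        # inverse-CDF of Exp(rate) truncated to [0, duration]
        u = rng.random(len(neurons))
        cap = 1.0 - math.exp(-rate * pulse.duration)
        times = -np.log1p(-u * cap) / rate
    return neurons, pulse.onset + times


# ---------------------------------------------------------------------------
# experiment simulation
# ---------------------------------------------------------------------------

def _spontaneous_times(
    config: SimulationConfig, duration_ms: float, rng: np.random.Generator
) -> np.ndarray:
    """Spontaneous ignition attempt times: Poisson with dead time.

    The exponential hazard is compensated for the refractory period so the
    realized mean rate matches ``spontaneous_burst_rate``.
    """
    if config.spontaneous_burst_rate <= 0:
        return np.array([])
    mean_ibi = 60_000.0 / config.spontaneous_burst_rate
    mean_exp = max(1.0, mean_ibi - config.refractory_ms)
    times = []
    t = rng.exponential(mean_exp)
    while t < duration_ms:
        times.append(t)
        t += config.refractory_ms + rng.exponential(mean_exp)
    return np.asarray(times)


class _DriveAccumulator:
    """Accumulates weighted firing intervals into per-ms activity counts.

    Firing within a burst is front-loaded: each neuron contributes a
    high-rate initial volley (weight 1 for ``burst_volley_ms``) followed by
    sustained reverberation at ``burst_sustain_level`` until its firing
    window ends. The volley gives bursts their sharp fluorescence onset;
    the sustained tail keeps the signal elevated for the burst duration.
    """

    def __init__(self, n_ms: int, inhibitory: np.ndarray, config: SimulationConfig):
        self.n_ms = n_ms
        self.inhibitory = inhibitory
        self.volley_ms = config.burst_volley_ms
        self.sustain = config.burst_sustain_level
        self.direct_level = config.direct_drive_level
        self._diff_exc = np.zeros(n_ms + 1)
        self._diff_inh = np.zeros(n_ms + 1)

    def _add_interval(self, n_exc: int, n_inh: int, start_ms: float, end_ms: float,
                      weight: float) -> None:
        a = int(np.clip(round(start_ms), 0, self.n_ms))
        b = int(np.clip(round(end_ms), 0, self.n_ms))
        if b <= a or weight == 0.0:
            return
        self._diff_exc[a] += weight * n_exc
        self._diff_exc[b] -= weight * n_exc
        self._diff_inh[a] += weight * n_inh
        self._diff_inh[b] -= weight * n_inh

    def add(
        self, neurons: np.ndarray, start_ms: float, end_ms: float, profile: str = "burst"
    ) -> None:
        if len(neurons) == 0:
            return
        n_inh = int(self.inhibitory[neurons].sum())
        n_exc = len(neurons) - n_inh
        if profile == "burst":
            volley_end = min(end_ms, start_ms + self.volley_ms)
            self._add_interval(n_exc, n_inh, start_ms, volley_end, 1.0 - self.sustain)
            self._add_interval(n_exc, n_inh, start_ms, end_ms, self.sustain)
        else:  # tonic light-driven firing without network reverberation
            self._add_interval(n_exc, n_inh, start_ms, end_ms, self.direct_level)

    def counts(self) -> Tuple[np.ndarray, np.ndarray]:
        return (
            np.cumsum(self._diff_exc[:-1]),
            np.cumsum(self._diff_inh[:-1]),
        )


def simulate_experiment(
    config: SimulationConfig,
    protocol: StimulationProtocol,
    duration_ms: float,
    seed: Optional[int] = None,
) -> Tuple[PopulationActivity, LineScanRecording]:
    """Simulate the experiment and render the line-scan read-out.

    Spontaneous bursts arise per compartment as a dead-time Poisson process;
    each 470 nm pulse photo-activates transduced neurons and attempts a
    quorum ignition (stimulation overrides the spontaneous refractory
    period); a full burst seeds the opposite compartment through the
    afferent axon bundle, with the transmission delay emerging from the
    receiving side's recruitment steps (1 ms per synaptic integration step —
    fewer afferent axons, more steps, longer delay).

    Returns the ground-truth :class:`PopulationActivity` and the rendered
    :class:`LineScanRecording`.
    """
    if protocol.end > duration_ms:
        raise ProtocolError(
            f"protocol extends to {protocol.end} ms beyond the {duration_ms} ms simulation"
        )
    seed = config.seed if seed is None else seed
    # independent sub-streams so that e.g. coupling parameters do not perturb
    # the spontaneous event series of either compartment
    streams = np.random.SeedSequence(seed).spawn(6)
    rng_graph = {"A": np.random.default_rng(streams[0]), "B": np.random.default_rng(streams[1])}
    rng_spont = {"A": np.random.default_rng(streams[2]), "B": np.random.default_rng(streams[3])}
    rng_evoked = np.random.default_rng(streams[4])
    rng_noise = np.random.default_rng(streams[5])

    networks = {c: QuorumNetwork.from_config(config, rng_graph[c]) for c in ("A", "B")}
    n_ms = int(round(duration_ms))
    drives = {c: _DriveAccumulator(n_ms, networks[c].inhibitory, config) for c in ("A", "B")}
    mult = config.cnqx_efficacy_multiplier
    bursts: List[GroundTruthBurst] = []
    last_full_burst = {"A": -math.inf, "B": -math.inf}

    # event queue: (time, tiebreak, kind, compartment, payload)
    queue: list = []
    counter = 0

    def push(t: float, kind: str, comp: Compartment, payload) -> None:
        nonlocal counter
        heapq.heappush(queue, (t, counter, kind, comp, payload))
        counter += 1

    for comp in ("A", "B"):
        for t in _spontaneous_times(config, duration_ms, rng_spont[comp]):
            push(float(t), "spontaneous", comp, None)
    for ev in protocol.events:
        push(ev.onset, "pulse", ev.target_compartment, ev)

    def run_ignition(
        comp: Compartment, t: float, seed_neurons: np.ndarray, origin: str,
        direct_times: Optional[np.ndarray] = None, pulse_end: Optional[float] = None,
    ) -> None:
        net = networks[comp]
        result = net.ignite(seed_neurons, mult)
        if result.recruited_fraction == 0:
            return
        bursts.append(
            GroundTruthBurst(
                compartment=comp,
                ignition_time_ms=t,
                recruited_fraction=result.recruited_fraction,
                origin=origin,
                ignition_delay_steps=result.ignition_delay_steps,
            )
        )
        # synaptic recruitment beyond the seed set distinguishes a network
        # burst (reverberating volley + sustained firing) from the purely
        # light-driven tonic response seen when transmission is blocked
        percolated = len(result.recruited_per_step) > 1
        if percolated:
            # every recruited neuron fires for the burst duration from its
            # recruitment step
            for step, neurons in enumerate(result.recruited_per_step):
                drives[comp].add(neurons, t + step, t + step + config.burst_firing_duration_ms)
            if result.is_full_burst:
                last_full_burst[comp] = t
                # seed the opposite compartment through its afferent axons
                # once this burst is fully ignited
                n_axons = config.n_axons_forward if comp == "A" else config.n_axons_reverse
                k = int(round(n_axons * result.recruited_fraction * mult))
                if k > 0:
                    push(t + result.ignition_delay_steps, "synaptic", _OTHER[comp], k)
        else:
            # no percolation: tonic direct drive only, sustained while light is on
            if direct_times is not None and len(direct_times):
                end = (pulse_end if pulse_end is not None else t) + config.direct_drive_tail_ms
                for ms in np.unique(np.floor(direct_times)):
                    sel = np.floor(direct_times) == ms
                    drives[comp].add(seed_neurons[sel], float(ms), end, profile="direct")
            else:
                drives[comp].add(
                    np.asarray(seed_neurons), t, t + config.direct_drive_tail_ms,
                    profile="direct",
                )

    while queue:
        t, _, kind, comp, payload = heapq.heappop(queue)
        net = networks[comp]
        if kind == "spontaneous":
            # spontaneous ignition respects the post-burst refractory period
            if t - last_full_burst[comp] < config.refractory_ms:
                continue
            k = min(config.spontaneous_seed_count, net.n_neurons)
            exc = net.excitatory_indices()
            seeds = rng_spont[comp].choice(exc, size=min(k, len(exc)), replace=False)
            run_ignition(comp, t, seeds, "spontaneous")
        elif kind == "pulse":
            neurons, times = _draw_photoactivation_times(payload, config, net, rng_evoked)
            if len(neurons) == 0:
                continue
            # evoked ignition bypasses the refractory period
            run_ignition(comp, t, neurons, "direct_photo", times, payload.end)
        elif kind == "synaptic":
            # ignore seeds echoing back while the target fires its own volley
            if t - last_full_burst[comp] < ECHO_DEAD_TIME_MS:
                continue
            seeds = rng_evoked.choice(net.n_neurons, size=min(payload, net.n_neurons), replace=False)
            run_ignition(comp, t, seeds, "synaptic_from_other_compartment")

    fraction: Dict[Compartment, np.ndarray] = {}
    drive: Dict[Compartment, np.ndarray] = {}
    for comp in ("A", "B"):
        exc, inh = drives[comp].counts()
        n = networks[comp].n_neurons
        # clip away accumulated floating-point residue from the diff/cumsum
        fraction[comp] = np.clip((exc + inh) / n, 0.0, 1.0)
        drive[comp] = np.maximum(exc - config.inhibition_strength * inh, 0.0) / n

    activity = PopulationActivity(
        time_ms=np.arange(n_ms, dtype=float),
        fraction_active=fraction,
        calcium_drive=drive,
        bursts=sorted(bursts, key=lambda b: b.ignition_time_ms),
    )
    recording = render_line_scan(activity, config, protocol, rng=rng_noise)
    return activity, recording


# ---------------------------------------------------------------------------
# line-scan rendering
# ---------------------------------------------------------------------------

def _calcium_kernel(config: SimulationConfig, dt_ms: float) -> np.ndarray:
    """Dual-exponential indicator kernel, normalized to unit steady-state gain."""
    t_max = 6.0 * config.ca_decay_tau
    t = np.arange(0.0, t_max, dt_ms)
    k = np.exp(-t / config.ca_decay_tau) - np.exp(-t / config.ca_rise_tau)
    s = k.sum()
    return k / s if s > 0 else k


def render_line_scan(
    activity: PopulationActivity,
    config: SimulationConfig,
    protocol: Optional[StimulationProtocol] = None,
    rng: Optional[np.random.Generator] = None,
) -> LineScanRecording:
    """Render ground-truth activity as a noisy, masked line-scan recording.

    The calcium drive is convolved with the indicator kernel at the line
    rate, scaled to fluorescence (baseline + amplitude x drive, where a
    sustained unit drive asymptotes at ``ca_amplitude`` above baseline),
    Gaussian noise is added per line, and ``cycles_per_sample`` consecutive
    lines are integrated per output sample. Output samples whose
    integration window overlaps a 470 nm pulse on either compartment are
    masked (the detector saturates during stimulation).
    """
    protocol = protocol if protocol is not None else StimulationProtocol()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    duration_ms = len(activity.time_ms)
    line_dt = 1000.0 / config.line_rate
    n_lines = int(duration_ms / line_dt)
    n_samples = n_lines // config.cycles_per_sample
    n_lines = n_samples * config.cycles_per_sample
    kernel = _calcium_kernel(config, line_dt)

    line_idx = np.minimum(
        (np.arange(n_lines) * line_dt).astype(int), duration_ms - 1
    )
    traces = {}
    for comp in ("A", "B"):
        drive_lines = activity.calcium_drive[comp][line_idx]
        f = config.baseline_F + config.ca_amplitude * fftconvolve(drive_lines, kernel)[:n_lines]
        if config.noise_sigma > 0:
            f = f + rng.normal(0.0, config.noise_sigma, size=n_lines)
        traces[comp] = f.reshape(n_samples, config.cycles_per_sample).mean(axis=1)

    sample_dt = line_dt * config.cycles_per_sample
    starts = np.arange(n_samples) * sample_dt
    ends = starts + sample_dt
    mask = np.zeros(n_samples, dtype=bool)
    for ev in protocol.events:
        if ev.role == "stimulation_470":
            mask |= (starts < ev.end) & (ends > ev.onset)

    return LineScanRecording(
        sampling_rate=config.sampling_rate,
        time_ms=starts + sample_dt / 2.0,
        trace_A=traces["A"],
        trace_B=traces["B"],
        mask_A=mask.copy(),
        mask_B=mask.copy(),
        protocol=protocol,
        provenance={"source": "simulated", "config_hash": config_hash(config)},
    )
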