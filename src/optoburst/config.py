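"""Configuration and stimulation-protocol types.

The simulator is parameterised by a single :class:`SimulationConfig` holding
the biological, optical and acquisition parameters of a two-compartment
("A" and "B") micro-fluidic culture experiment, and by a
:class:`StimulationProtocol`, an ordered list of timed light pulses.

Both are pydantic models so that JSON documents round-trip with validation;
``config_hash`` gives a stable provenance fingerprint.
"""

from __future__ import annotations

import hashlib
import json
from typing import List, Literal, Optional

from pydantic import BaseModel, Field, model_validator

Compartment = Literal["A", "B"]

#: concentration of CNQX (µM) treated as fully saturating: excitatory
#: synaptic transmission completely blocked.
CNQX_SATURATING_UM = 10.0


class SimulationConfig(BaseModel):
    """All parameters of the synthetic two-compartment experiment.

    Each compartment holds ``n_neurons_per_compartment`` neurons, of which
    ``inhibitory_fraction`` are inhibitory; ChR2 is expressed in
    ``transduced_fraction`` of the *excitatory* neurons only (inhibitory
    neurons are never transduced). Network bursts ignite by quorum
    percolation on a sparse random synaptic graph; compartments are coupled
    by a fixed number of axons per direction. Activity is read out through
    a calcium-indicator kernel sampled as a confocal line scan.
    """

    # --- populations -----------------------------------------------------
    n_neurons_per_compartment: int = Field(default=2000, ge=1)
    inhibitory_fraction: float = Field(default=0.15, ge=0.0, le=1.0)
    transduced_fraction: float = Field(default=0.70, ge=0.0, le=1.0)
    #: which compartments carry ChR2-expressing neurons
    transduced_compartments: Literal["both", "A", "B", "none"] = "both"

    # --- quorum percolation ----------------------------------------------
    quorum_threshold: float = Field(default=2.0, gt=0.0)
    mean_in_degree: float = Field(default=50.0, ge=0.0)
    synaptic_efficacy: float = Field(default=1.0, ge=0.0)
    cnqx_concentration: float = Field(default=0.0, ge=0.0)  # µM
    spontaneous_seed_count: int = Field(default=20, ge=0)

    # --- inter-compartment coupling --------------------------------------
    n_axons_forward: int = Field(default=100, ge=0)  # A -> B
    n_axons_reverse: int = Field(default=100, ge=0)  # B -> A

    # --- optogenetics ----------------------------------------------------
    photoactivation_rate: float = Field(default=0.05, ge=0.0)  # 1/ms at 1x
    crosstalk_549_activation: float = Field(default=0.0, ge=0.0)

    # --- burst dynamics ---------------------------------------------------
    spontaneous_burst_rate: float = Field(default=5.9, ge=0.0)  # bursts/min
    refractory_ms: float = Field(default=3000.0, ge=0.0)
    burst_firing_duration_ms: float = Field(default=1500.0, gt=0.0)
    #: initial high-rate population volley at burst onset (per neuron)
    burst_volley_ms: float = Field(default=30.0, ge=0.0)
    #: reverberation firing rate after the volley, relative to the volley rate
    burst_sustain_level: float = Field(default=0.06, ge=0.0, le=1.0)
    #: tonic ChR2-driven firing rate (relative to the volley rate) of
    #: directly photo-activated neurons when percolation fails (CNQX)
    direct_drive_level: float = Field(default=0.075, ge=0.0, le=1.0)
    direct_drive_tail_ms: float = Field(default=100.0, ge=0.0)
    inhibition_strength: float = Field(default=2.5, ge=0.0)

    # --- calcium indicator and read-out -----------------------------------
    ca_rise_tau: float = Field(default=10.0, gt=0.0)  # ms
    ca_decay_tau: float = Field(default=500.0, gt=0.0)  # ms
    #: fluorescence units per unit of sustained population drive; the default
    #: makes a full network burst peak at ΔF/F ~ 0.2 over the default baseline
    ca_amplitude: float = Field(default=700.0, ge=0.0)
    baseline_F: float = Field(default=100.0, gt=0.0)
    noise_sigma: float = Field(default=2.0, ge=0.0)  # F units per line
    line_rate: float = Field(default=8000.0, gt=0.0)  # Hz
    cycles_per_sample: int = Field(default=8, ge=1)

    seed: int = 0

    @model_validator(mode="after")
    def _check_kinetics(self) -> "SimulationConfig":
        if self.ca_rise_tau >= self.ca_decay_tau:
            raise ValueError("ca_rise_tau must be smaller than ca_decay_tau")
        return self

    # ------------------------------------------------------------------
    @property
    def sampling_rate(self) -> float:
        """Effective read-out rate in Hz (line rate / integration cycles)."""
        return self.line_rate / self.cycles_per_sample

    @property
    def cnqx_efficacy_multiplier(self) -> float:
        """Synaptic efficacy multiplier under CNQX.

        Linear block: 0 µM -> 1 (untouched), ``CNQX_SATURATING_UM`` and
        above -> 0 (fully blocked), 5 µM (under-saturating) -> 0.5.
        """
        return max(0.0, 1.0 - self.cnqx_concentration / CNQX_SATURATING_UM)

    def is_transduced(self, compartment: Compartment) -> bool:
        return self.transduced_compartments in ("both", compartment)

    def n_transduced(self, compartment: Compartment) -> int:
        """Number of ChR2-positive (always excitatory) neurons."""
        if not self.is_transduced(compartment):
            return 0
        n_exc = round(self.n_neurons_per_compartment * (1 - self.inhibitory_fraction))
        return round(n_exc * self.transduced_fraction)


class StimulusEvent(BaseModel):
    """A single timed light pulse."""

    onset: float = Field(ge=0.0)  # ms
    duration: float = Field(gt=0.0)  # ms
    target_compartment: Compartment
    role: Literal["stimulation_470", "imaging_549"] = "stimulation_470"
    intensity: float = Field(default=1.0, gt=0.0)  # relative to 1x

    @property
    def end(self) -> float:
        return self.onset + self.duration


class StimulationProtocol(BaseModel):
    """Ordered list of light pulses applied to the device."""

    events: List[StimulusEvent] = Field(default_factory=list)

    @model_validator(mode="after")
    def _check_events(self) -> "StimulationProtocol":
        ev = self.events
        if any(ev[i].onset > ev[i + 1].onset for i in range(len(ev) - 1)):
            raise ValueError("events must be sorted by onset")
        for comp in ("A", "B"):
            blue = [e for e in ev if e.role == "stimulation_470" and e.target_compartment == comp]
            for a, b in zip(blue, blue[1:]):
                if b.onset < a.end:
                    raise ValueError(
                        f"overlapping 470 nm events on compartment {comp} at {b.onset} ms"
                    )
        return self

    @property
    def end(self) -> float:
        """Time (ms) at which the last event finishes."""
        return max((e.end for e in self.events), default=0.0)

    def stimulations(self, compartment: Optional[Compartment] = None) -> List[StimulusEvent]:
        """The 470 nm events, optionally filtered by target compartment."""
        return [
            e
            for e in self.events
            if e.role == "stimulation_470"
            and (compartment is None or e.target_compartment == compartment)
        ]


# ---------------------------------------------------------------------------
# protocol builders for the canonical experimental designs
# ---------------------------------------------------------------------------

def alternating_protocol(
    n_per_side: int = 30,
    period_ms: float = 10_000.0,
    pulse_ms: float = 5.0,
    start_ms: float = 5_000.0,
    first: Compartment = "A",
) -> StimulationProtocol:
    """One stimulation every ``period_ms`` with the target side alternating.

    The default reproduces the propagation design: 30 stimulations per side
    at 0.1 Hz in alternation, 5 ms pulses.
    """
    other: Compartment = "B" if first == "A" else "A"
    events = [
        StimulusEvent(
            onset=start_ms + i * period_ms,
            duration=pulse_ms,
            target_compartment=first if i % 2 == 0 else other,
        )
        for i in range(2 * n_per_side)
    ]
    return StimulationProtocol(events=events)


def duration_series_protocol(
    durations_ms=(1, 2, 4, 8, 16, 32, 64, 128, 256, 512, 1024),
    spacing_ms: float = 5_000.0,
    target: Compartment = "A",
    start_ms: float = 5_000.0,
) -> StimulationProtocol:
    """Stimulus-duration series: one pulse of each duration every 5 s."""
    events = [
        StimulusEvent(onset=start_ms + i * spacing_ms, duration=float(d), target_compartment=target)
        for i, d in enumerate(durations_ms)
    ]
    return StimulationProtocol(events=events)


def imaging_protocol(
    intensity: float, duration_ms: float, compartment: Compartment = "A"
) -> StimulationProtocol:
    """Continuous 549 nm imaging illumination at a relative intensity."""
    return StimulationProtocol(
        events=[
            StimulusEvent(
                onset=0.0,
                duration=duration_ms,
                target_compartment=compartment,
                role="imaging_549",
                intensity=intensity,
            )
        ]
    )


def config_hash(config: SimulationConfig) -> str:
    """Stable SHA-256 fingerprint of a configuration (provenance tag)."""
    payload = json.dumps(config.model_dump(), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
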