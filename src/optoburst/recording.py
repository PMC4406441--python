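"""In-memory containers for simulated activity and line-scan recordings."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Literal

import numpy as np

from .config import Compartment, StimulationProtocol

BurstOrigin = Literal["spontaneous", "direct_photo", "synaptic_from_other_compartment"]


@dataclass
class GroundTruthBurst:
    """One ignition event of the synthetic culture, with its provenance."""

    compartment: Compartment
    ignition_time_ms: float
    recruited_fraction: float
    origin: BurstOrigin
    ignition_delay_steps: int = 0

    @property
    def is_full_burst(self) -> bool:
        from .network import FULL_BURST_FRACTION

        return self.recruited_fraction >= FULL_BURST_FRACTION


@dataclass
class PopulationActivity:
    """Ground-truth activity of both compartments at 1 ms resolution.

    ``fraction_active[c]`` is the fraction of neurons of compartment ``c``
    firing in each millisecond; ``calcium_drive[c]`` is the net drive of the
    calcium signal (excitatory minus weighted inhibitory activity, floored
    at zero) used by the renderer.
    """

    time_ms: np.ndarray
    fraction_active: Dict[Compartment, np.ndarray]
    calcium_drive: Dict[Compartment, np.ndarray]
    bursts: List[GroundTruthBurst] = field(default_factory=list)

    def bursts_in(
        self, compartment: Compartment, full_only: bool = False
    ) -> List[GroundTruthBurst]:
        return [
            b
            for b in self.bursts
            if b.compartment == compartment and (b.is_full_burst or not full_only)
        ]


@dataclass
class LineScanRecording:
    """Two-compartment fluorescence read-out at the effective sampling rate.

    Masked (saturated) samples are NaN in the traces and True in the masks.
    """

    sampling_rate: float  # Hz
    time_ms: np.ndarray
    trace_A: np.ndarray
    trace_B: np.ndarray
    mask_A: np.ndarray
    mask_B: np.ndarray
    protocol: StimulationProtocol
    provenance: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.time_ms)
        for name in ("trace_A", "trace_B", "mask_A", "mask_B"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length differs from the time axis")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        # invariant: masked samples carry no finite fluorescence value
        self.trace_A = np.where(self.mask_A, np.nan, self.trace_A)
        self.trace_B = np.where(self.mask_B, np.nan, self.trace_B)

    @property
    def sample_interval_ms(self) -> float:
        return 1000.0 / self.sampling_rate

    @property
    def duration_min(self) -> float:
        return len(self.time_ms) * self.sample_interval_ms / 60_000.0

    def trace(self, compartment: Compartment) -> np.ndarray:
        return self.trace_A if compartment == "A" else self.trace_B

    def mask(self, compartment: Compartment) -> np.ndarray:
        return self.mask_A if compartment == "A" else self.mask_B
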