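"""Quorum-percolation model of network-burst ignition.

A compartment is a directed synaptic graph over ``N`` neurons. A neuron
activates when the number of its *active excitatory* presynaptic inputs,
weighted by ``synaptic_efficacy`` times the CNQX efficacy multiplier,
reaches the quorum threshold. Updates are synchronous in discrete steps
(one step per synaptic integration interval, 1 ms in the simulator); once
active, a neuron stays active for the remainder of the ignition. A large
enough seed therefore percolates to (nearly) the whole population, while a
sub-critical seed stalls at a small active set — the mechanism behind
all-or-none network bursts and their ignition delays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .config import SimulationConfig

#: fraction of the final recruited count at which the ignition delay is read
DELAY_FRACTION = 0.95

#: recruited fraction above which an ignition counts as a full network burst
FULL_BURST_FRACTION = 0.3


@dataclass
class IgnitionResult:
    """Outcome of one quorum ignition."""

    recruited_fraction: float
    #: synchronous steps until the active count first reaches 95% of its
    #: final value (0 when the seed alone already does)
    ignition_delay_steps: int
    #: newly recruited neuron indices per step; entry 0 is the seed set
    recruited_per_step: list = field(repr=False, default_factory=list)

    @property
    def is_full_burst(self) -> bool:
        return self.recruited_fraction >= FULL_BURST_FRACTION


class QuorumNetwork:
    """Directed synaptic graph of one compartment with quorum dynamics.

    Parameters
    ----------
    adjacency:
        ``(N, N)`` matrix, ``adjacency[j, i] != 0`` meaning a synapse from
        neuron ``j`` onto neuron ``i``. Dense or scipy sparse.
    inhibitory:
        boolean mask of inhibitory neurons. Their activity never counts
        toward the recruitment quorum (inhibition shapes the calcium
        response amplitude, not ignition).
    quorum_threshold, synaptic_efficacy:
        a neuron activates when
        ``efficacy * efficacy_multiplier * n_active_excitatory_inputs >=
        quorum_threshold``.
    """

    def __init__(
        self,
        adjacency,
        inhibitory: np.ndarray,
        quorum_threshold: float,
        synaptic_efficacy: float = 1.0,
    ):
        adjacency = sparse.csr_matrix(adjacency, dtype=np.float64)
        if adjacency.shape[0] != adjacency.shape[1]:
            raise ValueError("adjacency must be square")
        self.adjacency = adjacency
        self.inhibitory = np.asarray(inhibitory, dtype=bool)
        if self.inhibitory.shape != (adjacency.shape[0],):
            raise ValueError("inhibitory mask length must match adjacency")
        if quorum_threshold <= 0:
            raise ValueError("quorum_threshold must be positive")
        self.quorum_threshold = float(quorum_threshold)
        self.synaptic_efficacy = float(synaptic_efficacy)
        # inputs from inhibitory neurons never count toward the quorum
        self._adj_exc = sparse.csr_matrix(
            adjacency.multiply((~self.inhibitory)[:, None])
        )

    # ------------------------------------------------------------------
    @classmethod
    def from_config(cls, config: SimulationConfig, rng: np.random.Generator) -> "QuorumNetwork":
        """Random directed Erdős–Rényi graph at the configured in-degree."""
        n = config.n_neurons_per_compartment
        p = min(1.0, config.mean_in_degree / max(1, n - 1))
        dense = rng.random((n, n)) < p
        np.fill_diagonal(dense, False)
        n_inh = round(n * config.inhibitory_fraction)
        inhibitory = np.zeros(n, dtype=bool)
        if n_inh:
            inhibitory[rng.choice(n, size=n_inh, replace=False)] = True
        return cls(
            sparse.csr_matrix(dense, dtype=np.float64),
            inhibitory,
            config.quorum_threshold,
            config.synaptic_efficacy,
        )

    @property
    def n_neurons(self) -> int:
        return self.adjacency.shape[0]

    def excitatory_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.inhibitory)

    # ------------------------------------------------------------------
    def ignite(self, seed_active: np.ndarray, efficacy_multiplier: float = 1.0) -> IgnitionResult:
        """Run synchronous quorum recruitment from an explicit seed set.

        Parameters
        ----------
        seed_active:
            boolean mask or integer index array of initially active neurons.
        efficacy_multiplier:
            CNQX block factor in [0, 1]; 0 disables all synaptic recruitment.
        """
        n = self.n_neurons
        active = np.zeros(n, dtype=bool)
        seed_active = np.asarray(seed_active)
        if seed_active.dtype == bool:
            active |= seed_active
        else:
            if seed_active.size and seed_active.min() < 0:
                raise ValueError("negative neuron index in seed set")
            active[seed_active] = True

        steps = [np.flatnonzero(active)]
        counts = [int(active.sum())]
        weight = self.synaptic_efficacy * float(efficacy_multiplier)
        if weight > 0:
            while True:
                inputs = self._adj_exc.T @ active.astype(np.float64)
                newly = (~active) & (weight * inputs >= self.quorum_threshold)
                if not newly.any():
                    break
                active |= newly
                steps.append(np.flatnonzero(newly))
                counts.append(int(active.sum()))

        final = counts[-1]
        if final == 0:
            return IgnitionResult(0.0, 0, steps)
        target = DELAY_FRACTION * final
        delay = int(np.searchsorted(counts, target))
        return IgnitionResult(final / n, delay, steps)


def ignite_quorum(
    n_seed_active: int,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    network: QuorumNetwork | None = None,
) -> IgnitionResult:
    """Ignite a quorum percolation from ``n_seed_active`` random neurons.

    Convenience wrapper: builds (or reuses) the compartment graph from the
    configuration, seeds the requested number of random neurons, and runs
    :meth:`QuorumNetwork.ignite` with the configuration's CNQX multiplier.
    """
    if n_seed_active < 0:
        raise ValueError("n_seed_active must be non-negative")
    if n_seed_active > config.n_neurons_per_compartment:
        raise ValueError("seed larger than the population")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    net = network if network is not None else QuorumNetwork.from_config(config, rng)
    seed = rng.choice(net.n_neurons, size=n_seed_active, replace=False)
    return net.ignite(seed, config.cnqx_efficacy_multiplier)
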