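"""Evoked response amplitude vs stimulus duration, with and without CNQX.

Without CNQX every pulse, however short, ignites a full network burst by
quorum percolation, so the response amplitude is duration-independent.
With 10 µM CNQX (saturating AMPA-receptor block) only directly
photo-activated neurons respond, and the amplitude grows with the pulse
duration through both the activated count and the calcium integration time.
"""

import numpy as np

from optoburst import PeristimulusSet, SimulationConfig, compute_dff, \
    extract_peristimulus, response_amplitude_curve, simulate_experiment
from optoburst.config import duration_series_protocol

durations = (1, 4, 16, 64, 256, 1024)


def amplitude_curve(cnqx_um: float):
    config = SimulationConfig(noise_sigma=0.0, spontaneous_burst_rate=0.0,
                              cnqx_concentration=cnqx_um)
    protocol = duration_series_protocol(durations)
    _, rec = simulate_experiment(config, protocol, protocol.end + 5_000.0, seed=3)
    dff = compute_dff(rec, "A")
    pset = extract_peristimulus(dff, rec, "A", 1_000.0, 3_000.0)
    psets = {
        d: PeristimulusSet(1_000.0, 3_000.0, pset.time_ms, pset.matrix[i:i + 1],
                           np.array([float(d)]), pset.sampling_rate)
        for i, d in enumerate(durations)
    }
    return response_amplitude_curve(psets)


control = amplitude_curve(0.0)
blocked = amplitude_curve(10.0)

print("duration (ms) | dF/F control | dF/F 10 uM CNQX")
for d, a0, a1 in zip(durations, control["mean_amplitude"], blocked["mean_amplitude"]):
    print(f"{d:13d} | {a0:12.3f} | {a1:15.3f}")
print("Control is flat (full percolation from any seed); under CNQX the")
print("response grows with duration and overtakes control for long pulses")
print("because the silenced inhibitory population no longer curbs it.")
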