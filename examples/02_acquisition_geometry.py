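"""Acquisition arithmetic of the stimulation and imaging set-up.

The stimulation spot size follows from the optical-fiber geometry (core
diameter, distance to the sample, acceptance half-angle), and the effective
sampling rate from the line-scan rate and the number of integration cycles
per stored sample.
"""

from optoburst import SimulationConfig, compute_spot_diameter

spot = compute_spot_diameter(fiber_diameter=0.5, distance=1.0, half_angle=26.0)
print(f"stimulation spot   : {spot:.2f} mm diameter "
      "(0.5 mm PMMA fiber, 1 mm above the culture, 26 deg half-angle)")
print("-> comfortably covers a 2 mm culture well without a lens.")

config = SimulationConfig(line_rate=8000.0, cycles_per_sample=8)
print(f"effective sampling : {config.sampling_rate:.0f} Hz "
      "(8 kHz line scan, fluorescence integrated over 8 cycles)")
print("-> millisecond resolution, enough to resolve few-ms burst delays.")
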