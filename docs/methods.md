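# Methods

## Scope

`optoburst` models and analyses a two-compartment neuronal-culture
experiment: two populations ("A" and "B") in PDMS micro-wells, connected by
axon micro-channels, optogenetically stimulated at 470 nm and read out with
a red-shifted calcium indicator through a confocal line scan positioned
astride both populations. Every analysis stage (ΔF/F, burst detection,
peristimulus averaging, cross-correlation delay estimation, device
classification) can therefore be exercised on synthetic recordings whose
ground truth is known.

## The ignition model

Each compartment is a directed Erdős–Rényi graph over N neurons (edge
probability k/(N−1), so the mean in-degree is k). A fraction of the neurons
is inhibitory; inhibitory neurons never express ChR2 (the CaMKIIa promoter
used for transduction is essentially inactive in them). Burst ignition
follows the quorum-percolation rule: in synchronous 1 ms steps, an inactive
neuron activates when

    efficacy × cnqx_multiplier × (# active excitatory presynaptic inputs) ≥ Θ

with quorum threshold Θ. Once the active set stops growing the ignition is
complete; the *ignition delay* is the number of steps until the active
count first reaches 95% of its final value. Inhibitory inputs do not count
toward the quorum — in this model inhibition shapes the calcium-signal
amplitude (below), not recruitment; bursts ignite *despite* inhibition.

CNQX (an AMPA-receptor antagonist) enters as a linear efficacy multiplier
max(0, 1 − c/10 µM): 10 µM — the lowest saturating concentration — blocks
excitatory transmission completely, 5 µM halves it. The multiplier also
scales the effective seed delivered across the inter-compartment channels.

With the defaults (N = 2000, k = 50, Θ = 2), a seed of a few neurons
percolates to the whole population in a handful of steps, which is what
makes very short light pulses sufficient to ignite bursts; at half efficacy
the effective quorum doubles and a 3-axon seed is subcritical while a
100-axon seed still percolates — the mechanism behind the CNQX-induced
switch from bidirectional to unidirectional transmission on diode devices.

## Events in a simulated experiment

* **Spontaneous bursts** arise per compartment as a Poisson process with a
  3 s dead time (a post-burst refractory period that applies to spontaneous
  ignitions only). The exponential hazard is compensated for the dead time
  so the realized mean rate equals `spontaneous_burst_rate` (default
  5.9 bursts/min, giving inter-burst intervals mostly between 5 and 10 s).
  Each ignition seeds `spontaneous_seed_count` random excitatory neurons.
* **470 nm pulses** directly activate Binomial(n_transduced, 1 −
  e^(−rate·duration·intensity)) neurons of the target compartment, with
  per-neuron activation times following the truncated exponential
  first-success law. The activated set then attempts a quorum ignition;
  stimulation overrides the spontaneous refractory period.
* **549 nm imaging light** activates through a separate crosstalk rate,
  zero by default — the indicator/opsin pair is chosen for spectral
  separation, and with zero crosstalk recordings are bit-identical across
  imaging intensities by construction (imaging events touch no other
  random stream).
* **Cross-compartment seeding**: when a full burst completes, it seeds the
  opposite compartment with round(n_axons × recruited_fraction ×
  cnqx_multiplier) neurons, n_axons being the afferent axon count of that
  direction (diode devices: reverse = 3% of forward). The receiving side's
  own recruitment steps then produce the transmission delay — fewer
  afferent axons, more integration steps, longer delay. Seeds arriving
  within 100 ms of a full burst in the target are ignored: this suppresses
  the unphysical A→B→A echo (which would arrive within a few ms, while the
  target is still firing its onset volley) without blocking genuine
  re-ignition later, since stimulation and afferent volleys are strong
  enough to override the slow refractory period.

## From activity to fluorescence

Within-burst firing is front-loaded: each recruited neuron fires a
high-rate volley for `burst_volley_ms` (30 ms) and then reverberates at
`burst_sustain_level` (6%) of the volley rate until `burst_firing_duration_ms`
(1.5 s) after its recruitment. This choice matters twice. The volley gives
the fluorescence transient a sharp onset, which is the feature that carries
millisecond timing into the cross-correlation; the sustained tail holds the
signal at a recruitment-determined plateau, so responses to long
stimulations — whose onset is hidden behind the saturation mask — still
show full amplitude, making the evoked amplitude duration-independent
without synaptic block. When percolation fails (saturating CNQX), directly
photo-activated neurons instead fire tonically at `direct_drive_level`
(7.5%) while the light is on plus a 100 ms tail: the response then grows
with stimulus duration through both the activated count and the
integration time.

The calcium drive of a compartment is

    drive(t) = max(0, active_excitatory(t) − s · active_inhibitory(t)) / N

with `inhibition_strength` s = 2.5. Under saturating CNQX the inhibitory
population is silent (its only excitation is synaptic), so long direct
responses exceed the inhibition-curbed network-burst amplitude — the
disinhibition effect.

The drive is convolved at the line rate with a dual-exponential indicator
kernel (rise 10 ms, decay 500 ms; the indicator's true kinetics are not
published, these defaults make single bursts resolvable at 1 kHz),
normalized to unit steady-state gain, scaled by `ca_amplitude` over
`baseline_F` (defaults chosen so a full burst peaks at ΔF/F ≈ 0.2), with
i.i.d. Gaussian noise per line. `cycles_per_sample` consecutive lines are
integrated per stored sample (8000 Hz / 8 = 1 kHz exactly), and every
sample whose half-open integration window overlaps a 470 nm pulse on
either compartment is masked — the detector saturates during stimulation.

## Analysis pipeline

* **ΔF/F**: F₀ is a centered rolling 10th percentile over 10 s windows of
  the unmasked samples (robust while bursts occupy < 50% of the time);
  masked samples stay masked.
* **Burst detection**: upward crossings of a threshold, by default 5×
  the robust noise SD estimated from median absolute successive
  differences — differencing removes the slow transients, so the estimate
  stays a noise measure even under dense stimulation. The peak is the
  maximum before the downward re-crossing; events closer than 500 ms are
  merged (well below the 5–10 s physiological inter-burst interval, above
  the transient width); masked gaps up to 1024 ms (the longest stimulus)
  are bridged by linear interpolation first; supra-threshold excursions
  shorter than 10 ms are discarded as noise.
* **Rate normalization**: per-culture rates divided by that culture's
  reference condition; cultures with a zero reference are excluded and
  reported.
* **Peristimulus sets**: one row per selected 470 nm event, masks carried
  through; means and SDs over unmasked entries only. The response
  amplitude of a trial is the post-stimulus peak minus the mean of the
  200 ms pre-stimulus baseline; a trial is "evoked" when that amplitude
  exceeds a threshold within 500 ms of stimulus end. Spontaneous-burst
  contamination is handled by averaging over repetitions, not by exclusion.
* **Transmission delay**: per-lag Pearson correlation of the overlapping
  unmasked portions of the two mean peristimulus traces (robust to
  baseline offsets; lags with < 10 overlapping samples are undefined),
  maximized over non-negative lags (causality w.r.t. the stimulated side),
  refined below the 1 ms sample interval by parabolic interpolation —
  needed since real delays are a few ms. The delay is estimated on a short
  onset-centered window (200 ms pre / 500 ms post by default): on the full
  window the slow shared plateau and decay dominate the correlation and
  flatten its peak, whereas the onset ramp carries the timing.
* **Classification**: *unidirectional* when the reverse direction never
  evokes a response; *symmetric* when both delays exist and differ by
  < 10% of the forward delay (below the smallest asymmetry observed on
  diode devices); otherwise *bidirectional-asymmetric*. The paired
  comparison of forward vs reverse delays across devices is a standard
  paired t-test (scipy), with zero-variance differences reported as
  degenerate.

## Parameter defaults

| parameter | default | meaning / rationale |
|---|---|---|
| `n_neurons_per_compartment` | 2000 | scale parameter; a 2 mm well at ~5000/mm² seeds ~15,700, simulated N is reduced for tractability and quorum behaviour is N-robust |
| `inhibitory_fraction` | 0.15 | 10–20% of cultured neurons are inhibitory |
| `transduced_fraction` | 0.70 | viral transduction efficiency (excitatory only) |
| `quorum_threshold` / `mean_in_degree` | 2 / 50 | few-neuron seeds percolate; halving efficacy (5 µM CNQX) makes sparse seeds subcritical |
| `n_axons_forward/reverse` | 100 / 100 | straight channels; diode helper sets reverse = 3% of forward |
| `photoactivation_rate` | 0.05 /ms | ~22% of transduced neurons activated by a 5 ms pulse; saturates by ~100 ms |
| `spontaneous_burst_rate` | 5.9 /min | matches the bursting rate of healthy cultures at 1x imaging light |
| `refractory_ms` | 3000 | spontaneous-only dead time |
| `burst_volley_ms` / `burst_sustain_level` | 30 / 0.06 | onset volley vs reverberation (see above) |
| `direct_drive_level` | 0.075 | tonic ChR2-driven firing under synaptic block |
| `inhibition_strength` | 2.5 | subtractive inhibition of the calcium drive |
| `ca_rise_tau` / `ca_decay_tau` | 10 / 500 ms | indicator kinetics (not published; chosen for 1 kHz resolvability) |
| `ca_amplitude` / `baseline_F` / `noise_sigma` | 700 / 100 / 2 | full burst ≈ 0.2 ΔF/F; per-line noise → ≈ 0.007 ΔF/F after 8-line integration |
| `line_rate` / `cycles_per_sample` | 8000 Hz / 8 | 1 kHz effective sampling |

## What the generator does and does not emulate

It emulates: all-or-none network bursts with physiological rates and
refractoriness, duration-dependent direct photo-activation, disinhibition
under synaptic block, direction-dependent transmission through axon
bundles, detector saturation during stimulation, and acquisition noise.

It does **not** emulate: spatial structure within a well (the line scan
already integrates each population), single-spike dynamics (the unit of
activity is burst participation), indicator bleaching or drift, shot
noise (noise is additive Gaussian at the line level), short-term
plasticity across stimulus trains, or differences in per-axon synaptic
strength between forward and reverse channel populations (the model varies
axon *count* only). Passing tests therefore validate the pipeline's logic
and calibration on this idealized data model, not its behaviour under
drift, movement artefacts or bleaching in real recordings.

## Numerical choices and degenerate inputs

Time is milliseconds, windows half-open [start, end). One seeded generator
per simulation, split into independent sub-streams (graphs, spontaneous
events per compartment, evoked draws, noise), so changing e.g. the imaging
intensity or coupling parameters does not perturb the spontaneous event
series; identical seeds give bit-identical recordings. CSV floats are
written with 17 significant digits and read with round-trip parsing, so
write→read is exact. All-masked traces, zero-reference cultures, fewer
than two paired delays, and protocols extending beyond the simulated
duration raise typed errors; zero-variance paired differences are reported
as degenerate rather than silently producing NaN. Problem sizes in the
bundled checks (e.g. 9 cultures × 10 min for the spontaneous-rate
calibration, 30 stimulations per side for delay estimation, graphs up to
N = 50 against the brute-force oracle) were chosen to keep each run in the
tens of seconds on one CPU while leaving sampling error well inside the
tolerances tested.

The spontaneous-rate calibration is measured on an *isolated* population
(coupling removed): reference bursting rates come from single-well
cultures, and with default coupling the partner compartment would nearly
double the apparent rate through propagated bursts.

## Known limitations

* The quorum model uses a single homogeneous graph per compartment;
  degree heterogeneity, distance-dependent connectivity and synaptic
  depression are out of scope.
* Delay estimates inherit a small bias (~±0.3 ms) from the asymmetric
  shape of the correlation peak; forward/reverse *differences* on the same
  device are much better determined than absolute delays.
* The linear CNQX dose–efficacy map is a convenience; only the anchor
  points (0 µM → 1, 5 µM → 0.5, ≥10 µM → 0) are used by the bundled
  scenarios.
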