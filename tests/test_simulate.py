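"""Simulator operations: optics, photo-activation, rendering, experiments."""

import math

import numpy as np
import pytest

from optoburst import (
    ParameterError,
    PopulationActivity,
    ProtocolError,
    SimulationConfig,
    StimulationProtocol,
    StimulusEvent,
    compute_spot_diameter,
    photo_activate,
    render_line_scan,
    simulate_experiment,
)
from optoburst.config import duration_series_protocol


# ---------------------------------------------------------------------------
# optics
# ---------------------------------------------------------------------------

class TestSpotDiameter:
    def test_reference_fiber_geometry(self):
        # 0.5 mm fiber, 1 mm above the culture, 26 degree acceptance half-angle
        assert round(compute_spot_diameter(0.5, 1.0, 26.0), 1) == 1.5

    def test_butt_coupled_fiber_gives_fiber_diameter(self):
        assert compute_spot_diameter(0.7, 0.0, 45.0) == 0.7

    def test_closed_form(self):
        expected = 0.5 + 4.0 * math.tan(math.radians(26.0))
        assert compute_spot_diameter(0.5, 2.0, 26.0) == pytest.approx(expected)

    @pytest.mark.parametrize("args", [(0.5, 1.0, 90.0), (-0.1, 1.0, 26.0)])
    def test_invalid_geometry_rejected(self, args):
        with pytest.raises(ParameterError):
            compute_spot_diameter(*args)


# ---------------------------------------------------------------------------
# photo-activation
# ---------------------------------------------------------------------------

class TestPhotoActivate:
    def test_vanishing_duration_activates_nobody(self, rng):
        config = SimulationConfig()
        pulse = StimulusEvent(onset=0, duration=1e-9, target_compartment="A")
        assert photo_activate(pulse, config, rng) == 0

    def test_imaging_light_without_crosstalk_activates_nobody(self, rng):
        config = SimulationConfig(crosstalk_549_activation=0.0)
        pulse = StimulusEvent(
            onset=0, duration=60_000, target_compartment="A", role="imaging_549",
            intensity=4.0,
        )
        assert photo_activate(pulse, config, rng) == 0

    def test_binomial_mean_matches_closed_form(self, rng):
        # 1000 transduced neurons, rate 0.1/ms, 16 ms pulse
        config = SimulationConfig(
            n_neurons_per_compartment=2000,
            inhibitory_fraction=0.0,
            transduced_fraction=0.5,
            photoactivation_rate=0.1,
        )
        assert config.n_transduced("A") == 1000
        pulse = StimulusEvent(onset=0, duration=16.0, target_compartment="A")
        p = 1 - math.exp(-1.6)
        draws = [photo_activate(pulse, config, rng) for _ in range(10_000)]
        se = math.sqrt(1000 * p * (1 - p)) / math.sqrt(len(draws))
        assert np.mean(draws) == pytest.approx(1000 * p, abs=3 * se)

    def test_untransduced_compartment_is_light_insensitive(self, rng):
        config = SimulationConfig(transduced_compartments="A")
        pulse = StimulusEvent(onset=0, duration=1024, target_compartment="B")
        assert photo_activate(pulse, config, rng) == 0


# ---------------------------------------------------------------------------
# line-scan rendering
# ---------------------------------------------------------------------------

def _activity(drive_a, drive_b=None):
    n = len(drive_a)
    drive_b = drive_b if drive_b is not None else np.zeros(n)
    return PopulationActivity(
        time_ms=np.arange(n, dtype=float),
        fraction_active={"A": drive_a.copy(), "B": drive_b.copy()},
        calcium_drive={"A": drive_a, "B": drive_b},
    )


class TestRenderLineScan:
    def test_effective_sampling_rate_is_line_rate_over_cycles(self):
        config = SimulationConfig(line_rate=8000.0, cycles_per_sample=8)
        rec = render_line_scan(_activity(np.zeros(2000)), config)
        assert rec.sampling_rate == 1000.0

    def test_quiescent_culture_sits_at_baseline(self):
        config = SimulationConfig(noise_sigma=0.0)
        rec = render_line_scan(_activity(np.zeros(3000)), config)
        assert np.allclose(rec.trace_A, config.baseline_F)
        assert not rec.mask_A.any()

    def test_impulse_response_matches_direct_convolution(self):
        """One ms of unit drive renders as the 8-line-averaged kernel."""
        config = SimulationConfig(noise_sigma=0.0)
        drive = np.zeros(4000)
        drive[100] = 1.0
        rec = render_line_scan(_activity(drive), config)

        # independent oracle: direct convolution at the line rate, then
        # block-average 8 lines per sample
        line_dt = 1000.0 / config.line_rate
        n_lines = int(4000 / line_dt)
        t = np.arange(0.0, 6 * config.ca_decay_tau, line_dt)
        kernel = np.exp(-t / config.ca_decay_tau) - np.exp(-t / config.ca_rise_tau)
        kernel /= kernel.sum()
        drive_lines = drive[np.minimum((np.arange(n_lines) * line_dt).astype(int), 3999)]
        f = config.baseline_F + config.ca_amplitude * np.convolve(drive_lines, kernel)[:n_lines]
        expected = f.reshape(-1, config.cycles_per_sample).mean(axis=1)
        assert np.allclose(rec.trace_A, expected, rtol=1e-10, atol=1e-8)

    def test_single_cycle_no_noise_is_exact_sampling(self):
        config = SimulationConfig(noise_sigma=0.0, cycles_per_sample=1)
        drive = np.zeros(1000)
        drive[50] = 1.0
        rec = render_line_scan(_activity(drive), config)
        assert rec.sampling_rate == config.line_rate
        # block size one: integration is the identity, values are the
        # convolved signal itself (strictly monotone decay after the peak)
        peak = np.argmax(rec.trace_A)
        tail = rec.trace_A[peak : peak + 1000]
        assert (np.diff(tail) < 0).all()

    def test_samples_overlapping_stimulus_are_masked_on_both_traces(self):
        config = SimulationConfig(noise_sigma=0.0)
        protocol = StimulationProtocol(
            events=[StimulusEvent(onset=500.0, duration=5.0, target_compartment="A")]
        )
        rec = render_line_scan(_activity(np.zeros(2000)), config, protocol)
        # half-open integration windows: exactly the samples whose window
        # intersects [onset, onset + duration) are masked
        sel = (rec.time_ms > 500.0) & (rec.time_ms < 505.0)
        assert rec.mask_A[sel].all() and rec.mask_B[sel].all()
        assert np.isnan(rec.trace_A[sel]).all()
        assert not rec.mask_A[rec.time_ms > 507.0].any()
        assert not rec.mask_A[rec.time_ms < 499.0].any()


# ---------------------------------------------------------------------------
# whole experiments
# ---------------------------------------------------------------------------

class TestSimulateExperiment:
    def test_disconnected_device_has_no_cross_compartment_bursts(self):
        config = SimulationConfig(n_axons_forward=0, n_axons_reverse=0)
        protocol = StimulationProtocol(
            events=[StimulusEvent(onset=5_000.0, duration=5.0, target_compartment="A")]
        )
        activity, _ = simulate_experiment(config, protocol, 60_000.0, seed=3)
        origins_b = {b.origin for b in activity.bursts_in("B")}
        assert "synaptic_from_other_compartment" not in origins_b
        origins_a = {b.origin for b in activity.bursts_in("A")}
        assert "synaptic_from_other_compartment" not in origins_a

    def test_protocol_beyond_duration_rejected(self):
        config = SimulationConfig()
        protocol = StimulationProtocol(
            events=[StimulusEvent(onset=50_000.0, duration=5.0, target_compartment="A")]
        )
        with pytest.raises(ProtocolError):
            simulate_experiment(config, protocol, 10_000.0)

    def test_identical_seeds_give_bit_identical_recordings(self):
        config = SimulationConfig()
        protocol = duration_series_protocol(durations_ms=(4, 16))
        _, rec1 = simulate_experiment(config, protocol, 20_000.0, seed=11)
        _, rec2 = simulate_experiment(config, protocol, 20_000.0, seed=11)
        assert np.array_equal(rec1.trace_A, rec2.trace_A, equal_nan=True)
        assert np.array_equal(rec1.trace_B, rec2.trace_B, equal_nan=True)
        assert np.array_equal(rec1.mask_A, rec2.mask_A)

    def test_saturating_cnqx_recruitment_grows_with_stimulus_duration(self):
        """Blocked synapses: only direct photo-activation, binomial in duration."""
        config = SimulationConfig(cnqx_concentration=10.0, spontaneous_burst_rate=0.0)
        protocol = duration_series_protocol(durations_ms=(1, 1024))
        activity, _ = simulate_experiment(config, protocol, 15_000.0, seed=21)
        bursts = activity.bursts_in("A")
        assert len(bursts) == 2
        short, long = sorted(bursts, key=lambda b: b.ignition_time_ms)
        assert long.recruited_fraction > short.recruited_fraction

    def test_without_cnqx_recruitment_is_duration_independent(self):
        """Percolation reaches the same fixed point from any seeding."""
        config = SimulationConfig(spontaneous_burst_rate=0.0)
        protocol = duration_series_protocol(durations_ms=(1, 1024))
        activity, _ = simulate_experiment(config, protocol, 15_000.0, seed=21)
        fractions = [b.recruited_fraction for b in activity.bursts_in("A")
                     if b.origin == "direct_photo"]
        assert len(fractions) == 2
        assert fractions[0] == pytest.approx(fractions[1], rel=0.02)

    def test_ground_truth_fractions_within_bounds(self, straight_run):
        _, activity, _ = straight_run
        assert all(0.0 <= b.recruited_fraction <= 1.0 for b in activity.bursts)
        duration = activity.time_ms[-1] + 1
        assert all(0.0 <= b.ignition_time_ms <= duration for b in activity.bursts)
        for comp in ("A", "B"):
            frac = activity.fraction_active[comp]
            assert frac.min() >= 0.0 and frac.max() <= 1.0
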