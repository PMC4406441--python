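"""ΔF/F computation, burst detection and rate statistics."""

import numpy as np
import pytest

from optoburst import (
    EmptyDataError,
    ParameterError,
    SimulationConfig,
    StimulationProtocol,
    bin_trace,
    bursting_rate,
    compute_dff,
    detect_bursts,
    normalize_rates,
    simulate_experiment,
)
from optoburst.recording import LineScanRecording
from optoburst.traces import BurstEvent, default_burst_threshold


def _recording(trace, mask=None, rate=1000.0):
    n = len(trace)
    mask = mask if mask is not None else np.zeros(n, dtype=bool)
    return LineScanRecording(
        sampling_rate=rate,
        time_ms=(np.arange(n) + 0.5) * 1000.0 / rate,
        trace_A=np.asarray(trace, dtype=float),
        trace_B=np.full(n, 100.0),
        mask_A=mask,
        mask_B=np.zeros(n, dtype=bool),
        protocol=StimulationProtocol(),
    )


class TestComputeDff:
    def test_constant_trace_is_zero(self):
        rec = _recording(np.full(20_000, 100.0))
        assert np.allclose(compute_dff(rec, "A"), 0.0)

    def test_plateau_amplitude_from_definition(self):
        """A 2 s plateau at 150 over baseline 100 has ΔF/F = 0.5."""
        trace = np.full(60_000, 100.0)
        trace[30_000:32_000] = 150.0
        dff = compute_dff(rec := _recording(trace), "A")
        assert np.allclose(dff[30_500:31_500], 0.5)
        assert np.allclose(dff[:20_000], 0.0)

    def test_all_masked_trace_rejected(self):
        rec = _recording(np.full(100, np.nan), mask=np.ones(100, dtype=bool))
        with pytest.raises(EmptyDataError):
            compute_dff(rec, "A")

    def test_masked_samples_stay_masked(self):
        mask = np.zeros(20_000, dtype=bool)
        mask[5_000:5_050] = True
        rec = _recording(np.full(20_000, 100.0), mask=mask)
        dff = compute_dff(rec, "A")
        assert np.isnan(dff[5_000:5_050]).all()
        assert np.isfinite(dff[~mask]).all()

    def test_simulated_burst_peak_tracks_ground_truth_drive(self):
        """Noise-free peak ΔF/F equals the kernel-filtered ground-truth drive."""
        config = SimulationConfig(noise_sigma=0.0, n_axons_forward=0, n_axons_reverse=0)
        activity, rec = simulate_experiment(config, StimulationProtocol(), 120_000.0, seed=5)
        dff = compute_dff(rec, "A")
        bursts = activity.bursts_in("A", full_only=True)
        assert bursts, "expected spontaneous bursts in 2 minutes"
        # oracle: convolve the ground-truth drive with the indicator kernel
        t = np.arange(0.0, 6 * config.ca_decay_tau)
        kernel = np.exp(-t / config.ca_decay_tau) - np.exp(-t / config.ca_rise_tau)
        kernel /= kernel.sum()
        f = config.ca_amplitude * np.convolve(activity.calcium_drive["A"], kernel)
        expected_peak = f.max() / config.baseline_F
        assert np.nanmax(dff) == pytest.approx(expected_peak, rel=0.10)


class TestDetectBursts:
    def test_flat_trace_has_no_bursts(self):
        events = detect_bursts(np.zeros(10_000), 1000.0, threshold_dff=0.1)
        assert events == []

    def test_two_rendered_transients_recovered_at_ignition_times(self):
        config = SimulationConfig(noise_sigma=0.0, spontaneous_burst_rate=0.0,
                                  n_axons_forward=0, n_axons_reverse=0)
        protocol = StimulationProtocol(events=[
            {"onset": 5_000.0, "duration": 5.0, "target_compartment": "A"},
            {"onset": 10_000.0, "duration": 5.0, "target_compartment": "A"},
        ])
        activity, rec = simulate_experiment(config, protocol, 20_000.0, seed=2)
        dff = compute_dff(rec, "A")
        events = detect_bursts(dff, rec.sampling_rate, threshold_dff=0.02)
        assert len(events) == 2
        truth = [b.ignition_time_ms for b in activity.bursts_in("A", full_only=True)]
        for ev, t in zip(events, truth):
            # onset trails ignition by the stimulus mask plus the time the
            # indicator needs to rise through the threshold
            assert t <= ev.onset_ms <= t + 10.0

    def test_transient_split_by_mask_is_one_event(self):
        # rendered-like transient with a 50 ms masked gap punched in
        t = np.arange(8_000, dtype=float)
        transient = np.where(t > 2_000, np.exp(-(t - 2_000) / 500.0), 0.0) * 0.3
        transient[2_100:2_150] = np.nan
        events = detect_bursts(transient, 1000.0, threshold_dff=0.05)
        assert len(events) == 1

    def test_long_masked_gap_splits_events(self):
        t = np.arange(12_000, dtype=float)
        transient = np.where(t > 2_000, np.exp(-(t - 2_000) / 500.0), 0.0) * 0.3
        transient += np.where(t > 8_000, np.exp(-(t - 8_000) / 500.0), 0.0) * 0.3
        events = detect_bursts(transient, 1000.0, threshold_dff=0.05)
        assert len(events) == 2

    def test_subthreshold_glitches_ignored(self):
        x = np.zeros(5_000)
        x[1_000] = 0.2  # single-sample exceedance: not a network burst
        assert detect_bursts(x, 1000.0, threshold_dff=0.1) == []

    def test_rate_invariant_under_amplitude_rescaling(self):
        rng = np.random.default_rng(0)
        t = np.arange(60_000, dtype=float)
        x = 0.001 * rng.normal(size=len(t))
        for onset in range(5_000, 55_000, 7_000):
            x += np.where(t > onset, np.exp(-(t - onset) / 400.0), 0.0) * 0.25
        thr = default_burst_threshold(x)
        n1 = len(detect_bursts(x, 1000.0, thr))
        n2 = len(detect_bursts(10 * x, 1000.0, 10 * thr))
        assert n1 == n2 > 0


class TestRates:
    def test_rate_arithmetic(self):
        events = [BurstEvent(i * 1000.0, i * 1000.0 + 1, 0.2, 100.0) for i in range(12)]
        assert bursting_rate(events, 2.0) == 6.0
        assert bursting_rate([], 5.0) == 0.0
        with pytest.raises(ParameterError):
            bursting_rate(events, 0.0)

    def test_poisson_rate_recovered_within_three_se(self):
        rng = np.random.default_rng(1)
        rate, minutes, runs = 6.0, 10.0, 20
        measured = []
        for _ in range(runs):
            n = rng.poisson(rate * minutes)
            measured.append(n / minutes)
        se = np.sqrt(rate / minutes) / np.sqrt(runs)
        assert np.mean(measured) == pytest.approx(rate, abs=3 * se)


class TestNormalizeRates:
    def test_reference_normalization_example(self):
        table = normalize_rates({"c1": {"1x": 6.0, "2x": 6.3, "4x": 5.8}}, "1x")
        normalized = table.set_index("condition")["normalized_rate"]
        assert normalized["1x"] == pytest.approx(1.0)
        assert normalized["2x"] == pytest.approx(1.05)
        assert normalized["4x"] == pytest.approx(0.9667, abs=1e-4)

    def test_equal_rates_normalize_to_one(self):
        table = normalize_rates({"c": {"1x": 4.4, "2x": 4.4}}, "1x")
        assert (table["normalized_rate"] == 1.0).all()

    def test_scale_invariance_across_cultures(self):
        a = {"1x": 2.0, "2x": 3.0, "4x": 2.5}
        b = {k: 3.7 * v for k, v in a.items()}
        table = normalize_rates({"a": a, "b": b}, "1x")
        rows_a = table[table.culture == "a"].set_index("condition")["normalized_rate"]
        rows_b = table[table.culture == "b"].set_index("condition")["normalized_rate"]
        assert np.allclose(rows_a, rows_b)

    def test_zero_reference_culture_excluded_and_reported(self):
        table = normalize_rates(
            {"ok": {"1x": 5.0, "2x": 6.0}, "dead": {"1x": 0.0, "2x": 1.0}}, "1x"
        )
        assert set(table["culture"]) == {"ok"}
        assert table.attrs["excluded_cultures"] == ["dead"]


class TestBinTrace:
    def test_unit_bin_is_identity(self):
        x = np.arange(100, dtype=float)
        assert np.array_equal(bin_trace(x, 1.0, 1000.0), x)

    def test_constant_trace_stays_constant(self):
        assert np.allclose(bin_trace(np.full(1000, 7.0), 50.0, 1000.0), 7.0)

    def test_ramp_bin_means(self):
        x = np.arange(1000, dtype=float)
        binned = bin_trace(x, 50.0, 1000.0)
        expected = x.reshape(-1, 50).mean(axis=1)  # 24.5, 74.5, ...
        assert np.array_equal(binned, expected)
        assert binned[0] == 24.5 and binned[1] == 74.5

    def test_fully_masked_bin_stays_masked(self):
        x = np.arange(200, dtype=float)
        x[50:100] = np.nan
        binned = bin_trace(x, 50.0, 1000.0)
        assert np.isnan(binned[1])
        assert np.isfinite(binned[[0, 2, 3]]).all()

    def test_non_multiple_bin_rejected(self):
        with pytest.raises(ParameterError):
            bin_trace(np.zeros(100), 1.5, 1000.0)
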