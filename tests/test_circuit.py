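"""Circuit assembly, stimulus generation, protocols and metric extraction."""

import numpy as np
import pytest

from giantfiber.circuit import (
    CalibrationCriteria,
    CircuitParams,
    SimulationResult,
    StimulusSpec,
    calibrate,
    compute_response_frequency,
    detect_spikes,
    evaluate_criteria,
    genotype_sweep,
    make_stimulus,
    run_circuit,
    single_pulse_spec,
    train_spec,
)


class TestStimulus:
    def test_deterministic_pulse_schedule(self):
        spec = StimulusSpec(pulse_rate=100.0, n_pulses=10, duration=100.0,
                            noise_sd=0.0, pulse_amplitude=50.0,
                            pulse_width=1.0)
        t, i = make_stimulus(spec)
        onsets = spec.onsets()
        assert len(onsets) == 10
        assert np.allclose(np.diff(onsets), 10.0)
        # rising edges of the pulse train occur exactly at the onsets
        rising = t[np.nonzero((i[:-1] == 0) & (i[1:] > 0))[0] + 1]
        assert np.allclose(rising, onsets)

    def test_same_seed_same_trace(self):
        spec = StimulusSpec(seed=7)
        _, a = make_stimulus(spec)
        _, b = make_stimulus(spec)
        assert np.array_equal(a, b)
        _, c = make_stimulus(spec.with_(seed=8))
        assert not np.array_equal(a, c)

    def test_noise_is_zero_mean(self):
        """Law of large numbers: the residual after removing the pulse
        component has mean within 4 standard errors of zero."""
        spec = StimulusSpec(duration=1000.0, dt=0.01, noise_sd=1.0, seed=3,
                            n_pulses=1)
        _, noisy = make_stimulus(spec)
        _, clean = make_stimulus(spec.with_(noise_sd=0.0))
        resid = noisy - clean
        n = resid.size
        assert n == 10 ** 5
        assert abs(resid.mean()) < 4.0 / np.sqrt(n)

    def test_too_short_duration_rejected(self):
        with pytest.raises(ValueError):
            StimulusSpec(pulse_rate=100.0, n_pulses=10, duration=50.0)


class TestSpikeDetection:
    def test_threshold_crossing_with_refractory(self):
        t = np.arange(0, 10, 0.01)
        v = np.full_like(t, -80.0)
        for center in (2.0, 2.5, 7.0):  # 2.5 falls in the refractory window
            v[np.abs(t - center) < 0.2] = 20.0
        spikes = detect_spikes(t, v, threshold=0.0, refractory_ms=2.0)
        assert len(spikes) == 2
        assert spikes[0] == pytest.approx(1.81, abs=0.02)
        assert spikes[1] == pytest.approx(6.81, abs=0.02)

    def test_no_crossing_no_spike(self):
        t = np.arange(0, 5, 0.01)
        assert detect_spikes(t, np.full_like(t, -60.0)).size == 0


class TestRunCircuit:
    def test_decoupled_synapse_silences_compartment3(self, quiet_train):
        params = CircuitParams(occupancy=0.0, chem_enabled=False)
        r = run_circuit(params, quiet_train)
        assert len(r.spike_times[3]) == 0
        assert r.response_pct == 0.0
        assert r.latency_ms is None

    def test_saturated_occupancy_single_spike(self, default_params,
                                              quiet_pulse):
        r = run_circuit(default_params.with_(occupancy=12.0), quiet_pulse)
        assert len(r.spike_times[3]) == 1
        assert r.latency_ms is not None

    def test_spike_times_strictly_increasing(self, default_params,
                                             quiet_train):
        r = run_circuit(default_params, quiet_train)
        for sp in r.spike_times:
            assert np.all(np.diff(sp) > 0)
        assert 0.0 <= r.response_pct <= 100.0

    def test_stimulus_amplitude_monotonicity(self, default_params):
        """A stronger pulse never silences compartment 0 (noise-free)."""
        counts = []
        for amp in (150.0, 300.0, 600.0):
            r = run_circuit(default_params,
                            single_pulse_spec(amp, noise_sd=0.0))
            counts.append(len(r.spike_times[0]))
        assert counts == sorted(counts)

    def test_seeded_runs_bit_reproducible(self, default_params):
        spec = train_spec(seed=42)
        r1 = run_circuit(default_params, spec)
        r2 = run_circuit(default_params, spec)
        assert np.array_equal(r1.v, r2.v)
        assert r1.latency_ms == r2.latency_ms
        assert r1.response_pct == r2.response_pct

    def test_gap_charge_conservation_in_traces(self, default_params,
                                               quiet_pulse):
        """The gap current entering compartment 3 equals the current
        leaving compartment 2 at every sample (ohmic antisymmetry)."""
        r = run_circuit(default_params, quiet_pulse)
        g = default_params.g_gap
        i_32 = g * (r.v[:, 3] - r.v[:, 2])
        i_23 = g * (r.v[:, 2] - r.v[:, 3])
        assert np.allclose(i_32 + i_23, 0.0)


class TestLatency:
    def test_identical_traces_give_zero(self):
        t = np.arange(0, 10, 0.01)
        v = -80 + 100 * np.exp(-((t - 3) / 0.3) ** 2)
        traces = np.stack([v, v, v, v], axis=1)
        r = SimulationResult(t=t, v=traces, s=np.zeros_like(t),
                             onsets=np.array([1.0]), isi_ms=100.0,
                             spike_times=[np.array([2.8])] * 4)
        from giantfiber.circuit import compute_latency
        assert compute_latency(r) == pytest.approx(0.0, abs=1e-9)

    def test_failure_flag_without_spike(self):
        t = np.arange(0, 10, 0.01)
        v = np.full_like(t, -80.0)
        traces = np.stack([v, v, v, v], axis=1)
        r = SimulationResult(t=t, v=traces, s=np.zeros_like(t),
                             onsets=np.array([1.0]), isi_ms=100.0,
                             spike_times=[np.empty(0)] * 4)
        from giantfiber.circuit import compute_latency
        assert compute_latency(r) is None

    def test_latency_shrinks_with_stronger_gap(self, default_params,
                                               quiet_pulse):
        weak = default_params.with_(
            gap_map=default_params.gap_map.with_(l_max=0.6), occupancy=12.0)
        strong = default_params.with_(
            gap_map=default_params.gap_map.with_(l_max=6.0), occupancy=12.0)
        lat_weak = run_circuit(weak, quiet_pulse).latency_ms
        lat_strong = run_circuit(strong, quiet_pulse).latency_ms
        assert lat_weak is not None and lat_strong is not None
        assert lat_strong < lat_weak


class TestResponseFrequency:
    def _result(self, spikes, onsets, isi):
        t = np.arange(0, 100, 0.01)
        v = np.zeros((t.size, 4))
        return SimulationResult(t=t, v=v, s=np.zeros_like(t),
                                onsets=np.asarray(onsets, dtype=float),
                                isi_ms=isi,
                                spike_times=[np.empty(0)] * 3
                                + [np.asarray(spikes, dtype=float)])

    def test_full_and_zero_following(self):
        onsets = 1.0 + 10.0 * np.arange(10)
        all_spikes = onsets + 1.0
        assert compute_response_frequency(
            self._result(all_spikes, onsets, 10.0)) == 100.0
        assert compute_response_frequency(
            self._result([], onsets, 10.0)) == 0.0

    def test_partial_following_counts_onsets(self):
        onsets = 1.0 + 10.0 * np.arange(10)
        # answers only after onsets 1, 2, 3, 5, 7 (0-based)
        spikes = onsets[[1, 2, 3, 5, 7]] + 2.0
        assert compute_response_frequency(
            self._result(spikes, onsets, 10.0)) == 50.0

    def test_double_spike_counts_once(self):
        onsets = [1.0, 11.0]
        spikes = [2.0, 3.5]  # both within the first window
        assert compute_response_frequency(
            self._result(spikes, onsets, 10.0)) == 50.0


class TestGenotypeSweep:
    def test_zero_occupancy_without_chem_is_silent(self):
        params = CircuitParams(chem_enabled=False)
        df = genotype_sweep([0.0], params, noise_sd=0.0, n_reps=1)
        assert df.loc[0, "response_pct_mean"] == 0.0

    def test_response_monotone_in_occupancy(self):
        df = genotype_sweep([1.0, 5.31, 9.04], noise_sd=0.0, n_reps=1)
        resp = df["response_pct_mean"].to_numpy()
        assert np.all(np.diff(resp) >= 0)
        assert resp[-1] > resp[0]

    def test_fixed_seed_reproducible(self):
        a = genotype_sweep([5.31], n_reps=1, seed=9)
        b = genotype_sweep([5.31], n_reps=1, seed=9)
        assert a.equals(b)

    def test_empty_occupancies_rejected(self):
        with pytest.raises(ValueError):
            genotype_sweep([])


class TestCalibration:
    def test_shipped_defaults_pass_their_own_criteria(self):
        crit = CalibrationCriteria()
        metrics = evaluate_criteria(CircuitParams(), 300.0, crit, n_reps=3)
        assert metrics["latency_high_ms"] < crit.latency_max_ms
        assert metrics["response_high_pct"] >= crit.response_min_pct
        assert metrics["response_low_pct"] <= crit.low_response_max_pct

    def test_contradictory_criteria_reported_infeasible(self):
        res = calibrate(CalibrationCriteria(latency_max_ms=-1.0))
        assert not res.feasible
        assert "reason" in res.metrics

    def test_calibration_deterministic(self):
        crit = CalibrationCriteria()
        a = calibrate(crit, amplitudes=(300.0,), g_axials=(6.0,),
                      l_maxes=(2.0,), n_reps=2, seed=5)
        b = calibrate(crit, amplitudes=(300.0,), g_axials=(6.0,),
                      l_maxes=(2.0,), n_reps=2, seed=5)
        assert a.feasible and b.feasible
        assert a.metrics == b.metrics
        assert a.pulse_amplitude == b.pulse_amplitude


def test_chem_removal_at_saturation_preserves_response(default_params,
                                                       quiet_train):
    """With saturated gap coupling, removing the chemical synapse leaves
    the response count unchanged (the electrical component dominates)."""
    sat = default_params.with_(occupancy=12.0)
    with_chem = run_circuit(sat, quiet_train)
    without = run_circuit(sat.with_(chem_enabled=False), quiet_train)
    assert with_chem.response_pct == without.response_pct
    assert len(with_chem.spike_times[3]) == len(without.spike_times[3])


def test_dt_convergence_of_latency(default_params):
    """Halving the integration step changes the noise-free single-pulse
    latency by less than 2%."""
    lat = {}
    for dt in (0.01, 0.005):
        r = run_circuit(default_params, single_pulse_spec(noise_sd=0.0,
                                                          dt=dt))
        lat[dt] = r.latency_ms
    assert lat[0.01] is not None and lat[0.005] is not None
    assert abs(lat[0.01] - lat[0.005]) / lat[0.005] < 0.02
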