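"""Ground-truth generator: trains, templates, rendering, synchrony."""

import numpy as np
import pytest
from scipy import stats

from stripmea import (
    BurstParams,
    SimulationConfig,
    detect_bursts,
    detect_network_bursts,
    generate_spike_train,
    inject_synchrony,
    make_template,
    render_recording,
    simulate_recording,
)
from stripmea.simulate import REFRACTORY_S, GroundTruthUnit, build_units
from stripmea.errors import ConfigurationError


class TestGenerateSpikeTrain:
    def test_zero_rate_gives_empty_train(self):
        assert generate_spike_train("irregular", 60.0, seed=0, rate_hz=0.0).size == 0

    def test_unknown_pattern_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_spike_train("tonic", 10.0)

    def test_times_strictly_increasing_within_duration(self):
        for pattern in ("bursting", "irregular", "slow"):
            t = generate_spike_train(pattern, 120.0, seed=11)
            assert np.all(np.diff(t) > 0)
            assert t.size == 0 or (t[0] >= 0 and t[-1] <= 120.0)

    def test_refractory_period_enforced(self):
        t = generate_spike_train("bursting", 300.0, seed=3, intra_burst_isi_ms=3.0)
        assert np.all(np.diff(t) >= REFRACTORY_S - 1e-12)

    def test_slow_train_poisson_count(self):
        # rate 0.05 Hz over 1800 s: ~90 spikes, within a generous Poisson band
        t = generate_spike_train("slow", 1800.0, seed=4, slow_rate_hz=0.05)
        lo, hi = stats.poisson.ppf([0.0005, 0.9995], 90)
        assert lo <= t.size <= hi

    def test_slow_rate_capped(self):
        with pytest.raises(ConfigurationError):
            generate_spike_train("slow", 10.0, slow_rate_hz=0.5)

    def test_irregular_rate_converges(self):
        t = generate_spike_train("irregular", 600.0, seed=5, rate_hz=5.0)
        n = 5.0 * 600.0
        assert abs(t.size - n) <= 4 * np.sqrt(n)

    def test_bursting_train_contains_qualifying_bursts(self):
        for seed in range(10):
            t = generate_spike_train("bursting", 120.0, seed=seed)
            assert len(detect_bursts(t)) >= 1

    def test_burst_rate_recovered_by_detector(self):
        # burst rate 2.3/min, 7.4 spikes/burst over 1800 s: the downstream
        # detector recovers the configured rate within the Poisson 95% band
        t = generate_spike_train(
            "bursting", 1800.0, seed=6,
            burst_rate_per_min=2.3, spikes_per_burst=7.4,
            intra_burst_isi_ms=14.0, baseline_rate_hz=0.0,
        )
        n = len(detect_bursts(t))
        expected = 2.3 * 30
        assert abs(n - expected) <= 1.96 * np.sqrt(expected)

    def test_determinism(self):
        a = generate_spike_train("bursting", 60.0, seed=42)
        b = generate_spike_train("bursting", 60.0, seed=42)
        assert np.array_equal(a, b)


class TestMakeTemplate:
    @pytest.mark.parametrize("ptp", [50.0, 80.0, 100.0])
    def test_ptp_and_length(self, ptp):
        t = make_template(ptp, 30000.0)
        assert t.size == 150
        assert np.ptp(t) == pytest.approx(ptp, rel=0.01)

    def test_extremum_at_one_ms(self):
        t = make_template(80.0, 30000.0)
        assert np.argmax(np.abs(t)) == 30  # 1 ms at 30 kHz

    def test_zero_mean(self):
        t = make_template(80.0, 30000.0)
        assert abs(t.mean()) < 1e-9

    def test_polarity(self):
        neg = make_template(60.0, polarity="negative_first")
        pos = make_template(60.0, polarity="positive_first")
        assert neg[30] < 0 < pos[30]

    def test_nonpositive_amplitude_rejected(self):
        with pytest.raises(ConfigurationError):
            make_template(0.0)


class TestRenderRecording:
    def _unit(self, electrode="E1", times=(0.5,), ptp=80.0):
        return GroundTruthUnit(
            unit_id=f"{electrode}-U1",
            electrode_id=electrode,
            pattern="irregular",
            spike_times=np.array(times),
            template=make_template(ptp),
        )

    def test_noise_only_trace_has_requested_sd(self):
        cfg = SimulationConfig(duration=10.0, n_strips=1, electrodes_per_strip=2,
                               noise_sd=5.0, seed=1)
        rec, truth = render_recording([], cfg)
        assert truth.empty
        for ch in rec.samples:
            assert ch.std() == pytest.approx(5.0, rel=0.02)

    def test_noiseless_rendering_preserves_template_ptp(self):
        cfg = SimulationConfig(duration=2.0, n_strips=1, electrodes_per_strip=1,
                               noise_sd=0.0, seed=1)
        unit = self._unit(times=(0.3, 0.9, 1.5), ptp=73.0)
        rec, truth = render_recording([unit], cfg)
        x = rec.samples[0]
        assert truth.shape[0] == 3
        for t in unit.spike_times:
            i = round(t * 30000)
            seg = x[i - 30 : i + 120]
            assert np.ptp(seg) == pytest.approx(73.0, rel=0.01)

    def test_unknown_electrode_rejected(self):
        cfg = SimulationConfig(duration=1.0, n_strips=1, electrodes_per_strip=1)
        with pytest.raises(ConfigurationError):
            render_recording([self._unit(electrode="E99")], cfg)

    def test_determinism_bit_identical(self):
        cfg = SimulationConfig(duration=3.0, n_strips=1, electrodes_per_strip=2, seed=9)
        rec1, truth1 = render_recording(build_units(cfg), cfg)
        rec2, truth2 = render_recording(build_units(cfg), cfg)
        assert np.array_equal(rec1.samples, rec2.samples)
        assert truth1.equals(truth2)

    def test_edge_spikes_clipped_not_fatal(self):
        cfg = SimulationConfig(duration=1.0, n_strips=1, electrodes_per_strip=1,
                               noise_sd=0.0)
        unit = self._unit(times=(0.0001, 0.9999))
        rec, _ = render_recording([unit], cfg)
        assert np.isfinite(rec.samples).all()


class TestInjectSynchrony:
    def _bursty_units(self, n=4, duration=120.0):
        units = []
        for k in range(n):
            t = generate_spike_train("bursting", duration, seed=100 + k,
                                     burst_rate_per_min=6.0, baseline_rate_hz=0.0)
            units.append(
                GroundTruthUnit(
                    unit_id=f"E{k + 1}-U1",
                    electrode_id=f"E{k + 1}",
                    pattern="bursting",
                    spike_times=t,
                    template=make_template(80.0),
                )
            )
        return units

    def test_fraction_zero_is_identity(self):
        units = self._bursty_units()
        assert inject_synchrony(units, 0.0, seed=0) is units

    def test_spike_counts_preserved(self):
        units = self._bursty_units()
        out = inject_synchrony(units, 1.0, jitter_ms=5.0, seed=1)
        for a, b in zip(units, out):
            assert b.spike_times.size == a.spike_times.size
            assert np.all(np.diff(b.spike_times) > 0)

    def test_full_synchrony_detected_as_network_bursts(self):
        units = self._bursty_units(n=4)
        out = inject_synchrony(units, 1.0, jitter_ms=5.0, seed=2)
        trains = {u.electrode_id: u.spike_times for u in out}
        events = detect_network_bursts(trains, BurstParams(network_fraction=0.5),
                                       frame_duration=120.0)
        assert len(events) >= 1
        assert max(e.n_electrodes for e in events) >= 3  # >= 75% of 4 electrodes

    def test_half_synchrony_moves_about_half_the_bursts(self):
        units = self._bursty_units(n=2, duration=600.0)
        out = inject_synchrony(units, 0.5, jitter_ms=5.0, seed=3)
        ref_onsets = np.array([b.start for b in detect_bursts(out[0].spike_times)])
        moved = detect_bursts(out[1].spike_times)
        near = sum(
            np.min(np.abs(ref_onsets - b.start)) < 0.05 for b in moved
        )
        frac = near / len(moved)
        assert 0.25 <= frac <= 0.85


class TestSimulateRecording:
    def test_bundle_is_deterministic(self):
        cfg = SimulationConfig(duration=2.0, n_strips=1, electrodes_per_strip=2, seed=5)
        rec1, _, truth1 = simulate_recording(cfg)
        rec2, _, truth2 = simulate_recording(cfg)
        assert np.array_equal(rec1.samples, rec2.samples)
        assert truth1.equals(truth2)

    def test_layout_matches_config(self):
        cfg = SimulationConfig(duration=1.0, n_strips=2, electrodes_per_strip=3, seed=0)
        rec, units, _ = simulate_recording(cfg)
        assert rec.n_channels == 6
        assert len(units) == 6 * cfg.units_per_electrode
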