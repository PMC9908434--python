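"""Tests for reverse-correlation RF mapping, PSTHs, and latency search."""

import numpy as np
import pytest

from ocuphys.errors import AnalysisError, InputError
from ocuphys.rf_mapping import (SpikeTrain, StimulusEvent, StimulusGrid,
                                estimate_latency, psth, reverse_correlate_rf,
                                rf_center)
from ocuphys.synth import NeuronSpec, SynthConfig, simulate_rf_events, simulate_spikes


def brute_force_rf(spikes, events, grid, latency_ms, min_reps=5):
    """Independent per-presentation tally of the reverse correlation."""
    sp = spikes.spikes
    dt = grid.patch_duration_ms
    rates = np.full((grid.n_rows, grid.n_cols), np.nan)
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            evs = [e for e in events if e.row == r and e.col == c]
            if len(evs) < min_reps:
                continue
            total = 0
            for e in evs:
                lo = e.t_onset + latency_ms
                total += int(np.sum((sp >= lo) & (sp < lo + dt)))
            rates[r, c] = total * (1000.0 / dt) / len(evs)
    return rates


def events_for_cell(row, col, n, dt=50.0, gap=500.0):
    return [StimulusEvent(row=row, col=col, t_onset=1000.0 + i * gap,
                          duration_ms=dt) for i in range(n)]


class TestReverseCorrelateRF:
    def test_unit_normalization_hand_example(self, grid):
        """5 presentations, 50 ms windows, 10 spikes total:
        C = (1/5)(1000/50)*10 = 40 Hz exactly."""
        events = events_for_cell(2, 3, 5)
        spikes = []
        for i, e in enumerate(events):
            for j in range(2):  # 2 spikes per shifted window -> 10 total
                spikes.append(e.t_onset + 40.0 + 10.0 * j + 1.0)
        m = reverse_correlate_rf(SpikeTrain(0, np.sort(spikes)), events, grid,
                                 latency_ms=40.0)
        assert m.rates[2, 3] == 40.0

    def test_zero_spikes_all_defined_cells_zero(self, grid):
        events = events_for_cell(0, 0, 6)
        m = reverse_correlate_rf(SpikeTrain(0, np.empty(0)), events, grid)
        assert m.rates[0, 0] == 0.0
        assert np.isnan(m.rates[1, 1])  # unstimulated cell undefined

    def test_matches_brute_force_oracle_exactly(self, grid, rng):
        for _ in range(10):
            events = [StimulusEvent(row=int(rng.integers(6)),
                                    col=int(rng.integers(6)),
                                    t_onset=float(t))
                      for t in np.sort(rng.uniform(0, 20000, 150))]
            spikes = SpikeTrain(0, np.sort(rng.uniform(0, 21000, 400)))
            lat = float(rng.uniform(0, 80))
            m = reverse_correlate_rf(spikes, events, grid, latency_ms=lat,
                                     min_reps=2)
            oracle = brute_force_rf(spikes, events, grid, lat, min_reps=2)
            np.testing.assert_array_equal(m.rates, oracle)

    def test_time_shift_invariance(self, grid, rng):
        events = [StimulusEvent(row=int(rng.integers(6)),
                                col=int(rng.integers(6)), t_onset=float(t))
                  for t in np.sort(rng.uniform(0, 10000, 100))]
        spikes = np.sort(rng.uniform(0, 11000, 300))
        m1 = reverse_correlate_rf(SpikeTrain(0, spikes), events, grid,
                                  min_reps=1)
        k = 12345.0
        shifted = [StimulusEvent(e.row, e.col, e.t_onset + k) for e in events]
        m2 = reverse_correlate_rf(SpikeTrain(0, spikes + k), shifted, grid,
                                  min_reps=1)
        np.testing.assert_array_equal(m1.rates, m2.rates)

    def test_homogeneous_poisson_flat_within_standard_error(self, grid, rng):
        rate = 50.0
        reps = 60
        events = []
        t = 0.0
        for i in range(reps):
            for r in range(6):
                for c in range(6):
                    events.append(StimulusEvent(r, c, t))
                    t += 50.0
        span = t + 200.0
        n = rng.poisson(rate * span / 1000.0)
        spikes = SpikeTrain(0, np.sort(rng.uniform(0, span, n)))
        m = reverse_correlate_rf(spikes, events, grid, latency_ms=0.0)
        se = np.sqrt(rate / (reps * 0.05))
        assert np.all(np.abs(m.rates - rate) < 3 * se)

    def test_variance_shrinks_with_repetitions(self, grid, rng):
        """Stimulus-independence null: map variance falls as reps grow."""
        def var_at(reps, seed):
            r = np.random.default_rng(seed)
            events = []
            t = 0.0
            for _ in range(reps):
                for row in range(6):
                    for c in range(6):
                        events.append(StimulusEvent(row, c, t))
                        t += 50.0
            spikes = SpikeTrain(0, np.sort(r.uniform(0, t + 100,
                                                     r.poisson(30 * t / 1000))))
            m = reverse_correlate_rf(spikes, events, grid, latency_ms=0.0)
            return np.var(m.rates)
        assert var_at(80, 3) < var_at(5, 3)

    def test_errors(self, grid):
        with pytest.raises(InputError, match="no stimulus events"):
            reverse_correlate_rf(SpikeTrain(0, np.empty(0)), [], grid)
        with pytest.raises(InputError):
            SpikeTrain(0, np.array([3.0, 1.0]))  # unsorted


class TestRFCenter:
    def test_single_hot_cell(self, grid):
        rates = np.zeros((6, 6))
        rates[2, 3] = 80.0
        m = type("M", (), {})
        from ocuphys.rf_mapping import RFMap
        m = RFMap(rates=rates, n_per_cell=np.full((6, 6), 10),
                  latency_ms=40, grid=grid)
        assert rf_center(m) == pytest.approx(grid.cell_center(2, 3))

    def test_two_equal_adjacent_cells_midpoint(self, grid):
        from ocuphys.rf_mapping import RFMap
        rates = np.zeros((6, 6))
        rates[2, 3] = rates[2, 4] = 80.0
        m = RFMap(rates=rates, n_per_cell=np.full((6, 6), 10),
                  latency_ms=40, grid=grid)
        cx, cy = rf_center(m)
        x1, y1 = grid.cell_center(2, 3)
        x2, y2 = grid.cell_center(2, 4)
        assert cx == pytest.approx((x1 + x2) / 2)
        assert cy == pytest.approx(y1)

    def test_flat_map_rejected(self, grid):
        from ocuphys.rf_mapping import RFMap
        m = RFMap(rates=np.full((6, 6), 20.0),
                  n_per_cell=np.full((6, 6), 10), latency_ms=40, grid=grid)
        with pytest.raises(AnalysisError, match="no RF detected"):
            rf_center(m)

    def test_synthetic_neuron_center_within_half_pitch(self, grid):
        cfg = SynthConfig(cal_epoch_s=0.0, free_viewing_s=0.0, rf_reps=12)
        events = simulate_rf_events(cfg, seed=31)
        trains = simulate_spikes(cfg, events, [], seed=31)
        m = reverse_correlate_rf(trains[0], events, cfg.grid, latency_ms=40.0)
        cx, cy = rf_center(m)
        tx, ty = cfg.neurons[0].rf_center
        assert np.hypot(cx - tx, cy - ty) < grid.pitch_x / 2


class TestPSTH:
    def test_zero_spikes_zero_rate(self):
        p = psth(SpikeTrain(0, np.empty(0)), [100.0, 200.0])
        assert np.all(p.rate_hz == 0.0)

    def test_flat_poisson_recovers_rate(self, rng):
        rate = 30.0
        span = 600000.0
        spikes = SpikeTrain(0, np.sort(
            rng.uniform(0, span, rng.poisson(rate * span / 1000.0))))
        aligns = rng.uniform(1000, span - 1000, 500)
        p = psth(spikes, aligns, window=(-200, 200), bin_ms=20)
        assert abs(p.rate_hz.mean() - rate) < 3 * np.sqrt(
            rate / (500 * 0.4))

    def test_psth_reproduces_rf_rate_algebraically(self, grid, rng):
        """Summing the aligned PSTH over [t', t'+dt) for one cell equals the
        reverse-correlation rate for that cell, bin for bin."""
        events = events_for_cell(1, 1, 20)
        spikes = SpikeTrain(0, np.sort(rng.uniform(500, 12000, 800)))
        lat = 40.0
        m = reverse_correlate_rf(spikes, events, grid, latency_ms=lat)
        p = psth(spikes, [e.t_onset for e in events],
                 window=(lat, lat + 50.0), bin_ms=50.0)
        assert p.rate_hz[0] == pytest.approx(m.rates[1, 1])

    def test_empty_align_times_rejected(self):
        with pytest.raises(InputError):
            psth(SpikeTrain(0, np.empty(0)), [])


class TestEstimateLatency:
    def _sim(self, latency, seed, reps=20):
        neuron = NeuronSpec(latency_ms=latency)
        cfg = SynthConfig(cal_epoch_s=0.0, free_viewing_s=0.0, rf_reps=reps,
                          neurons=(neuron,))
        events = simulate_rf_events(cfg, seed=seed)
        trains = simulate_spikes(cfg, events, [], seed=seed)
        return trains[0], events, cfg.grid

    def test_embedded_latency_recovered(self):
        spikes, events, grid = self._sim(40.0, seed=41)
        est = estimate_latency(spikes, events, grid)
        assert not est.flagged
        assert abs(est.latency_ms - 40.0) <= 5.0

    def test_zero_latency_recovered(self):
        spikes, events, grid = self._sim(0.0, seed=42)
        est = estimate_latency(spikes, events, grid)
        assert not est.flagged
        assert est.latency_ms <= 5.0

    def test_stimulus_independent_spiking_flagged(self, rng):
        cfg = SynthConfig(cal_epoch_s=0.0, free_viewing_s=0.0, rf_reps=20,
                          neurons=(NeuronSpec(rf_peak_hz=0.0,
                                              burst_peak_hz=0.0),))
        events = simulate_rf_events(cfg, seed=43)
        trains = simulate_spikes(cfg, events, [], seed=43)
        est = estimate_latency(trains[0], events, cfg.grid)
        assert est.flagged
        assert est.latency_ms == est.default_ms == 40.0
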