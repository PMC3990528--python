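"""LFP, up/down-state detection and neuron-state classification."""

import numpy as np
import pandas as pd
import pytest

from rewirenet import (ActivityThresholds, LfpTrace, SimulationResult,
                       classify_highly_active, classify_neuron_states,
                       class_rate_and_conductance_summary, compute_lfp,
                       derive_low_threshold, detect_up_down_states,
                       functional_in_degree)
from rewirenet.balance import HIGH, LOW, NEUTRAL
from rewirenet.experiments import generate_fixture_network
from rewirenet.topology import ConfigurationError


def make_result(n_nodes=2, duration=100.0, spikes=(), currents=None, v=None,
                dt=1.0):
    """Minimal hand-constructed SimulationResult for analysis tests."""
    times = np.array([t for t, _ in spikes], dtype=float)
    ids = np.array([i for _, i in spikes], dtype=np.int64)
    order = np.argsort(times, kind="stable")
    n_bins = int(duration / dt)
    return SimulationResult(
        spike_times=times[order], spike_ids=ids[order],
        lfp=np.zeros(n_bins), lfp_dt=dt, trace_dt=dt,
        trace_t=np.arange(n_bins) * dt,
        v=v, current_traces=currents,
        meta={"n_nodes": n_nodes, "duration": duration, "burn_in": 0.0,
              "dt": 0.05})


class TestLfp:
    def test_crafted_constant_currents(self):
        n_bins = 100
        cur = {"ext": np.tile([2.0, 1.0], (n_bins, 1)),
               "exc": np.tile([-3.0, 0.0], (n_bins, 1)),
               "inh": np.zeros((n_bins, 2))}
        res = make_result(currents=cur)
        lfp = compute_lfp(res, constant=1.0)
        assert np.allclose(lfp.values, 6.0)
        assert compute_lfp(res, constant=2.5).values[0] == pytest.approx(15.0)

    def test_zero_currents(self):
        cur = {k: np.zeros((50, 2)) for k in ("ext", "exc", "inh")}
        res = make_result(duration=50.0, currents=cur)
        assert np.all(compute_lfp(res).values == 0.0)

    def test_nonnegative_from_simulation(self, short_run):
        lfp = compute_lfp(short_run)
        assert lfp.values.min() >= 0.0

    def test_missing_traces_raises(self):
        res = make_result()
        res.lfp = np.array([])
        with pytest.raises(ConfigurationError):
            compute_lfp(res)


def two_level_trace(low=1.0, high=10.0, block_ms=500, n_blocks=6, dt=1.0,
                    jitter=0.02, seed=0):
    rng = np.random.default_rng(seed)
    vals, truth = [], []
    for b in range(n_blocks):
        level = high if b % 2 else low
        n = int(block_ms / dt)
        vals.append(np.full(n, level) * (1 + jitter * rng.standard_normal(n)))
        truth.append(np.full(n, b % 2, dtype=bool))
    return (LfpTrace(np.abs(np.concatenate(vals)), dt),
            np.concatenate(truth))


class TestStateDetector:
    def test_constant_trace_single_downstate(self):
        states = detect_up_down_states(LfpTrace(np.full(2000, 3.0), 1.0))
        assert (states.intervals["state"] == "down").all()
        assert len(states.intervals) == 1

    def test_two_level_trace_boundaries_within_fine_window(self):
        lfp, truth = two_level_trace()
        states = detect_up_down_states(lfp)
        edges_true = np.flatnonzero(np.diff(truth.astype(int))) + 1
        ups = states.intervals[states.intervals.state == "up"]
        assert len(ups) == 3
        found = np.sort(np.concatenate([ups.start_ms.to_numpy(),
                                        ups.end_ms.to_numpy()]))
        for e in edges_true:
            assert np.min(np.abs(found - e)) <= 5.0

    def test_durations_recovered(self):
        lfp, _ = two_level_trace()
        states = detect_up_down_states(lfp)
        for d in states.durations("up"):
            assert abs(d - 500.0) <= 5.0
        for d in states.durations("down"):
            assert abs(d - 500.0) <= 5.0

    def test_intervals_tile_window(self):
        lfp, _ = two_level_trace()
        states = detect_up_down_states(lfp)
        iv = states.intervals
        assert iv.start_ms.iloc[0] == 0.0
        assert iv.end_ms.iloc[-1] == pytest.approx(lfp.duration)
        assert np.allclose(iv.end_ms.to_numpy()[:-1], iv.start_ms.to_numpy()[1:])
        assert iv.duration_ms.sum() == pytest.approx(lfp.duration)
        states_alt = iv.state.to_numpy()
        assert (states_alt[1:] != states_alt[:-1]).all()

    def test_raising_k_sd_never_adds_upstate_time(self):
        lfp, _ = two_level_trace(jitter=0.3, seed=3)
        prev = np.inf
        for k in (1.0, 2.0, 3.0, 5.0):
            states = detect_up_down_states(lfp, k_sd=k)
            up = states.intervals.query("state=='up'").duration_ms.sum()
            assert up <= prev + 1e-9
            prev = up

    def test_scale_invariance(self):
        lfp, _ = two_level_trace(seed=5)
        a = detect_up_down_states(lfp).intervals
        b = detect_up_down_states(LfpTrace(lfp.values * 37.0, 1.0)).intervals
        pd.testing.assert_frame_equal(
            a.drop(columns="geo_mean"), b.drop(columns="geo_mean"))
        assert np.allclose(b.geo_mean, a.geo_mean * 37.0, rtol=1e-9)

    def test_geo_mean_up_exceeds_down(self):
        lfp, _ = two_level_trace(seed=2)
        states = detect_up_down_states(lfp)
        iv = states.intervals
        assert iv[iv.state == "up"].geo_mean.min() > \
            iv[iv.state == "down"].geo_mean.max()

    def test_merge_gap_joins_nearby_upstates(self):
        v = np.full(3000, 1.0)
        v[1000:1200] = 10.0
        v[1320:1520] = 10.0  # 120-ms gap, wider than the coarse window
        states2 = detect_up_down_states(LfpTrace(v, 1.0))
        assert (states2.intervals.state == "up").sum() == 2
        states = detect_up_down_states(LfpTrace(v, 1.0), merge_gap=150.0)
        assert (states.intervals.state == "up").sum() == 1

    def test_too_short_trace_rejected(self):
        with pytest.raises(ConfigurationError):
            detect_up_down_states(LfpTrace(np.ones(50), 1.0))


class TestNeuronStates:
    def trace_result(self):
        v = np.zeros((100, 3))
        v[:, 2] = -8.0  # crafted potential below the low threshold
        return make_result(n_nodes=3, duration=100.0,
                           spikes=[(40.0, 0)], v=v)

    def test_high_low_neutral_rules(self):
        res = self.trace_result()
        states = classify_neuron_states(res, low_v_threshold=-5.0)
        # node 0 spiked at 40 ms: high for bins in (40, 55] ms
        assert states.labels[50, 0] == HIGH
        assert states.labels[56, 0] == NEUTRAL
        assert states.labels[30, 0] == NEUTRAL
        # node 1 silent at rest: neutral throughout
        assert (states.labels[:, 1] == NEUTRAL).all()
        # node 2 below threshold: low
        assert (states.labels[:, 2] == LOW).all()

    def test_high_overrides_low(self):
        v = np.full((100, 1), -8.0)
        res = make_result(n_nodes=1, duration=100.0, spikes=[(40.0, 0)], v=v)
        states = classify_neuron_states(res, low_v_threshold=-5.0)
        assert states.labels[45, 0] == HIGH
        assert states.labels[70, 0] == LOW

    def test_occupancy_sums_to_one(self):
        states = classify_neuron_states(self.trace_result(), -5.0)
        occ = states.occupancy()
        assert sum(occ.values()) == pytest.approx(1.0)

    def test_low_threshold_from_random_run(self, short_run):
        thr = derive_low_threshold(short_run)
        v = short_run.v[100:]
        assert thr == pytest.approx(v.mean() - 2 * v.std())


class TestHighlyActive:
    def test_strict_threshold_rules(self):
        ei = np.array([0, 0, 1, 1])
        spikes = ([(t, 0) for t in np.linspace(1, 999, 5)]       # 5 sp/s E
                  + [(t, 2) for t in np.linspace(1, 999, 30)]    # 30 sp/s I
                  + [(t, 3) for t in np.linspace(1, 999, 31)])   # 31 sp/s I
        res = make_result(n_nodes=4, duration=1000.0, spikes=spikes)
        flags = classify_highly_active(res, (0.0, 1000.0), ei)
        assert flags.tolist() == [True, False, False, True]

    def test_zero_length_interval_rejected(self):
        res = make_result()
        with pytest.raises(ConfigurationError):
            classify_highly_active(res, (10.0, 10.0), np.array([0, 0]))


class TestFunctionalInDegree:
    def test_all_active_equals_constant_indegree(self, scaled_random):
        flags = np.ones(scaled_random.n_nodes, dtype=bool)
        k = functional_in_degree(scaled_random, flags,
                                 origin_mask=scaled_random.exc_mask)
        assert (k == 160).all()

    def test_no_active_zeroes(self, scaled_random):
        flags = np.zeros(scaled_random.n_nodes, dtype=bool)
        assert (functional_in_degree(scaled_random, flags) == 0).all()

    def test_crafted_network_hand_enumeration(self):
        net = generate_fixture_network("toy_ffi")  # E1->E0, E1->I2, I2->E0
        flags = np.array([False, True, True])
        k = functional_in_degree(net, flags)
        assert k.tolist() == [2, 0, 1]
        k_e = functional_in_degree(net, flags, origin_mask=net.exc_mask)
        assert k_e.tolist() == [1, 0, 1]


class TestClassSummary:
    def test_crafted_raster_exact_rates(self, scaled_rewired):
        spikes = [(t, 0) for t in np.linspace(10, 990, 10)]
        res = make_result(n_nodes=scaled_rewired.n_nodes, duration=1000.0,
                          spikes=spikes)
        table = class_rate_and_conductance_summary(res, scaled_rewired,
                                                   interval=(0.0, 1000.0))
        cls0 = scaled_rewired.class_name(0)
        row = table[table["class"] == cls0].iloc[0]
        assert row.mean_rate == pytest.approx(10.0 / row.n)
        assert table[table["class"] != cls0].mean_rate.eq(0).all()

    def test_unrewired_lattice_only_class1(self, scaled_lattice):
        res = make_result(n_nodes=scaled_lattice.n_nodes, duration=100.0)
        table = class_rate_and_conductance_summary(res, scaled_lattice)
        assert sorted(table["class"]) == ["E1", "I1"]
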