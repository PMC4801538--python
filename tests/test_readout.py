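import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spadflim import (
    DecayMap,
    PhotonEvent,
    SensorConfig,
    allocate_tdcs,
    apply_dead_time,
    encode_positions_and_validate,
    generate_photon_arrivals,
    quantize_time,
    readout_exposure,
)
from spadflim.readout import DetectedEvent


def ev(t, row=0, col=0, pulse=0):
    return PhotonEvent(pulse_index=pulse, row=row, col=col, t=t)


def brute_force_dead_time(times, tp, mode):
    """Independent per-event loop implementation of the OR-tree merge."""
    accepted = []
    for i, t in enumerate(times):
        if i == 0:
            accepted.append(i)
            continue
        ref = times[i - 1] if mode == "paralyzable" else times[accepted[-1]]
        if t - ref >= tp:
            accepted.append(i)
    return accepted


class TestDeadTime:
    def test_single_event_accepted(self):
        assert apply_dead_time([ev(3.0)], 0.36) == [ev(3.0)]

    def test_interval_of_exactly_tp_survives(self):
        events = [ev(1.0), ev(1.36, col=1)]
        assert apply_dead_time(events, 0.36) == events
        assert apply_dead_time(events, 0.36, "nonparalyzable") == events

    def test_merging_cascade_example(self):
        """Events at 0, 0.2, 0.5, 1.0 ns with t_p = 0.36 ns."""
        events = [ev(0.0), ev(0.2, col=1), ev(0.5, col=2), ev(1.0, col=3)]
        # paralyzable: 0.2 merges with 0; 0.5 is only 0.3 after 0.2, still
        # inside the extended OR pulse; 1.0 clears it
        para = apply_dead_time(events, 0.36, "paralyzable")
        assert [e.t for e in para] == [0.0, 1.0]
        # nonparalyzable: the window re-arms only on acceptance
        nonpara = apply_dead_time(events, 0.36, "nonparalyzable")
        assert [e.t for e in nonpara] == [0.0, 0.5, 1.0]

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError):
            apply_dead_time([ev(2.0), ev(1.0, col=1)], 0.36)

    @settings(deadline=None, max_examples=200)
    @given(
        times=st.lists(
            st.floats(0.0, 99.0, allow_nan=False, width=32), min_size=0, max_size=12
        ),
        tp=st.floats(0.0, 2.0, allow_nan=False),
        mode=st.sampled_from(["paralyzable", "nonparalyzable"]),
    )
    def test_matches_brute_force_loop(self, times, tp, mode):
        times = sorted(times)
        events = [ev(t, col=i % 8) for i, t in enumerate(times)]
        got = [e.t for e in apply_dead_time(events, tp, mode)]
        want = [times[i] for i in brute_force_dead_time(times, tp, mode)]
        assert got == want


class TestAllocation:
    def test_capacity_not_exceeded_keeps_all(self):
        events = [ev(float(i), col=i) for i in range(4)]
        assert allocate_tdcs(events, 4) == events

    def test_earliest_kept_when_over_capacity(self):
        events = [ev(float(i), col=i) for i in range(6)]
        assert allocate_tdcs(events, 4) == events[:4]


class TestQuantization:
    def test_origin_maps_to_code_zero(self, config):
        assert quantize_time(0.0, config) == 0

    def test_code_above_range_discarded(self, config):
        """t = 95 ns -> code 973 >= 950 -> outside the quantized range."""
        assert int(np.floor(95_000 / 97.6)) == 973
        assert quantize_time(95.0, config) is None

    def test_negative_time_rejected(self, config):
        with pytest.raises(ValueError):
            quantize_time(-0.1, config)

    def test_uniform_times_give_uniform_codes(self, config, rng):
        from scipy import stats

        t = rng.uniform(0, config.quantized_range_ns, 200_000)
        codes = np.floor(t / config.h_ns).astype(int)
        assert codes.max() < config.tdc_code_max
        counts = np.bincount(codes // 50, minlength=19)  # 19 coarse bins
        expected = np.full(19, len(t) / 19.0)
        res = stats.chisquare(counts, expected)
        assert res.pvalue > 0.01


class TestEncoder:
    def test_single_event_codes(self, config):
        d = DetectedEvent(pulse_index=0, row=3, col=5, t=1.0, code=10)
        frame = encode_positions_and_validate([d], config)
        assert frame.row_codes == (3,) and frame.col_codes == (5,)
        assert frame.valid
        assert len(frame.time_codes) == len(frame.row_codes) == len(frame.col_codes)

    def test_hold_time_zero_always_valid(self, config):
        events = [
            DetectedEvent(0, 0, 0, 1.0, 10),
            DetectedEvent(0, 0, 1, 1.05, 10),
        ]
        assert encode_positions_and_validate(events, config).valid

    def test_close_events_invalidate_frame(self, config):
        cfg = config.replace(encoder_hold_time=200.0)  # 0.2 ns
        events = [
            DetectedEvent(0, 0, 0, 1.0, 10),
            DetectedEvent(0, 0, 1, 1.1, 11),
        ]
        frame = encode_positions_and_validate(events, cfg)
        assert not frame.valid
        from spadflim.readout import INVALID_CODE

        assert frame.row_codes[0] == INVALID_CODE


def brute_force_readout(stream, config):
    """Compose the single-group reference operations event by event."""
    recorded = []
    losses = dict(dead=0, tdc=0, overflow=0, invalid=0)
    groups = {}
    for e in stream:
        sa = int(config.subarray_of(e.row, e.col))
        groups.setdefault((e.pulse_index, sa), []).append(e)
    for key in sorted(groups):
        evs = sorted(groups[key], key=lambda e: (e.t, e.row, e.col))
        kept = apply_dead_time(evs, config.tp_ns, config.dead_time_mode)
        losses["dead"] += len(evs) - len(kept)
        alloc = allocate_tdcs(kept, config.n_tdc_per_subarray)
        losses["tdc"] += len(kept) - len(alloc)
        quantized = []
        for e in alloc:
            code = quantize_time(e.t, config)
            if code is None:
                losses["overflow"] += 1
            else:
                quantized.append(
                    DetectedEvent(e.pulse_index, e.row, e.col, e.t, code)
                )
        if not quantized:
            continue
        frame = encode_positions_and_validate(quantized, config)
        if frame.valid:
            recorded.extend((e.pulse_index, e.row, e.col, e.code) for e in quantized)
        else:
            losses["invalid"] += len(quantized)
    return recorded, losses


class TestExposureReadout:
    def test_empty_stream(self, config):
        decay = DecayMap.uniform(config, 10.5, p0=0.0)
        stream = generate_photon_arrivals(config, decay, 100, seed=0)
        result = readout_exposure(stream, config)
        assert len(result) == 0
        assert result.losses.total_lost == 0

    def test_no_contention_no_losses(self, one_subarray_config):
        """One event per pulse cannot merge, exhaust TDCs or be invalid."""
        cfg = one_subarray_config
        decay = DecayMap.uniform(cfg, 5.0, p0=0.0)
        tau = np.full((8, 8), 5.0)
        p0 = np.zeros((8, 8))
        p0[2, 3] = 1.0
        stream = generate_photon_arrivals(cfg, DecayMap(tau, p0), 5000, seed=1)
        result = readout_exposure(stream, cfg)
        assert result.losses.dead_time_merged == 0
        assert result.losses.tdc_exhausted == 0
        assert result.losses.invalid_frame == 0

    def test_event_conservation(self, config):
        decay = DecayMap.uniform(config, 5.0, p0=0.05)
        stream = generate_photon_arrivals(config, decay, 20_000, seed=2)
        result = readout_exposure(stream, config)
        L = result.losses
        assert L.generated == len(stream)
        assert L.generated == L.recorded + L.total_lost

    @pytest.mark.parametrize("mode", ["paralyzable", "nonparalyzable"])
    @pytest.mark.parametrize("hold_ps", [0.0, 500.0])
    def test_vectorized_pipeline_matches_brute_force(self, mode, hold_ps):
        """Exact agreement with the per-event reference loop."""
        cfg = SensorConfig(
            dead_time_mode=mode, encoder_hold_time=hold_ps, photon_rate_P0=0.15
        )
        decay = DecayMap.uniform(cfg, 3.0)
        stream = generate_photon_arrivals(cfg, decay, 400, seed=3)
        result = readout_exposure(stream, cfg)
        got = sorted(
            zip(
                result.pulse_index[result.valid],
                result.row[result.valid],
                result.col[result.valid],
                result.code[result.valid],
            )
        )
        want, losses = brute_force_readout(stream, cfg)
        assert got == sorted(want)
        assert result.losses.dead_time_merged == losses["dead"]
        assert result.losses.tdc_exhausted == losses["tdc"]
        assert result.losses.code_overflow == losses["overflow"]
        assert result.losses.invalid_frame == losses["invalid"]

    def test_data_rate_reduction(self, config):
        """At most 4 records per 64-pixel sub-array per pulse: 1/16 rate."""
        decay = DecayMap.uniform(config, 2.0, p0=0.3)
        stream = generate_photon_arrivals(config, decay, 2000, seed=4)
        result = readout_exposure(stream, config)
        key = result.pulse_index * config.n_subarrays + result.subarray
        counts = np.bincount((key - key.min()).astype(int))
        assert counts.max() <= config.n_tdc_per_subarray

    def test_recorded_count_monotone_in_dead_time_and_tdcs(self, config):
        decay = DecayMap.uniform(config, 5.0, p0=0.05)
        stream = generate_photon_arrivals(config, decay, 20_000, seed=5)
        rec = {}
        for tp in (0.0, 360.0, 2000.0):
            rec[tp] = readout_exposure(stream, config.replace(dead_time_tp=tp)).losses.recorded
        assert rec[0.0] >= rec[360.0] >= rec[2000.0]
        rec_tdc = {}
        for n in (1, 2, 4):
            rec_tdc[n] = readout_exposure(
                stream, config.replace(n_tdc_per_subarray=n)
            ).losses.recorded
        assert rec_tdc[4] >= rec_tdc[2] >= rec_tdc[1]

    def test_frames_round_trip(self, one_subarray_config):
        cfg = one_subarray_config.replace(photon_rate_P0=0.1)
        decay = DecayMap.uniform(cfg, 5.0)
        stream = generate_photon_arrivals(cfg, decay, 200, seed=6)
        result = readout_exposure(stream, cfg)
        frames = result.to_frames()
        assert sum(len(f.time_codes) for f in frames) == len(result)
        for f in frames:
            assert len(f.time_codes) == len(f.row_codes) == len(f.col_codes)
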