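"""Filtering, event detection, labeling, normalization, windowing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gaitphase as gp
from gaitphase.preprocess import EventKind, GaitEventSet


class TestLowpassFilter:
    def test_dc_gain_is_unity(self):
        x = np.full((200, 3), 3.7)
        y = gp.lowpass_filter(x, fs=100, cutoff=20)
        assert np.max(np.abs(y - 3.7)) < 1e-6

    def test_stopband_attenuation(self):
        """45 Hz tone through a 20 Hz 6th-order Butterworth is suppressed."""
        t = np.arange(2000) / 100.0
        x = np.sin(2 * np.pi * 45 * t)[:, None]
        y = gp.lowpass_filter(x, fs=100, cutoff=20)
        assert np.abs(y[200:-200]).max() < 0.05

    def test_passband_preserved(self):
        t = np.arange(2000) / 100.0
        x = np.sin(2 * np.pi * 1.0 * t)[:, None]
        y = gp.lowpass_filter(x, fs=100, cutoff=20)
        assert np.abs(y[100:-100] - x[100:-100]).max() < 0.01

    @pytest.mark.parametrize("cutoff", [50.0, 100.0, 0.0, -5.0])
    def test_nyquist_bound_enforced(self, cutoff):
        with pytest.raises(ValueError, match="Nyquist"):
            gp.lowpass_filter(np.zeros((100, 2)), fs=100, cutoff=cutoff)


class TestBinarizePressure:
    def test_all_zero_channel_stays_zero(self):
        assert not gp.binarize_pressure(np.zeros((10, 2))).any()

    def test_threshold_at_half_max(self):
        col = np.array([0, 0, 5, 6, 0], dtype=float)
        out = gp.binarize_pressure(np.stack([col, col], axis=1))
        np.testing.assert_array_equal(out[:, 0], [0, 0, 1, 1, 0])

    def test_constant_positive_channel_all_on(self):
        out = gp.binarize_pressure(np.full((5, 2), 2.0))
        assert out.all()

    def test_negative_pressure_rejected(self):
        with pytest.raises(ValueError):
            gp.binarize_pressure(np.array([[-1.0, 0.0]]))


class TestDetectEvents:
    def test_edges_to_events_on_imu_timeline(self):
        heel = [0, 1, 1, 1, 0, 0]
        meta = [0, 0, 1, 1, 1, 0]
        ev = gp.detect_events(np.stack([heel, meta], axis=1))
        assert list(ev) == [
            (2, EventKind.HEEL_STRIKE),
            (4, EventKind.TOE_STRIKE),
            (8, EventKind.HEEL_OFF),
            (10, EventKind.TOE_OFF),
        ]

    def test_all_zero_and_all_one_inputs_give_no_events(self):
        assert len(gp.detect_events(np.zeros((6, 2), dtype=int))) == 0
        assert len(gp.detect_events(np.ones((6, 2), dtype=int))) == 0

    def test_interior_violation_raises_with_index(self):
        # heel strikes twice with no heel-off; meta events in between make
        # the violation interior so it cannot be trimmed away
        heel = [0, 1, 1, 0, 1, 1, 1, 1, 0, 0]
        meta = [0, 0, 1, 1, 1, 0, 0, 1, 1, 0]
        with pytest.raises(ValueError, match="cyclic"):
            gp.detect_events(np.stack([heel, meta], axis=1))

    def test_leading_partial_cycle_trimmed(self):
        # stream starts mid-stance: first edges are HEEL_OFF / TOE_OFF
        heel = [1, 1, 0, 0, 0, 1, 1, 1]
        meta = [1, 1, 1, 0, 0, 0, 1, 1]
        ev = gp.detect_events(np.stack([heel, meta], axis=1))
        kinds = [k for _, k in ev]
        assert kinds == [EventKind.HEEL_OFF, EventKind.TOE_OFF, EventKind.HEEL_STRIKE, EventKind.TOE_STRIKE]

    def test_event_set_cyclic_order_validated(self):
        with pytest.raises(ValueError):
            GaitEventSet([(0, EventKind.HEEL_STRIKE), (5, EventKind.HEEL_OFF)])
        with pytest.raises(ValueError):
            GaitEventSet([(5, EventKind.HEEL_STRIKE), (5, EventKind.TOE_STRIKE)])


class TestLabelPhases:
    def test_enumerated_intervals(self):
        ev = GaitEventSet([
            (0, EventKind.HEEL_STRIKE), (10, EventKind.TOE_STRIKE),
            (20, EventKind.HEEL_OFF), (30, EventKind.TOE_OFF),
            (40, EventKind.HEEL_STRIKE),
        ])
        lab = gp.label_phases(ev, 45)
        expected = np.concatenate([
            np.full(10, 0), np.full(10, 1), np.full(10, 2), np.full(10, 3), np.full(5, -1)
        ])
        np.testing.assert_array_equal(lab, expected)

    def test_empty_events_all_undefined(self):
        np.testing.assert_array_equal(gp.label_phases(GaitEventSet([]), 5), [-1] * 5)

    def test_event_beyond_stream_rejected(self):
        ev = GaitEventSet([(0, EventKind.HEEL_STRIKE), (10, EventKind.TOE_STRIKE)])
        with pytest.raises(ValueError):
            gp.label_phases(ev, 10)

    def test_labels_only_between_first_and_last_event(self, small_recording):
        lab = small_recording.truth_labels
        idx = small_recording.truth_events.indices()
        assert (lab[: idx[0]] == -1).all()
        assert (lab[idx[-1] :] == -1).all()


class TestNormalizer:
    def test_zscore_affine_map(self):
        rng = np.random.default_rng(0)
        x = 5 + 2 * rng.standard_normal((5000, 1))
        stats = gp.fit_normalizer(x, "zscore")
        out = gp.apply_normalizer(np.array([[9.0]]), stats)
        assert abs(out[0, 0] - (9 - stats.loc[0]) / stats.scale[0]) < 1e-12
        assert abs(stats.loc[0] - 5) < 0.1 and abs(stats.scale[0] - 2) < 0.1

    def test_constant_channel_guarded(self):
        x = np.full((10, 2), 4.2)
        stats = gp.fit_normalizer(x, "zscore")
        assert np.abs(gp.apply_normalizer(x, stats)).max() < 1e-12
        assert (stats.scale == 1).all()

    def test_minmax_maps_to_unit_interval(self):
        x = np.array([[2.0], [4.0], [6.0]])
        out = gp.apply_normalizer(x, gp.fit_normalizer(x, "minmax"))
        np.testing.assert_allclose(out.ravel(), [0, 0.5, 1])

    def test_train_stats_reused_on_heldout(self):
        rng = np.random.default_rng(1)
        train, test = rng.standard_normal((100, 3)), rng.standard_normal((50, 3)) + 10
        stats = gp.fit_normalizer(train)
        out = gp.apply_normalizer(test, stats)
        # held-out data is shifted, not re-centered
        assert out.mean() > 5

    def test_refit_on_normalized_data_is_standard(self):
        rng = np.random.default_rng(2)
        x = 3 + 7 * rng.standard_normal((2000, 12))
        z = gp.apply_normalizer(x, gp.fit_normalizer(x))
        stats2 = gp.fit_normalizer(z)
        assert np.abs(stats2.loc).max() < 1e-10
        assert np.abs(stats2.scale - 1).max() < 1e-10


def brute_force_windows(stream, labels, Lw, s):
    """Independent reference slicer for window/label construction."""
    out = []
    T = len(stream)
    for i in range(0, T - Lw + 1, s):
        lab = labels[i + Lw - 1]
        if lab >= 0:
            out.append((stream[i : i + Lw], lab))
    return out


class TestMakeWindows:
    def test_single_window_edge(self):
        ws = gp.make_windows(np.zeros((50, 12)), np.full(50, 2), Lw=50)
        assert len(ws) == 1 and ws.labels[0] == 2

    def test_window_count_without_filtering(self):
        ws = gp.make_windows(np.zeros((100, 12)), np.ones(100, dtype=int), Lw=50, s=1)
        assert len(ws) == 51

    def test_short_stream_rejected(self):
        with pytest.raises(ValueError, match="shorter than window"):
            gp.make_windows(np.zeros((49, 12)), np.zeros(49, dtype=int), Lw=50)

    def test_terminal_label_and_undefined_dropped(self):
        labels = np.array([0, 0, 1, -1, 2, 2])
        ws = gp.make_windows(np.arange(6)[:, None].repeat(12, 1), labels, Lw=3)
        # terminal samples: idx 2,3,4,5 -> labels 1,-1,2,2 -> keep 3 windows
        np.testing.assert_array_equal(ws.labels, [1, 2, 2])
        assert ws.windows[0, -1, 0] == 2  # window ends at its label sample

    def test_label_offset_next_sample(self):
        labels = np.array([0, 0, 1, 2, 3])
        ws = gp.make_windows(np.zeros((5, 12)), labels, Lw=3, label_offset=1)
        # label index i+Lw: windows at i=0,1 -> labels[3],labels[4]
        np.testing.assert_array_equal(ws.labels, [2, 3])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        T=st.integers(5, 60),
        Lw=st.integers(1, 10),
        s=st.integers(1, 4),
        seed=st.integers(0, 10_000),
    )
    def test_matches_brute_force(self, T, Lw, s, seed):
        if T < Lw:
            return
        rng = np.random.default_rng(seed)
        stream = rng.standard_normal((T, 12))
        labels = rng.integers(-1, 4, size=T)
        ws = gp.make_windows(stream, labels, Lw=Lw, s=s)
        ref = brute_force_windows(stream, labels, Lw, s)
        assert len(ws) == len(ref)
        for k, (w_ref, lab_ref) in enumerate(ref):
            np.testing.assert_allclose(ws.windows[k], w_ref.astype(np.float32), rtol=1e-6)
            assert ws.labels[k] == lab_ref
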