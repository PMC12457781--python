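"""Metrics, cross-validation machinery, AWGN injection and calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gaitphase as gp
from gaitphase.evaluation import EvalReport, make_folds


class TestEvaluate:
    def test_perfect_diagonal(self):
        labels = np.repeat([0, 1, 2, 3], 10)
        rep = gp.evaluate(labels, labels)
        assert rep.overall_accuracy == 1.0
        np.testing.assert_array_equal(np.diag(rep.confusion), [10, 10, 10, 10])
        np.testing.assert_array_equal(rep.per_class_recall, [1, 1, 1, 1])

    def test_partial_accuracy(self):
        truth = np.zeros(40, dtype=int)
        pred = truth.copy()
        pred[:10] = 1  # 30 of 40 correct
        assert gp.evaluate(truth, pred).overall_accuracy == 0.75

    def test_total_confusion(self):
        rep = gp.evaluate(np.full(5, 2), np.full(5, 3))
        assert rep.overall_accuracy == 0.0
        assert rep.per_class_recall[2] == 0.0
        assert np.isnan(rep.per_class_recall[0])

    def test_row_normalization_sums_to_one(self):
        rng = np.random.default_rng(0)
        rep = gp.evaluate(rng.integers(0, 4, 200), rng.integers(0, 4, 200))
        norm = rep.normalized()
        np.testing.assert_allclose(norm.sum(axis=1), 1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            gp.evaluate([0, 1], [0])

    def test_confusion_total_equals_n(self):
        rng = np.random.default_rng(1)
        t, p = rng.integers(0, 4, 123), rng.integers(0, 4, 123)
        rep = gp.evaluate(t, p)
        assert rep.confusion.sum() == rep.n_samples == 123

    def test_oa_equals_naive_mean_oracle(self):
        """Trace/N agrees with mean(pred == truth) on random vectors."""
        rng = np.random.default_rng(2)
        for _ in range(200):
            n = int(rng.integers(1, 50))
            t = rng.integers(0, 4, n)
            p = rng.integers(0, 4, n)
            assert gp.evaluate(t, p).overall_accuracy == pytest.approx(np.mean(t == p))


class TestFolds:
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(n=st.integers(5, 400), seed=st.integers(0, 1000))
    def test_partition_laws(self, n, seed):
        folds = make_folds(n, 5, seed=seed)
        allidx = np.concatenate(folds)
        assert len(allidx) == n
        assert len(np.unique(allidx)) == n  # disjoint and complete
        sizes = [len(f) for f in folds]
        assert max(sizes) - min(sizes) <= 1

    def test_divisible_fold_sizes(self):
        assert [len(f) for f in make_folds(100, 5, seed=0)] == [20] * 5

    def test_seeded_determinism(self):
        a = make_folds(37, 5, seed=4)
        b = make_folds(37, 5, seed=4)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa, fb)

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError):
            make_folds(4, 5)

    def test_block_mode_contiguous(self):
        folds = make_folds(10, 5, mode="block")
        for f in folds:
            assert np.array_equal(f, np.arange(f[0], f[-1] + 1))


class TestSnrConversion:
    @pytest.mark.parametrize(
        "snr_db,ratio",
        [(5, 3.162), (0, 1.0), (10, 10.0), (15, 31.62), (20, 100.0), (25, 316.2), (30, 1000.0)],
    )
    def test_power_ratios(self, snr_db, ratio):
        assert gp.snr_to_power_ratio(snr_db) == pytest.approx(ratio, rel=5e-4)


@pytest.fixture(scope="module")
def windows():
    rng = np.random.default_rng(3)
    w = (rng.standard_normal((50, 50, 12)) + 1.0).astype(np.float32)
    return gp.WindowSet(w, rng.integers(0, 4, 50), np.array(["s"] * 50), 50)


class TestInjectAwgn:

    def test_vanishing_noise_limit(self, windows):
        noisy = gp.inject_awgn(windows, gp.NoiseSpec(snr_db=200.0, rng_seed=0))
        scale = np.abs(windows.windows).max()
        assert np.abs(noisy.windows - windows.windows).max() < 1e-6 * scale

    def test_empirical_snr_within_half_db(self, windows):
        for snr in (5.0, 15.0, 30.0):
            noisy = gp.inject_awgn(windows, gp.NoiseSpec(snr_db=snr, rng_seed=1))
            noise = noisy.windows.astype(np.float64) - windows.windows.astype(np.float64)
            p_sig = np.mean(windows.windows.astype(np.float64) ** 2)
            p_noise = np.mean(noise**2)
            measured = 10 * np.log10(p_sig / p_noise)
            assert abs(measured - snr) < 0.5

    def test_seeded_determinism_and_labels_unchanged(self, windows):
        spec = gp.NoiseSpec(snr_db=10.0, rng_seed=2)
        a, b = gp.inject_awgn(windows, spec), gp.inject_awgn(windows, spec)
        np.testing.assert_array_equal(a.windows, b.windows)
        np.testing.assert_array_equal(a.labels, windows.labels)

    def test_zero_power_channel_left_unchanged(self):
        w = np.zeros((5, 50, 12), np.float32)
        w[..., 0] = 1.0
        ws = gp.WindowSet(w, np.zeros(5, int), np.array(["s"] * 5), 50)
        with pytest.warns(UserWarning, match="zero-power"):
            noisy = gp.inject_awgn(ws, gp.NoiseSpec(snr_db=10.0, rng_seed=0))
        assert not noisy.windows[..., 1:].any()
        assert not np.array_equal(noisy.windows[..., 0], ws.windows[..., 0])

    def test_recording_injection(self, small_recording):
        noisy = gp.inject_awgn(small_recording, gp.NoiseSpec(snr_db=20.0, rng_seed=5))
        assert noisy.imu.shape == small_recording.imu.shape
        assert not np.array_equal(noisy.imu, small_recording.imu)
        np.testing.assert_array_equal(noisy.truth_labels, small_recording.truth_labels)


class TestExternalValidate:
    def test_subject_leakage_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="held-out"):
            gp.external_validate(small_cohort, small_cohort[0])

    def test_report_counts_heldout_windows(self, small_cohort):
        cfg = gp.TrainConfig(epochs=1, sda_epochs=1, rng_seed=0)
        ev = gp.external_validate(small_cohort[:3], small_cohort[3], config=cfg, window_step=40)
        assert ev.report.n_samples == len(ev.test_windows)
        assert {sid for sid in ev.test_windows.subject_ids} == {small_cohort[3].subject_id}


class TestCrossval:
    def test_folds_partition_and_reports(self, small_cohort):
        cfg = gp.TrainConfig(epochs=1, sda_epochs=1, rng_seed=0)
        ws, _, _ = gp.build_windows(small_cohort[:2], window_step=60)
        reports, folds = gp.crossval_5fold(ws, config=cfg, seed=1)
        assert len(reports) == 5
        allidx = np.concatenate(folds)
        assert len(np.unique(allidx)) == len(ws)
        assert sum(r.n_samples for r in reports) == len(ws)


class TestRobustnessSweep:
    def test_table_shape_and_clean_row(self, small_cohort):
        cfg = gp.TrainConfig(epochs=2, sda_epochs=2, rng_seed=0)
        ev = gp.external_validate(small_cohort[:3], small_cohort[3], config=cfg, window_step=40)
        table = gp.robustness_sweep(ev.results, ev.test_windows, seed=0)
        assert len(table) == 7
        clean = table[table["snr_db"].isna()]
        assert clean["All"].iloc[0] == pytest.approx(ev.report.overall_accuracy)

    def test_empty_levels_rejected(self, small_cohort):
        cfg = gp.TrainConfig(epochs=1, sda_epochs=1, rng_seed=0)
        ev = gp.external_validate(small_cohort[:3], small_cohort[3], config=cfg, window_step=60)
        with pytest.raises(ValueError):
            gp.robustness_sweep(ev.results, ev.test_windows, levels=[])
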