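import numpy as np
import pytest

from crossband.data import InvalidDataError, MotionTrace, ParcellatedRun, RunRecord, RawEEG
from crossband.qc import (QCMask, Segment, apply_masks_and_segment, combine_masks,
                          mask_hf_power, mask_mad_outliers, mask_motion,
                          rescale_eeg, zscore_regions)


def _run(n_tr=200, n_regions=2, seed=0):
    rng = np.random.default_rng(seed)
    parcels = ParcellatedRun(rng.standard_normal((n_tr, n_regions)),
                             [f"r{i}" for i in range(n_regions)],
                             0.378, "sub-01", "run-01")
    motion = MotionTrace(np.zeros(n_tr))
    eeg = RawEEG({"O1": np.zeros(250)}, 250.0)
    return RunRecord(parcels, motion, eeg)


class TestMaskMotion:
    def test_strictly_above_threshold(self):
        mask = mask_motion(MotionTrace([0.1, 0.4, 0.2]), 0.3)
        np.testing.assert_array_equal(mask.bad, [False, True, False])

    def test_all_zero_trace_clean(self):
        assert not mask_motion(MotionTrace(np.zeros(50))).bad.any()

    def test_boundary_value_not_masked(self):
        mask = mask_motion(MotionTrace([0.3]), 0.3)
        assert not mask.bad[0]

    def test_negative_threshold_rejected(self):
        with pytest.raises(InvalidDataError):
            mask_motion(MotionTrace([0.1]), -1.0)


class TestMaskHfPower:
    def test_constant_series_masks_nothing(self):
        with pytest.warns(UserWarning, match="zero variance"):
            mask = mask_hf_power(np.ones(100))
        assert not mask.bad.any()

    def test_large_spike_masked(self, rng):
        x = rng.standard_normal(1000)
        x[500] = 50.0
        mask = mask_hf_power(x)
        assert mask.bad[500]

    def test_threshold_is_adjustable(self, rng):
        x = rng.standard_normal(1000)
        strict = mask_hf_power(x, z_threshold=0.5)
        default = mask_hf_power(x, z_threshold=1.0)
        assert strict.bad.sum() > default.bad.sum()


class TestMaskMadOutliers:
    def test_planted_spike_detected_with_low_false_positives(self):
        flagged_spike, false_pos = 0, []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal(2000)
            x[500] = 50.0
            mask = mask_mad_outliers(x, window_tr=1000, n_mad=6)
            flagged_spike += mask.bad[500]
            false_pos.append((mask.bad.sum() - mask.bad[500]) / 1999)
        assert flagged_spike == 20
        assert np.mean(false_pos) < 0.01

    def test_constant_series_masks_nothing(self):
        mask = mask_mad_outliers(np.ones(100), window_tr=50)
        assert not mask.bad.any()

    def test_stricter_threshold_flags_more(self, rng):
        x = rng.standard_normal(3000)
        x[100:110] = 5.0
        loose = mask_mad_outliers(x, n_mad=6).bad.sum()
        strict = mask_mad_outliers(x, n_mad=3).bad.sum()
        assert strict >= loose

    def test_small_window_rejected(self):
        with pytest.raises(InvalidDataError):
            mask_mad_outliers(np.ones(10), window_tr=2)


class TestSegmentation:
    def _targets(self, n):
        return {"alpha": np.linspace(0, 1, n), "delta": np.linspace(1, 2, n)}

    def test_clean_run_loses_initial_discard_only(self):
        run = _run(200)
        mask = combine_masks([mask_motion(run.motion)], initial_discard=20)
        segs = apply_masks_and_segment(run, mask, self._targets(200))
        assert len(segs) == 1
        assert segs[0].start == 20 and segs[0].n_tr == 180

    def test_single_bad_tr_splits_into_two_segments(self):
        run = _run(200)
        bad = np.zeros(200, dtype=bool)
        bad[120] = True
        mask = combine_masks([QCMask(bad, {"motion": bad})], initial_discard=20)
        segs = apply_masks_and_segment(run, mask, self._targets(200))
        assert [s.n_tr for s in segs] == [100, 79]

    def test_short_stretch_dropped(self):
        run = _run(79)  # 79 - 20 = 59 < 60
        mask = combine_masks([mask_motion(run.motion)], initial_discard=20)
        segs = apply_masks_and_segment(run, mask, self._targets(79))
        assert segs == []

    def test_no_masked_tr_inside_any_segment_and_full_coverage(self, rng):
        run = _run(500, seed=1)
        bad = rng.uniform(size=500) < 0.05
        mask = combine_masks([QCMask(bad, {"motion": bad})], initial_discard=20)
        segs = apply_masks_and_segment(run, mask, self._targets(500))
        covered = np.zeros(500, dtype=int)
        for s in segs:
            assert not mask.bad[s.start:s.stop].any()
            covered[s.start:s.stop] += 1
        assert covered.max() <= 1  # each TR in at most one segment
        # every retained TR belongs to a segment unless its clean stretch < 60
        good = ~mask.bad
        i = 0
        while i < 500:
            if good[i]:
                j = i
                while j < 500 and good[j]:
                    j += 1
                if j - i >= 60:
                    assert covered[i:j].all()
                i = j
            else:
                i += 1


class TestNormalization:
    def _segment(self, fmri, targets=None, subject="sub-01", start=0):
        n = len(fmri)
        targets = targets or {"alpha": np.linspace(0.1, 0.9, n)}
        return Segment(subject, "run-01", start, np.asarray(fmri, float), targets)

    def test_zscore_small_example(self):
        seg = self._segment(np.array([[1.0], [2.0], [3.0]]))
        out = zscore_regions([seg])[0]
        np.testing.assert_allclose(out.fmri[:, 0], [-1.0, 0.0, 1.0])

    def test_zscore_idempotent(self, rng):
        seg = self._segment(rng.standard_normal((100, 3)))
        once = zscore_regions([seg])[0]
        twice = zscore_regions([self._segment(once.fmri)])[0]
        np.testing.assert_allclose(once.fmri, twice.fmri, atol=1e-12)

    def test_zscore_per_subject_across_scales(self, rng):
        a = self._segment(rng.standard_normal((80, 2)) * 10, subject="sub-01")
        b = self._segment(rng.standard_normal((80, 2)) * 0.1, subject="sub-02")
        out = zscore_regions([a, b])
        for seg in out:
            np.testing.assert_allclose(seg.fmri.std(axis=0, ddof=1), 1.0, rtol=1e-6)

    def test_zscore_spans_runs_of_one_subject(self, rng):
        a = self._segment(rng.standard_normal((80, 1)) + 5, start=0)
        b = self._segment(rng.standard_normal((80, 1)) - 5, start=100)
        out = zscore_regions([a, b], scope="subject")
        stacked = np.vstack([s.fmri for s in out])
        assert abs(stacked.mean()) < 1e-10
        # each segment keeps its offset relative to the subject mean
        assert out[0].fmri.mean() > 0.8 and out[1].fmri.mean() < -0.8

    def test_rescale_small_example(self):
        seg = self._segment(np.zeros((3, 1)), {"alpha": np.array([2.0, 4.0, 6.0])})
        out = rescale_eeg([seg], "alpha")[0]
        np.testing.assert_allclose(out.targets["alpha"], [0.0, 0.5, 1.0])

    def test_rescale_is_global_per_subject(self):
        a = self._segment(np.zeros((2, 1)), {"alpha": np.array([0.0, 1.0])}, start=0)
        b = self._segment(np.zeros((2, 1)), {"alpha": np.array([3.0, 4.0])}, start=10)
        out = rescale_eeg([a, b], "alpha")
        np.testing.assert_allclose(out[0].targets["alpha"], [0.0, 0.25])
        np.testing.assert_allclose(out[1].targets["alpha"], [0.75, 1.0])

    def test_rescale_constant_target_rejected(self):
        seg = self._segment(np.zeros((3, 1)), {"alpha": np.ones(3)})
        with pytest.raises(InvalidDataError, match="constant"):
            rescale_eeg([seg], "alpha")


def test_planted_artifact_recovery_on_synthetic_runs():
    """Motion spikes are recovered almost exactly; clean TRs stay unmasked."""
    import crossband as cb
    recovered, false_pos = [], []
    for seed in range(4):
        cfg = cb.scaled_config(n_subjects=1, run_length_tr=1500, seed=seed)
        ds, truth = cb.generate_dataset(cfg)
        run = ds.runs[0]
        spike_trs = [i for i in truth.artifact_tr_indices["sub-01/run-01"]
                     if run.motion.displacement_mm[i] > 0.3]
        from crossband.bandpower import run_band_power
        from crossband.qc import combine_masks, mask_hf_power, mask_mad_outliers, mask_missing
        tr_times = np.arange(1500) * cfg.tr_seconds
        power = run_band_power(run.eeg, tr_times)
        art_series = power["artifact"].values
        mask = combine_masks([
            mask_motion(run.motion),
            mask_hf_power(art_series),
            mask_mad_outliers(power["delta"].values),
            mask_mad_outliers(art_series),
            mask_missing(*(s.values for s in power.values())),
        ], initial_discard=20)
        recovered.append(np.mean([mask.bad[i] for i in spike_trs]))
        # clean = past the initial discard, inside EEG support, and away from
        # any planted artifact (the 5 s spectrogram window smears bursts)
        art = truth.artifact_tr_indices["sub-01/run-01"]
        near = np.zeros(1500, dtype=bool)
        for i in art:
            near[max(0, i - 10): i + 11] = True
        clean = ~near & ~mask.reasons["missing"]
        clean[:20] = False
        false_pos.append(mask.bad[clean].mean())
    assert np.mean(recovered) >= 0.95
    assert np.mean(false_pos) < 0.02
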