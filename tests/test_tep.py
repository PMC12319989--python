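import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tdcsdose import synth, tep
from tdcsdose.epochs import EpochSet
from tdcsdose.synth import DEFAULT_EEG_CHANNELS, EvokedTemplate, generate_eeg_epochs

CH = ["FC2", "C1", "Cz", "C2", "C4", "CP2"]


def make_eeg(noise_sd=0.0, artifact=0.0, offset_sd=0.0, n_trials=6,
             weights=None, seed=3, gain_sd=0.0, template=None):
    tpl = template or EvokedTemplate(noise_sd=noise_sd)
    w = np.ones(len(CH)) if weights is None else weights
    return generate_eeg_epochs(tpl, CH, w, n_trials=n_trials,
                               rng=np.random.default_rng(seed),
                               artifact_amp_uv=artifact,
                               baseline_offset_sd=offset_sd,
                               trial_gain_sd=gain_sd)


class TestPreprocess:
    def test_constant_offset_trace_becomes_zero(self):
        t = np.arange(-500, 500.2, 0.2)
        data = np.full((2, 1, t.size), 7.3)
        es = EpochSet(data, t, ["Cz"], 5000.0)
        out = tep.preprocess_epochs(es)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_planted_artifact_is_bounded_by_edge_interpolation(self):
        es = make_eeg(artifact=100 * 5.0)
        out = tep.preprocess_epochs(es)
        t = out.time_ms
        win = (t >= -3) & (t <= 10)
        # after cleaning, the artifact window is on the scale of the signal,
        # not the 500 µV spike
        assert np.abs(out.data[:, :, win]).max() < 20.0

    def test_artifact_free_signal_unchanged_within_1pct(self):
        es = make_eeg(artifact=0.0)
        raw_summary = tep.median_tep(es)
        clean_summary = tep.median_tep(tep.preprocess_epochs(es))
        a = raw_summary.window_amplitudes.to_numpy()
        b = clean_summary.window_amplitudes.to_numpy()
        assert np.abs(a - b).max() <= 0.01 * np.abs(a).max()

    def test_preprocessing_is_idempotent(self):
        es = make_eeg(noise_sd=1.0, artifact=300.0, offset_sd=2.0)
        once = tep.preprocess_epochs(es)
        twice = tep.preprocess_epochs(once)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-9)

    def test_baseline_mean_is_zero_after_preprocessing(self):
        es = make_eeg(noise_sd=1.0, offset_sd=5.0)
        out = tep.preprocess_epochs(es)
        bl = (out.time_ms >= -500) & (out.time_ms <= -400)
        np.testing.assert_allclose(out.data[:, :, bl].mean(axis=2), 0.0,
                                   atol=1e-10)

    def test_short_epoch_rejected(self):
        t = np.arange(-100, 100, 0.2)
        es = EpochSet(np.zeros((1, 1, t.size)), t, ["Cz"], 5000.0)
        with pytest.raises(tep.FormatError):
            tep.preprocess_epochs(es)


class TestMedianTep:
    def test_single_trial_median_is_that_trial(self):
        es = make_eeg(noise_sd=1.0, n_trials=1)
        summ = tep.median_tep(es)
        np.testing.assert_array_equal(summ.median_tep, es.data[0])

    def test_symmetric_noise_median_recovers_template(self):
        es = make_eeg(noise_sd=2.0, n_trials=41, seed=8)
        summ = tep.median_tep(es)
        clean = es.meta["clean"]
        # median SE of 41 trials with sd 2 is ~0.39; the max over the ~30k
        # channel-sample grid of such draws sits near 4.5 sigma
        assert np.abs(summ.median_tep - clean).max() < 2.2
        assert np.abs(summ.median_tep - clean).mean() < 0.5

    def test_one_extreme_outlier_trial_barely_moves_the_median(self):
        es = make_eeg(noise_sd=0.5, n_trials=59, seed=9)
        summ = tep.median_tep(es)
        spoiled = es.copy()
        spoiled.data = np.concatenate(
            [spoiled.data, 1e5 * np.ones((1,) + spoiled.data.shape[1:])])
        summ2 = tep.median_tep(spoiled)
        # adding one huge trial to 59 shifts the median at most to the next
        # order statistic
        assert np.abs(summ2.median_tep - summ.median_tep).max() < 0.5


class TestFieldPower:
    def test_zero_tep_gives_zero_lmfp(self):
        es = make_eeg(template=EvokedTemplate(peak_amplitudes=(0, 0, 0, 0, 0),
                                              noise_sd=0.0))
        summ = tep.median_tep(es, roi_channels=("C2", "C4"))
        np.testing.assert_allclose(tep.lmfp(summ), 0.0, atol=1e-12)

    def test_single_channel_roi_reduces_to_absolute_value(self):
        es = make_eeg()
        summ = tep.median_tep(es)
        idx = summ.channels.index("C2")
        np.testing.assert_allclose(tep.lmfp(summ, roi=("C2",)),
                                   np.abs(summ.median_tep[idx]), atol=1e-12)

    def test_opposite_channels_give_common_magnitude(self):
        t = np.arange(-500, 500.2, 0.2)
        v = np.sin(t / 50.0)
        data = np.stack([v, -v])[None, :, :]
        es = EpochSet(data, t, ["C2", "C4"], 5000.0)
        summ = tep.median_tep(es)
        np.testing.assert_allclose(tep.lmfp(summ), np.abs(v), atol=1e-12)

    def test_empty_roi_rejected(self):
        summ = tep.median_tep(make_eeg())
        with pytest.raises(tep.StatisticalError):
            tep.lmfp(summ, roi=())


def window_table(rng, n_per_group=12, shift_per_level=0.0, noise=1.0):
    """Long-form window-amplitude table with an optional dose-proportional
    negative shift planted at the 45-ms window in ROI channels."""
    rows = []
    sid = 0
    for level, ma in enumerate((0.0, 4.0, 6.0)):
        for _ in range(n_per_group):
            sid += 1
            for ch in CH:
                for w in tep.PEAK_WINDOW_CENTERS_MS:
                    pre = rng.normal(0, noise)
                    post = pre + rng.normal(0, noise)
                    if w == 45.0 and ch in ("C2", "C4"):
                        post -= shift_per_level * level
                    rows.append({"subject_id": f"S{sid:03d}", "group_mA": ma,
                                 "channel": ch, "window_ms": w,
                                 "pre": pre, "post": post})
    return pd.DataFrame(rows)


class TestCompareMaps:
    def test_exact_null_flags_nothing(self, rng):
        table = window_table(rng)
        table["post"] = table["pre"]
        maps = tep.compare_maps(table)
        assert not maps["roi_dose"]["significant"].any()
        assert (maps["wilcoxon"]["p"] == 1.0).all()

    def test_planted_45ms_dose_shift_detected_not_175ms(self):
        """A dose-proportional negative shift at 45 ms in ROI channels is
        flagged there (and not at 175 ms) in >= 90% of seeded replicates."""
        hits_45, hits_175 = 0, 0
        n_rep = 12
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            table = window_table(rng, n_per_group=14, shift_per_level=1.6)
            roi = tep.compare_maps(table)["roi_dose"].set_index("window_ms")
            hits_45 += bool(roi.loc[45.0, "significant"])
            hits_175 += bool(roi.loc[175.0, "significant"])
        assert hits_45 / n_rep >= 0.9
        assert hits_175 / n_rep <= 0.25

    def test_signed_rank_p_matches_independent_implementation(self, rng):
        import pingouin as pg
        table = window_table(rng, n_per_group=7)
        maps = tep.compare_maps(table)["wilcoxon"]
        for _, row in maps.sample(8, random_state=4).iterrows():
            sub = table[(table["channel"] == row["channel"])
                        & (table["window_ms"] == row["window_ms"])]
            d = (sub["post"] - sub["pre"]).to_numpy()
            expected = pg.wilcoxon(d).at["Wilcoxon", "p_val"]
            assert row["p"] == pytest.approx(expected, rel=1e-6)

    def test_bonferroni_correction_recorded_and_reproducible(self, rng):
        table = window_table(rng)
        roi = tep.compare_maps(table)["roi_dose"]
        assert (roi["n_comparisons"] == 5).all()
        np.testing.assert_allclose(roi["p_bonf"],
                                   np.minimum(roi["p"] * 5, 1.0))

    def test_hemisphere_mirror_symmetry(self, rng):
        """Mirroring channel labels left-right leaves every statistic equal."""
        table = window_table(rng)
        mirror = {"FC2": "FC1", "C1": "C2", "Cz": "Cz", "C2": "C1",
                  "C4": "C3", "CP2": "CP1"}
        mirrored = table.assign(channel=table["channel"].map(mirror))
        a = tep.compare_maps(table, roi_channels=("C2", "C4"))
        b = tep.compare_maps(mirrored, roi_channels=("C1", "C3"))
        np.testing.assert_allclose(
            a["roi_dose"]["p"].to_numpy(), b["roi_dose"]["p"].to_numpy())
        merged = a["kruskal"].merge(b["kruskal"].assign(
            channel=b["kruskal"]["channel"].map(
                {v: k for k, v in mirror.items()})),
            on=["channel", "window_ms"], suffixes=("_a", "_b"))
        np.testing.assert_allclose(merged["p_a"], merged["p_b"])

    def test_tiny_group_rejected(self, rng):
        table = window_table(rng, n_per_group=1)
        with pytest.raises(tep.StatisticalError):
            tep.compare_maps(table)


def test_window_amplitudes_linear_in_signal():
    es = make_eeg()
    summ1 = tep.median_tep(es)
    scaled = es.copy()
    scaled.data = 2.5 * scaled.data
    summ2 = tep.median_tep(scaled)
    np.testing.assert_allclose(summ2.window_amplitudes.to_numpy(),
                               2.5 * summ1.window_amplitudes.to_numpy())


def test_cohort_tep_pipeline_runs_end_to_end(eeg_cohort):
    groups = eeg_cohort.manifest.set_index("subject_id")["group_mA"]
    res = tep.score_cohort_tep(eeg_cohort.eeg, groups)
    assert set(res["roi_dose"]["window_ms"]) == set(tep.PEAK_WINDOW_CENTERS_MS)
    assert len(res["table"]) == 12 * len(eeg_cohort.config.eeg_channels) * 5
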