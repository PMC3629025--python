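"""Synthetic MSIT generator: schedule, behaviour, BOLD and file round trips."""

import numpy as np
import pandas as pd
import pandas.testing as pdt
import pytest

import rtbold as rb
from rtbold.simulate import read_series


class TestSchedule:
    def test_default_counts_and_span(self, default_spec):
        table = rb.generate_schedule(default_spec, seed=0)
        assert len(table) == 5 * 60
        for _, run in table.groupby("run"):
            counts = run["trial_type"].value_counts()
            assert counts["congruent"] == 24
            assert counts["incongruent"] == 24
            assert counts["fixation"] == 12
            onsets = run["onset"].to_numpy()
            assert np.array_equal(onsets, np.arange(60) * 3.0)
        assert default_spec.run_duration == 180.0

    def test_empty_spec_gives_empty_table(self):
        spec = rb.ScheduleSpec(n_congruent_per_run=0, n_incongruent_per_run=0,
                               n_fixation_per_run=0)
        assert len(rb.generate_schedule(spec, seed=0)) == 0

    def test_single_trial_at_onset_zero(self):
        spec = rb.ScheduleSpec(n_runs=1, n_congruent_per_run=1,
                               n_incongruent_per_run=0, n_fixation_per_run=0)
        table = rb.generate_schedule(spec, seed=0)
        assert len(table) == 1
        assert table.loc[0, "onset"] == 0.0
        assert table.loc[0, "trial_type"] == "congruent"

    def test_invalid_durations_rejected(self):
        with pytest.raises(ValueError):
            rb.ScheduleSpec(trial_duration=0.0)
        with pytest.raises(ValueError):
            rb.ScheduleSpec(tr=-1.0)

    def test_fixation_carries_no_rt(self, default_spec, rt_model):
        table = rb.sample_behavior(
            rb.generate_schedule(default_spec, seed=3), rt_model, seed=4
        )
        fix = table[table["trial_type"] == "fixation"]
        assert not np.isfinite(fix["response_time"]).any()
        assert not np.isfinite(fix["accuracy"]).any()

    def test_same_seed_is_bit_identical(self, default_spec, rt_model):
        a = rb.sample_behavior(
            rb.generate_schedule(default_spec, seed=9), rt_model, seed=10
        )
        b = rb.sample_behavior(
            rb.generate_schedule(default_spec, seed=9), rt_model, seed=10
        )
        pdt.assert_frame_equal(a, b)


class TestBehavior:
    def test_degenerate_distribution_returns_mu(self, default_spec):
        model = rb.RTModel(
            congruent=rb.ConditionBehavior(mu=700.0, sigma=1e-9, tau=0.0),
            incongruent=rb.ConditionBehavior(mu=900.0, sigma=1e-9, tau=0.0),
        )
        table = rb.sample_behavior(
            rb.generate_schedule(default_spec, seed=1), model, seed=2
        )
        cong = table[table["trial_type"] == "congruent"]["response_time"]
        assert np.allclose(cong, 700.0)

    def test_error_probability_one_flags_all_incorrect(self, default_spec):
        model = rb.RTModel(
            congruent=rb.ConditionBehavior(mu=700, sigma=50, tau=100,
                                           p_error=1.0),
            incongruent=rb.ConditionBehavior(mu=900, sigma=50, tau=100,
                                             p_error=1.0),
        )
        table = rb.sample_behavior(
            rb.generate_schedule(default_spec, seed=1), model, seed=2
        )
        task = table[table["trial_type"] != "fixation"]
        assert (task["accuracy"] == 0).all()

    def test_rts_positive(self, default_spec, rt_model):
        table = rb.sample_behavior(
            rb.generate_schedule(default_spec, seed=5), rt_model, seed=6
        )
        rt = table["response_time"]
        assert (rt[np.isfinite(rt)] > 0).all()

    def test_calibrated_group_congruency_effect(self, default_spec, rt_model):
        # 28 participants at the default calibration: raw generative RT
        # difference is 969.8 - 686.9 = 282.9 ms
        diffs = []
        for i in range(28):
            t = rb.sample_behavior(
                rb.generate_schedule(default_spec, seed=100 + i),
                rt_model, seed=200 + i,
            )
            correct = t[(t["accuracy"] == 1)]
            by = correct.groupby("trial_type")["response_time"].mean()
            diffs.append(by["incongruent"] - by["congruent"])
        assert abs(np.mean(diffs) - 282.9) < 15.0


class TestBold:
    def test_symmetry_without_rt_or_increment(self, small_spec):
        # equal baselines, zero slope/increment/noise: both conditions evoke
        # identical event responses, so swapping labels changes nothing
        truth = rb.BoldTruth(baseline_congruent=1.0, baseline_incongruent=1.0,
                             rt_slope=0.0, congruency_increment=0.0,
                             noise_sd=0.0, drift_amplitude=0.0)
        table = rb.sample_behavior(
            rb.generate_schedule(small_spec, seed=1), rb.RTModel(), seed=2
        )
        a = rb.synthesize_bold(table, truth, spec=small_spec, seed=3)
        swapped = table.copy()
        swapped["trial_type"] = swapped["trial_type"].map(
            {"congruent": "incongruent", "incongruent": "congruent",
             "fixation": "fixation"}
        )
        b = rb.synthesize_bold(swapped, truth, spec=small_spec, seed=4)
        assert np.allclose(a.data, b.data)

    def test_amplitude_difference_forced_by_generative_equation(self):
        truth = rb.BoldTruth(rt_slope=0.002)
        row_c = pd.Series({"trial_type": "congruent", "response_time": 686.9})
        row_i = pd.Series({"trial_type": "incongruent", "response_time": 969.8})
        from rtbold.simulate import _trial_amplitude

        diff = _trial_amplitude(row_i, truth) - _trial_amplitude(row_c, truth)
        assert diff == pytest.approx(0.5658, abs=1e-9)

    def test_pure_noise_mean_and_lag1_autocorrelation(self):
        # all trial amplitudes zero -> the series is the AR(1) recursion, whose
        # lag-1 autocorrelation converges to the coefficient
        spec = rb.ScheduleSpec(n_runs=20)
        truth = rb.BoldTruth(rt_slope=0.0, noise_sd=1.0, ar1=0.4,
                             drift_amplitude=0.0)
        table = rb.sample_behavior(
            rb.generate_schedule(spec, seed=1), rb.RTModel(), seed=2
        )
        series = rb.synthesize_bold(table, truth, spec=spec, seed=3)
        x = series.data[:, 0]
        n = len(x)
        assert n == 20 * 90
        assert abs(x.mean()) < 4.0 / np.sqrt(n * (1 - 0.4)) + 0.05
        r1 = np.corrcoef(x[1:], x[:-1])[0, 1]
        assert abs(r1 - 0.4) < 0.06

    def test_missing_rt_on_correct_trial_raises(self, small_spec):
        table = rb.sample_behavior(
            rb.generate_schedule(small_spec, seed=1), rb.RTModel(), seed=2
        )
        correct = table.index[table["accuracy"] == 1][0]
        table.loc[correct, "response_time"] = np.nan
        with pytest.raises(ValueError, match="without an RT"):
            rb.synthesize_bold(table, rb.BoldTruth(), spec=small_spec, seed=3)

    def test_same_seed_identical_series(self, small_spec, rt_model):
        table = rb.sample_behavior(
            rb.generate_schedule(small_spec, seed=1), rt_model, seed=2
        )
        a = rb.synthesize_bold(table, rb.BoldTruth(), spec=small_spec, seed=5)
        b = rb.synthesize_bold(table, rb.BoldTruth(), spec=small_spec, seed=5)
        assert np.array_equal(a.data, b.data)

    def test_volumetric_mode_places_signal_in_sphere(self):
        spec = rb.ScheduleSpec(n_runs=1)
        grid = rb.GridSpec(shape=(8, 8, 6), origin=(-13.0, 1.0, 34.0))
        roi = rb.ROISpec(radius=5.0)
        truth = rb.BoldTruth(rt_slope=0.002, noise_sd=0.1,
                             drift_amplitude=0.0)
        table = rb.sample_behavior(
            rb.generate_schedule(spec, seed=1), rb.RTModel(), seed=2
        )
        img, active = rb.synthesize_bold_volume(
            table, truth, grid=grid, roi=roi, spec=spec, seed=3
        )
        data = np.asarray(img.dataobj)
        assert data.shape == (8, 8, 6, 90)
        series = rb.roi_average(np.moveaxis(data, -1, 0), active)
        outside = np.ones(grid.shape, dtype=bool)
        outside[tuple(active.T)] = False
        # task variance concentrates in the sphere
        assert series.std() > 3 * data[outside].std(axis=-1).mean()


class TestDatasetIO:
    def test_round_trip_preserves_all_trial_fields(self, tmp_path, small_spec,
                                                   rt_model):
        table = rb.sample_behavior(
            rb.generate_schedule(small_spec, seed=1), rt_model, seed=2
        )
        series = rb.synthesize_bold(table, rb.BoldTruth(), spec=small_spec,
                                    seed=3)
        rb.write_dataset(table, series, tmp_path)
        files = sorted(tmp_path.glob("run-*_events.tsv"))
        assert len(files) == small_spec.n_runs
        back = rb.read_events(files)
        pdt.assert_frame_equal(
            back.reset_index(drop=True), table.reset_index(drop=True),
            check_dtype=False,
        )
        series_back = read_series(tmp_path)
        assert np.allclose(series_back.data, series.data)
        assert series_back.tr == series.tr

    def test_empty_table_writes_valid_header_only_tsv(self, tmp_path):
        spec = rb.ScheduleSpec(n_congruent_per_run=0, n_incongruent_per_run=0,
                               n_fixation_per_run=0)
        table = rb.generate_schedule(spec, seed=0)
        written = rb.write_dataset(table, None, tmp_path)
        assert len(written) == 1
        back = rb.read_events(written[0])
        assert len(back) == 0
        assert list(back.columns) == list(table.columns)

    def test_default_dataset_has_five_runs_with_bounded_onsets(
        self, tmp_path, default_spec, rt_model
    ):
        table = rb.sample_behavior(
            rb.generate_schedule(default_spec, seed=1), rt_model, seed=2
        )
        rb.write_dataset(table, None, tmp_path)
        files = sorted(tmp_path.glob("run-*_events.tsv"))
        assert len(files) == 5
        for f in files:
            events = rb.read_events(f)
            assert (events["onset"] >= 0).all()
            assert (events["onset"] < 180.0).all()
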