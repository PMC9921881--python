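import numpy as np
import pandas as pd
import pytest

from valenscope import ClassifierConfig, SimSpec
from valenscope.analysis import (
    band_feature_analysis,
    cohort_feature_table,
    export_boxplot_data,
    final_evaluation,
    five_number_summary,
    gamma_subband_analysis,
    per_subject_table,
    summarize_evaluation,
    threshold_sensitivity,
    timeslot_analysis,
)
from valenscope.band_filters import apply_bandpass, get_band
from valenscope.labeling import LabelScheme
from valenscope.synthetic import generate_cohort

KNN = ClassifierConfig(kind="knn")


@pytest.fixture(scope="module")
def planted_cohort():
    """Four subjects, planted alpha asymmetry (ratio 2), 20 trials each."""
    return generate_cohort(SimSpec(n_subjects=4, n_trials=20, seed=31))


@pytest.fixture(scope="module")
def null_cohort():
    return generate_cohort(
        SimSpec(n_subjects=4, n_trials=20, effect_ratio=1.0, seed=32)
    )


class TestBandFeatureAnalysis:
    def test_planted_alpha_effect_peaks_in_alpha(self, planted_cohort):
        table = band_feature_analysis(
            planted_cohort, config=KNN, n_per_side=4
        )
        assert table.shape == (5, 5)
        for feat in ("activity", "psd"):
            assert table.loc[feat].idxmax() == "alpha"
        # the effect is a variance asymmetry: power features beat mobility
        assert table.loc["activity", "alpha"] >= table.loc["mobility", "alpha"]

    def test_null_cohort_stays_at_chance(self, null_cohort):
        table = band_feature_analysis(
            null_cohort,
            features=("activity", "psd"),
            config=KNN,
            n_per_side=4,
        )
        # 8 folds x 4 subjects per cell; binomial 99% band around 50%
        assert ((table.values >= 25.0) & (table.values <= 75.0)).all()

    def test_gamma_subband_shape_and_restriction(self, planted_cohort):
        table = gamma_subband_analysis(
            planted_cohort, config=KNN, n_per_side=4
        )
        assert table.shape == (2, 3)
        assert list(table.columns) == ["slow_gamma", "mid_gamma", "fast_gamma"]

    def test_planted_fast_gamma_effect_peaks_there(self):
        cohort = generate_cohort(
            SimSpec(
                n_subjects=3,
                n_trials=16,
                effect_band="gamma",
                effect_ratio=3.0,
                seed=33,
            )
        )
        # the gamma effect is spread over 30-60 Hz; the screen should place
        # every gamma sub-band above chance
        table = gamma_subband_analysis(cohort, config=KNN, n_per_side=4)
        assert (table.loc["activity"] > 60).all()


class TestTimeslotAnalysis:
    def test_shape_and_uniform_effect_prefers_full_minute(self, planted_cohort):
        table = timeslot_analysis(planted_cohort, config=KNN, n_per_side=4)
        assert table.shape == (4, 6)
        for column in table.columns:
            if column[0] == "alpha":  # effect band: more data can't hurt
                assert table.loc["full60", column] >= (
                    table.loc[["first20", "middle20", "last20"], column].min()
                )

    def test_time_localized_effect_found_in_its_slot(self):
        """Boosting high-class alpha only within 20-40 s makes the middle
        slot the most informative 20 s window."""
        cohort = generate_cohort(
            SimSpec(n_subjects=3, n_trials=16, effect_ratio=1.0, seed=34)
        )
        rng = np.random.default_rng(99)
        band = get_band("alpha")
        for archive in cohort:
            i0 = int((archive.baseline_s + 20) * archive.fs)
            i1 = int((archive.baseline_s + 40) * archive.fs)
            for t in np.flatnonzero(archive.valence() > 5):
                burst = apply_bandpass(
                    rng.standard_normal(archive.n_samples), archive.fs, band
                ).samples
                burst *= 8.0 / burst.std()
                archive.data[t, 0, i0:i1] += burst[i0:i1]
        table = timeslot_analysis(
            cohort,
            slots=("first20", "middle20", "last20"),
            bands=("alpha",),
            config=KNN,
            n_per_side=4,
        )
        col = ("alpha", "activity")
        assert table.loc["middle20", col] == table[col].max()


class TestFinalEvaluation:
    def test_summary_and_per_subject_shapes(self, planted_cohort):
        results = final_evaluation(planted_cohort, classifier="knn")
        summary = summarize_evaluation(results)
        assert summary.shape == (3, 3)
        assert set(summary.columns) == {"delta", "alpha", "fast_gamma"}
        assert set(summary.index) == {"activity", "psd", "activity+psd"}
        breakdown = per_subject_table(results)
        assert breakdown.shape[0] == len(planted_cohort) + 1  # + Average row
        assert "Average" in breakdown.index

    def test_planted_alpha_effect_recovered(self, planted_cohort):
        results = final_evaluation(
            planted_cohort,
            bands=("alpha",),
            feature_sets=(("activity", "psd"),),
        )
        assert results[("alpha", "activity+psd")].mean_accuracy >= 90.0

    def test_null_cohort_at_chance(self, null_cohort):
        results = final_evaluation(
            null_cohort,
            bands=("alpha",),
            feature_sets=(("activity", "psd"),),
        )
        assert 25.0 <= results[("alpha", "activity+psd")].mean_accuracy <= 75.0

    def test_three_class_mode_uses_three_labels(self, planted_cohort):
        results = final_evaluation(
            planted_cohort,
            mode="three_class",
            bands=("alpha",),
            feature_sets=(("activity",),),
        )
        ev = next(iter(results.values()))
        observed = set()
        for subject_eval in ev.per_subject.values():
            observed.update(subject_eval.labels)
        assert observed <= {"low", "neutral", "high"}
        assert len(observed) >= 2


class TestThresholdSensitivity:
    def test_rating_statistics_are_population_statistics(self, tiny_archive):
        stats, _ = threshold_sensitivity(
            [tiny_archive], thresholds=(5.0,), config=ClassifierConfig(k=1)
        )
        r = tiny_archive.valence()
        assert stats.loc["tiny", "median"] == pytest.approx(np.median(r))
        assert stats.loc["tiny", "mean"] == pytest.approx(np.mean(r))
        assert stats.loc["tiny", "sd"] == pytest.approx(np.std(r))  # 1/N

    def test_worked_statistics_example(self):
        ratings = np.array([1.0, 5.0, 9.0])
        assert np.median(ratings) == 5.0
        assert np.std(ratings) == pytest.approx(3.266, abs=1e-3)

    def test_shifted_rating_center_prefers_matching_threshold(self):
        """A cohort whose ratings center near 6 is labelled more cleanly
        by a threshold of 6 than by the default 5."""
        cohort = generate_cohort(
            SimSpec(
                n_subjects=3,
                n_trials=20,
                rating_low_mean=5.0,
                rating_high_mean=7.5,
                seed=35,
            )
        )
        _, accs = threshold_sensitivity(cohort, thresholds=(5.0, 6.0))
        assert (
            accs.loc["all_subjects", "threshold=6"]
            >= accs.loc["all_subjects", "threshold=5"]
        )


class TestBoxplotData:
    def test_five_number_summary_identity(self):
        summary = five_number_summary(np.array([1.0, 2.0, 3.0, 4.0, 5.0]))
        assert (
            summary["min"], summary["q1"], summary["median"],
            summary["q3"], summary["max"],
        ) == (1.0, 2.0, 3.0, 4.0, 5.0)

    def test_planted_effect_separates_class_medians(self, planted_cohort):
        table = cohort_feature_table(
            planted_cohort, bands=[get_band("alpha")]
        )
        scheme = LabelScheme()
        labels = scheme.apply(table["rating_valence"].to_numpy())
        box = export_boxplot_data(
            table, labels, bands=("alpha",), features=("activity",)
        ).set_index("class")
        pooled_iqr = (box["q3"] - box["q1"]).mean()
        assert (
            abs(box.loc["high", "median"] - box.loc["low", "median"])
            > pooled_iqr / 2
        )

    def test_group_counts_bookkeeping(self, planted_cohort):
        table = cohort_feature_table(planted_cohort, bands=[get_band("alpha")])
        labels = np.array(
            ["low", "high"] * (len(table) // 2), dtype=object
        )
        box = export_boxplot_data(
            table, labels, bands=("alpha",), features=("activity", "psd")
        )
        assert len(box) == 2 * 1 * 2  # features x bands x classes
        assert box["n"].sum() == 2 * len(table)
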