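"""Cohort-level analyses: band/feature screening, timeslots, evaluations.

These orchestrate the full pipeline over a cohort of per-subject archives
and produce the plot-ready tables of the study design:

* **band_feature_analysis** — which feature computed from which band best
  separates strong high- from strong low-valence trials (strongest-16
  subset, kNN LOOCV, one feature at a time);
* **gamma_subband_analysis** — the same screen restricted to the three
  gamma sub-bands;
* **timeslot_analysis** — whether 20 s excerpts beat the full minute;
* **final_evaluation** — binary or three-class classification of all
  trials with kNN or tuned RBF-SVM, per band and feature set, with the
  per-subject breakdown;
* **threshold_sensitivity** — rating statistics per subject and accuracy
  under alternative binary thresholds;
* **export_boxplot_data** — five-number summaries of features per class.

Strongest-16 analyses label trials by selection side (bottom-8 = low,
top-8 = high) rather than re-thresholding, which matches the
highest/lowest framing and guarantees balanced folds. All functions
accept a precomputed feature table so a single extraction pass can be
shared across analyses.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .band_filters import (
    BandDef,
    CANONICAL_BANDS,
    GAMMA_SUBBANDS,
    default_bands,
    get_band,
)
from .classify import ClassifierConfig, EvalResult, aggregate_cohort, loocv_evaluate
from .eeg_io import TrialArchive
from .features import canonical_feature, extract_features, FEATURE_NAMES
from .labeling import HIGH, LOW, LabelScheme, select_strongest
from .preprocess import TimeslotSpec

DEFAULT_EVAL_BANDS = ("delta", "alpha", "fast_gamma")
DEFAULT_FEATURE_SETS: tuple[tuple[str, ...], ...] = (
    ("activity",),
    ("psd",),
    ("activity", "psd"),
)


def feature_set_name(features: Sequence[str]) -> str:
    return "+".join(canonical_feature(f) for f in features)


def cohort_feature_table(
    cohort: Sequence[TrialArchive],
    bands: Sequence[BandDef] | None = None,
    slot: TimeslotSpec | None = None,
    pair: tuple[str, str] = ("Fp1", "Fp2"),
) -> pd.DataFrame:
    """One extraction pass over the cohort; rows are (subject, trial).

    ``slot=None`` uses each trial's entire post-baseline series."""
    if not len(cohort):
        raise ValueError("cohort is empty")
    if bands is None:
        bands = default_bands()
    return pd.concat(
        [extract_features(a, pair=pair, bands=bands, slot=slot) for a in cohort],
        ignore_index=True,
    )


def _strongest_subset(
    subject_table: pd.DataFrame, n_per_side: int
) -> tuple[pd.DataFrame, np.ndarray]:
    ratings = subject_table["rating_valence"].to_numpy()
    low_idx, high_idx = select_strongest(ratings, n_per_side)
    keep = np.concatenate([low_idx, high_idx])
    labels = np.array([LOW] * len(low_idx) + [HIGH] * len(high_idx), dtype=object)
    return subject_table.iloc[keep], labels


def band_feature_analysis(
    cohort: Sequence[TrialArchive],
    bands: Sequence[str] = CANONICAL_BANDS,
    features: Sequence[str] = FEATURE_NAMES,
    config: ClassifierConfig | None = None,
    n_per_side: int = 8,
    feature_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Cohort-mean LOOCV accuracy (%) for every (feature, band) singleton.

    Per subject, the strongest 2*n_per_side trials are labelled by
    selection side and classified from one feature column at a time.
    Returns a features x bands DataFrame.
    """
    config = config or ClassifierConfig(kind="knn")
    if feature_table is None:
        feature_table = cohort_feature_table(
            cohort, bands=[get_band(b) for b in bands]
        )
    features = [canonical_feature(f) for f in features]
    cells: dict[str, dict[str, float]] = {f: {} for f in features}
    per_subject = dict(tuple(feature_table.groupby("subject_id", sort=False)))
    for feat in features:
        for band in bands:
            column = f"{band}_{feat}"
            accuracies = []
            for sid, table in per_subject.items():
                subset, labels = _strongest_subset(table, n_per_side)
                result = loocv_evaluate(
                    subset[[column]], labels, config, subject_id=sid
                )
                accuracies.append(result.accuracy)
            cells[feat][band] = aggregate_cohort(accuracies)
    return pd.DataFrame(cells).T.loc[list(features), list(bands)]


def gamma_subband_analysis(
    cohort: Sequence[TrialArchive],
    subbands: Sequence[str] = GAMMA_SUBBANDS,
    features: Sequence[str] = ("activity", "psd"),
    config: ClassifierConfig | None = None,
    n_per_side: int = 8,
    feature_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Band/feature screen restricted to the gamma sub-bands."""
    return band_feature_analysis(
        cohort,
        bands=subbands,
        features=features,
        config=config,
        n_per_side=n_per_side,
        feature_table=feature_table,
    )


def timeslot_analysis(
    cohort: Sequence[TrialArchive],
    slots: Sequence[str] = ("first20", "middle20", "last20", "full60"),
    bands: Sequence[str] = DEFAULT_EVAL_BANDS,
    features: Sequence[str] = ("activity", "psd"),
    config: ClassifierConfig | None = None,
    n_per_side: int = 8,
) -> pd.DataFrame:
    """Strongest-emotion accuracy per timeslot and (band, feature).

    Rows are timeslots, columns a (band, feature) MultiIndex.
    """
    config = config or ClassifierConfig(kind="knn")
    features = [canonical_feature(f) for f in features]
    band_defs = [get_band(b) for b in bands]
    rows = {}
    for slot_name in slots:
        slot = TimeslotSpec.parse(slot_name)
        table = cohort_feature_table(cohort, bands=band_defs, slot=slot)
        row = {}
        for band in bands:
            for feat in features:
                column = f"{band}_{feat}"
                accuracies = []
                for sid, sub in table.groupby("subject_id", sort=False):
                    subset, labels = _strongest_subset(sub, n_per_side)
                    res = loocv_evaluate(
                        subset[[column]], labels, config, subject_id=sid
                    )
                    accuracies.append(res.accuracy)
                row[(band, feat)] = aggregate_cohort(accuracies)
        rows[slot_name] = row
    out = pd.DataFrame(rows).T
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["band", "feature"])
    return out.loc[
        list(slots), [(b, f) for b in bands for f in features]
    ]


def final_evaluation(
    cohort: Sequence[TrialArchive],
    mode: str = "binary",
    classifier: str = "knn",
    bands: Sequence[str] = DEFAULT_EVAL_BANDS,
    feature_sets: Sequence[Sequence[str]] = DEFAULT_FEATURE_SETS,
    scheme: LabelScheme | None = None,
    config: ClassifierConfig | None = None,
    feature_table: pd.DataFrame | None = None,
    seed: int | None = None,
) -> dict[tuple[str, str], EvalResult]:
    """Full-cohort valence classification over all trials.

    Labels come from the LabelScheme (threshold 5 binary by default, or
    the 3/6 three-class cuts); every (band, feature set) combination is
    evaluated with per-subject LOOCV and cohort-mean aggregation. Returns
    ``{(band, feature_set_name): EvalResult}``.
    """
    scheme = scheme or LabelScheme(mode=mode)
    if scheme.mode != mode:
        scheme = LabelScheme(
            mode=mode,
            binary_threshold=scheme.binary_threshold,
            low_cut=scheme.low_cut,
            high_cut=scheme.high_cut,
        )
    if config is None:
        config = ClassifierConfig(
            kind=classifier, tuner_seed=0 if seed is None else seed
        )
    if feature_table is None:
        feature_table = cohort_feature_table(
            cohort, bands=[get_band(b) for b in bands]
        )
    results: dict[tuple[str, str], EvalResult] = {}
    per_subject_tables = dict(tuple(feature_table.groupby("subject_id", sort=False)))
    for band in bands:
        for feats in feature_sets:
            feats = [canonical_feature(f) for f in feats]
            columns = [f"{band}_{f}" for f in feats]
            evals = {}
            for sid, table in per_subject_tables.items():
                labels = scheme.apply(table["rating_valence"].to_numpy())
                evals[sid] = loocv_evaluate(
                    table[columns], labels, config, subject_id=sid
                )
            mean_acc = aggregate_cohort([e.accuracy for e in evals.values()])
            results[(band, feature_set_name(feats))] = EvalResult(
                per_subject=evals,
                mean_accuracy=mean_acc,
                config=config,
                seed=seed,
            )
    return results


def summarize_evaluation(
    results: Mapping[tuple[str, str], EvalResult]
) -> pd.DataFrame:
    """Feature-set x band matrix of cohort-mean accuracies (%)."""
    table: dict[str, dict[str, float]] = {}
    for (band, fset), result in results.items():
        table.setdefault(fset, {})[band] = result.mean_accuracy
    return pd.DataFrame(table).T


def per_subject_table(
    results: Mapping[tuple[str, str], EvalResult]
) -> pd.DataFrame:
    """Per-subject accuracy breakdown with an ``Average`` bottom row."""
    columns: dict[str, dict[str, float]] = {}
    for (band, fset), result in results.items():
        col = f"{band}/{fset}"
        for sid, ev in result.per_subject.items():
            columns.setdefault(col, {})[sid] = ev.accuracy
    frame = pd.DataFrame(columns)
    frame.loc["Average"] = [
        aggregate_cohort(frame[c].dropna()) for c in frame.columns
    ]
    return frame


def threshold_sensitivity(
    cohort: Sequence[TrialArchive],
    subject_ids: Sequence[str] | None = None,
    thresholds: Sequence[float] = (5.0, 6.0),
    band: str = "alpha",
    features: Sequence[str] = ("activity", "psd"),
    classifier: str = "knn",
    config: ClassifierConfig | None = None,
    feature_table: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rating statistics and re-thresholded accuracies.

    Returns ``(stats, accuracies)``: per listed subject and for the whole
    cohort, the median / mean / population SD of the valence ratings, and
    the binary LOOCV accuracy at each threshold.
    """
    if feature_table is None:
        feature_table = cohort_feature_table(cohort, bands=[get_band(band)])
    per_subject = dict(tuple(feature_table.groupby("subject_id", sort=False)))
    if subject_ids is None:
        subject_ids = list(per_subject)
    columns = [f"{band}_{canonical_feature(f)}" for f in features]

    stats_rows = {}
    for sid in subject_ids:
        r = per_subject[sid]["rating_valence"].to_numpy()
        stats_rows[sid] = {
            "median": float(np.median(r)),
            "mean": float(np.mean(r)),
            "sd": float(np.std(r)),
        }
    pooled = feature_table["rating_valence"].to_numpy()
    stats_rows["all_subjects"] = {
        "median": float(np.median(pooled)),
        "mean": float(np.mean(pooled)),
        "sd": float(np.std(pooled)),
    }
    stats = pd.DataFrame(stats_rows).T

    acc_rows: dict[str, dict[str, float]] = {}
    for threshold in thresholds:
        scheme = LabelScheme(mode="binary", binary_threshold=threshold)
        key = f"threshold={threshold:g}"
        acc_rows[key] = {}
        cohort_accs = []
        for sid, table in per_subject.items():
            labels = scheme.apply(table["rating_valence"].to_numpy())
            if np.unique(labels).size < 2:
                continue  # threshold degenerates this subject's task
            res = loocv_evaluate(
                table[columns],
                labels,
                config or ClassifierConfig(kind=classifier),
                subject_id=sid,
            )
            cohort_accs.append(res.accuracy)
            if sid in subject_ids:
                acc_rows[key][sid] = res.accuracy
        acc_rows[key]["all_subjects"] = aggregate_cohort(cohort_accs)
    return stats, pd.DataFrame(acc_rows)


def five_number_summary(values: np.ndarray) -> dict[str, float]:
    """Minimum, linear-interpolation quartiles, median and maximum."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot summarize an empty group")
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return {
        "min": float(values.min()),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "max": float(values.max()),
        "n": int(values.size),
    }


def export_boxplot_data(
    feature_table: pd.DataFrame,
    labels: Sequence[str],
    bands: Sequence[str] = DEFAULT_EVAL_BANDS,
    features: Sequence[str] = ("activity", "psd"),
) -> pd.DataFrame:
    """Five-number summaries per (feature, band, class), plot-ready.

    Whiskers are the data extremes (no Tukey fence clipping); quartiles
    use linear interpolation.
    """
    labels = np.asarray(list(labels), dtype=object)
    if labels.size != len(feature_table):
        raise ValueError("one label per feature-table row is required")
    rows = []
    for feat in features:
        feat = canonical_feature(feat)
        for band in bands:
            column = f"{band}_{feat}"
            for cls in pd.unique(labels):
                values = feature_table.loc[labels == cls, column].to_numpy()
                summary = five_number_summary(values)
                rows.append(
                    {"feature": feat, "band": band, "class": cls, **summary}
                )
    return pd.DataFrame(rows)
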