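"""Bundled reference table for the cohort-aggregation worked example.

``cohort_reference_accuracies.csv`` holds published per-subject LOOCV
valence accuracies (%) for a 32-subject cohort, for the combined
variance+power feature set in the delta, alpha and fast-gamma bands under
kNN and tuned RBF-SVM classifiers. It serves as a fixed worked example
for :func:`valenscope.classify.aggregate_cohort`: averaging each column
must reproduce the table's published Average row to two decimals.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: Published cohort-mean accuracies (%) for each column of the table.
REFERENCE_MEANS = {
    "knn_delta": 95.0,
    "knn_alpha": 96.33,
    "knn_fast_gamma": 85.55,
    "svm_delta": 97.19,
    "svm_alpha": 97.42,
    "svm_fast_gamma": 87.11,
}


def load_reference_accuracies() -> pd.DataFrame:
    """Per-subject reference accuracies, indexed by subject number."""
    source = resources.files("valenscope.data").joinpath(
        "cohort_reference_accuracies.csv"
    )
    with resources.as_file(source) as path:
        return pd.read_csv(path, index_col="subject")
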