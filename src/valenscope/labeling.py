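"""Mapping continuous valence ratings to class labels.

Self-assessed valence lies on a continuous 1-9 scale (1 = sad, 9 = happy).
Binary classification splits at a threshold (default 5, the conventional
mid-scale split); the three-class scheme uses cuts at 3 and 6 to form
low / neutral / high classes. Boundary conventions are fixed and
configurable: binary "high" requires a rating strictly above the
threshold; three-class "low" is rating <= low_cut and "high" is
rating >= high_cut. Ratings are continuous, so exact boundary hits are
rare in real data, but the conventions make synthetic edge cases
deterministic.

Feature analyses use only each subject's strongest emotions: the trials
with the eight highest and eight lowest ratings, labelled by selection
side, which guarantees a balanced and well-separated two-class task.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

LOW, NEUTRAL, HIGH = "low", "neutral", "high"


@dataclass(frozen=True)
class LabelScheme:
    """Thresholding rules mapping 1-9 ratings to class labels."""

    mode: str = "binary"  # "binary" | "three_class"
    binary_threshold: float = 5.0
    low_cut: float = 3.0
    high_cut: float = 6.0

    def __post_init__(self) -> None:
        if self.mode not in {"binary", "three_class"}:
            raise ValueError(f"unknown label mode {self.mode!r}")
        if not 1 <= self.binary_threshold <= 9:
            raise ValueError("binary threshold must lie in [1, 9]")
        if not 1 <= self.low_cut < self.high_cut <= 9:
            raise ValueError("need 1 <= low_cut < high_cut <= 9")

    def apply(self, ratings: np.ndarray) -> np.ndarray:
        ratings = np.asarray(ratings, dtype=float)
        if self.mode == "binary":
            return np.array(
                [binarize_valence(r, self.binary_threshold) for r in ratings]
            )
        return np.array(
            [three_class_valence(r, self.low_cut, self.high_cut) for r in ratings]
        )


def _check_rating(rating: float) -> float:
    rating = float(rating)
    if not 1.0 <= rating <= 9.0:
        raise ValueError(f"rating {rating} outside the 1-9 scale")
    return rating


def binarize_valence(rating: float, threshold: float = 5.0) -> str:
    """``high`` iff rating > threshold, else ``low``."""
    return HIGH if _check_rating(rating) > threshold else LOW


def three_class_valence(
    rating: float, low_cut: float = 3.0, high_cut: float = 6.0
) -> str:
    """``low`` iff rating <= low_cut, ``high`` iff rating >= high_cut,
    else ``neutral``."""
    rating = _check_rating(rating)
    if rating <= low_cut:
        return LOW
    if rating >= high_cut:
        return HIGH
    return NEUTRAL


def select_strongest(
    ratings: np.ndarray, n_per_side: int = 8
) -> tuple[np.ndarray, np.ndarray]:
    """Indices of the ``n_per_side`` lowest- and highest-rated trials.

    Returns ``(low_indices, high_indices)``, each sorted ascending. Sides
    are disjoint; rating ties are broken by lower trial index, with the
    low side claiming tied trials first.
    """
    ratings = np.asarray(ratings, dtype=float)
    n = ratings.size
    if n < 2 * n_per_side:
        raise ValueError(
            f"need at least {2 * n_per_side} trials for n_per_side="
            f"{n_per_side}, got {n}"
        )
    ascending = np.argsort(ratings, kind="stable")  # ties -> lower index first
    low = ascending[:n_per_side]
    taken = set(low.tolist())
    # Highest ratings, ties by lower index, skipping trials claimed as low.
    descending = sorted(range(n), key=lambda i: (-ratings[i], i))
    high = [i for i in descending if i not in taken][:n_per_side]
    return np.sort(low), np.sort(np.array(high, dtype=low.dtype))
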