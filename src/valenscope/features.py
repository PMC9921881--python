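"""Per-band scalar features of the prefrontal difference signal.

Five descriptors are computed from each band-limited series y[n]:

* **activity** — Hjorth activity, the population variance of y (uV^2);
* **mobility** — sqrt(var(dy)/var(y)), a root-mean-square frequency proxy,
  where dy is the first-difference sequence y[n+1] - y[n];
* **complexity** — mobility(dy)/mobility(y), a waveform-shape measure that
  equals 1 for a pure sinusoid and grows with bandwidth;
* **zero_crossings** — the number of strict sign reversals, a rate proxy
  for the dominant oscillation;
* **psd** — total mean power from the DFT, (1/N^2) * sum_k |Y(k)|^2, which
  by Parseval equals mean(y^2) and hence the activity for zero-mean
  signals.

Conventions that matter for cross-implementation agreement: variances are
population (1/N) variances; the derivative is the unscaled first
difference (no fs factor — the factor cancels in complexity and only
rescales mobility by a dataset-wide constant, removed downstream by
standardization); the DFT is taken without windowing or mean removal
(band-passed input is zero-mean by construction); a zero sample inherits
the most recent nonzero sign when counting crossings, so sinusoids that
hit exact grid zeros are counted deterministically.

A constant input has zero activity and its mobility/complexity are
reported as NaN (a distinguished missing value, not an exception).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .band_filters import BandDef, BandSignal, bandpass_matrix, default_bands
from .eeg_io import TrialArchive, get_channel_pair
from .preprocess import TimeslotSpec, channel_difference, drop_baseline, extract_timeslot

FEATURE_NAMES = ("activity", "mobility", "complexity", "zero_crossings", "psd")

#: Aliases accepted wherever a feature name is configured.
FEATURE_ALIASES = {"variance": "activity", "power": "psd"}


def canonical_feature(name: str) -> str:
    key = name.strip().lower()
    key = FEATURE_ALIASES.get(key, key)
    if key not in FEATURE_NAMES:
        raise KeyError(f"unknown feature {name!r}; options: {FEATURE_NAMES}")
    return key


def _samples(signal_like) -> np.ndarray:
    if isinstance(signal_like, BandSignal):
        return signal_like.samples
    return np.asarray(signal_like, dtype=np.float64)


def hjorth_parameters(signal_like) -> tuple[float, float, float]:
    """Hjorth activity, mobility and complexity of a 1-D series."""
    y = _samples(signal_like)
    if y.size < 3:
        raise ValueError(f"need at least 3 samples, got {y.size}")
    var_y = float(np.var(y))
    if var_y == 0.0:
        return 0.0, float("nan"), float("nan")
    d1 = np.diff(y)
    var_d1 = float(np.var(d1))
    mobility = np.sqrt(var_d1 / var_y)
    if var_d1 == 0.0:
        return var_y, mobility, float("nan")
    d2 = np.diff(d1)
    mobility_d = np.sqrt(float(np.var(d2)) / var_d1)
    return var_y, float(mobility), float(mobility_d / mobility)


def zero_crossings(signal_like) -> int:
    """Number of sign reversals; zero samples inherit the previous sign."""
    y = _samples(signal_like)
    if y.size < 2:
        raise ValueError(f"need at least 2 samples, got {y.size}")
    signs = np.sign(y)
    signs = signs[signs != 0]  # zeros (and leading zeros) carry no reversal
    if signs.size < 2:
        return 0
    return int(np.count_nonzero(signs[1:] != signs[:-1]))


def psd_total_power(signal_like) -> float:
    """Total mean power: the squared DFT magnitudes summed over all bins,
    normalized by N^2 (Parseval: equals mean(y^2))."""
    y = _samples(signal_like)
    if y.size < 2:
        raise ValueError(f"need at least 2 samples, got {y.size}")
    spectrum = np.fft.fft(y)
    return float(np.sum(spectrum.real**2 + spectrum.imag**2) / y.size**2)


def feature_row(signal_like) -> dict[str, float]:
    """All five features of one band-limited series."""
    activity, mobility, complexity = hjorth_parameters(signal_like)
    return {
        "activity": activity,
        "mobility": mobility,
        "complexity": complexity,
        "zero_crossings": float(zero_crossings(signal_like)),
        "psd": psd_total_power(signal_like),
    }


def extract_features(
    archive: TrialArchive,
    pair: tuple[str, str] = ("Fp1", "Fp2"),
    bands: Sequence[BandDef] | None = None,
    slot: TimeslotSpec | None = None,
    order: int = 3,
) -> pd.DataFrame:
    """Per-trial feature table for one subject.

    Each trial runs through baseline removal, Fp1 - Fp2 differencing,
    timeslot extraction (``slot=None`` keeps the entire post-baseline
    series — the full minute for DEAP-geometry trials) and per-band
    zero-phase filtering; the result is a
    DataFrame with one row per trial, metadata columns (``subject_id``,
    ``trial``, plus ``rating_<dim>`` for each recorded rating dimension)
    and one ``{band}_{feature}`` column per band/feature combination.
    """
    if bands is None:
        bands = default_bands()
    chan_a, chan_b = get_channel_pair(archive, *pair)
    diff = channel_difference(chan_a, chan_b)
    diff = drop_baseline(diff, archive.fs, archive.baseline_s)
    if slot is not None:
        diff = extract_timeslot(diff, archive.fs, slot)

    filtered = bandpass_matrix(diff, archive.fs, bands, order=order)
    records = []
    for t in range(archive.n_trials):
        row: dict[str, float | str | int] = {
            "subject_id": archive.subject_id,
            "trial": t,
        }
        for d, dim in enumerate(archive.dimension_names):
            row[f"rating_{dim}"] = archive.ratings[t, d]
        for band in bands:
            try:
                values = feature_row(filtered[band.name][t])
            except ValueError as exc:
                raise ValueError(f"trial {t}, band {band.name}: {exc}") from exc
            for feat, value in values.items():
                row[f"{band.name}_{feat}"] = value
        records.append(row)
    return pd.DataFrame.from_records(records)


def feature_columns(
    bands: Sequence[str], features: Sequence[str]
) -> list[str]:
    """Column names for the given band/feature combination."""
    return [
        f"{band}_{canonical_feature(feat)}" for band in bands for feat in features
    ]
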