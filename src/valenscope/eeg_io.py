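"""Reading, writing and validating EEG trial archives.

The in-memory model is a :class:`TrialArchive`: one subject's stimulus
trials as a ``[n_trials x n_channels x n_samples]`` tensor in microvolts,
together with the per-trial self-assessment ratings (1-9 continuous scale),
the 10/20 montage, the sampling rate and the leading baseline duration.
This mirrors the per-subject layout of the preprocessed DEAP release
(40 trials, 63 s at 128 Hz with a 3 s pre-trial baseline) so that real
data drops in unchanged, while staying format-agnostic.

The native on-disk container is a NumPy ``.npz`` holding the data tensor
and ratings matrix, next to a JSON sidecar carrying the scalar metadata
(subject id, sampling rate, montage, baseline). Single recordings can also
be read from EDF/EDF+ for feature-extraction-only use.

Values are assumed to be microvolts and are never rescaled; every feature
downstream is scale-covariant and classification standardizes per fold, so
absolute units only matter for reporting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import (
    ArchiveValidationError,
    ChannelLookupError,
    EdfFormatError,
    ShapeMismatchError,
    UnsupportedEdfError,
)

RATING_MIN = 1.0
RATING_MAX = 9.0


def _normalize_label(label: str) -> str:
    """10/20 labels compare case-insensitively on the letter part and
    exactly on the digits; upper-casing the whole label achieves both."""
    return label.strip().upper()


@dataclass(frozen=True)
class Montage:
    """An ordered set of 10/20 electrode labels (e.g. ``Fp1``, ``Fp2``)."""

    channel_names: tuple[str, ...]
    reference_note: str = ""

    def __init__(self, channel_names: Sequence[str], reference_note: str = ""):
        object.__setattr__(self, "channel_names", tuple(channel_names))
        object.__setattr__(self, "reference_note", reference_note)
        normalized = [_normalize_label(c) for c in self.channel_names]
        if len(set(normalized)) != len(normalized):
            raise ArchiveValidationError(
                f"montage labels are not unique: {self.channel_names}"
            )

    def __len__(self) -> int:
        return len(self.channel_names)

    def index_of(self, label: str) -> int:
        """Index of ``label`` (case-insensitive letters, exact digits)."""
        target = _normalize_label(label)
        for i, name in enumerate(self.channel_names):
            if _normalize_label(name) == target:
                return i
        raise ChannelLookupError(
            f"channel {label!r} not in montage; available: "
            f"{list(self.channel_names)}"
        )


@dataclass
class TrialArchive:
    """One subject's trials: signals, ratings and recording metadata."""

    subject_id: str
    data: np.ndarray  # [n_trials, n_channels, n_samples], microvolts
    ratings: np.ndarray  # [n_trials, n_dimensions], 1-9 scale
    dimension_names: tuple[str, ...]
    montage: Montage
    fs: float
    baseline_s: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.ratings = np.asarray(self.ratings, dtype=np.float64)
        self.dimension_names = tuple(self.dimension_names)
        self.validate()

    def validate(self) -> None:
        if self.data.ndim != 3:
            raise ShapeMismatchError(
                f"data must be [n_trials x n_channels x n_samples]; "
                f"got {self.data.ndim}-d array of shape {self.data.shape}"
            )
        n_trials, n_channels, _ = self.data.shape
        if n_trials < 1:
            raise ArchiveValidationError("archive must contain at least one trial")
        if self.fs <= 0:
            raise ArchiveValidationError(f"sampling rate must be positive, got {self.fs}")
        if self.baseline_s < 0:
            raise ArchiveValidationError("baseline duration cannot be negative")
        if len(self.montage) != n_channels:
            raise ShapeMismatchError(
                f"montage has {len(self.montage)} labels but data has "
                f"{n_channels} channels"
            )
        if self.ratings.size:
            if self.ratings.ndim != 2 or self.ratings.shape[0] != n_trials:
                raise ShapeMismatchError(
                    f"ratings must be [n_trials x n_dims] = [{n_trials} x *]; "
                    f"got shape {self.ratings.shape}"
                )
            if len(self.dimension_names) != self.ratings.shape[1]:
                raise ShapeMismatchError(
                    f"{len(self.dimension_names)} dimension names for "
                    f"{self.ratings.shape[1]} rating columns"
                )
            bad = np.where(
                (self.ratings < RATING_MIN) | (self.ratings > RATING_MAX)
            )
            if bad[0].size:
                trial, dim = int(bad[0][0]), int(bad[1][0])
                raise ArchiveValidationError(
                    f"rating {self.ratings[trial, dim]} outside "
                    f"[{RATING_MIN}, {RATING_MAX}] at trial {trial}, "
                    f"dimension {self.dimension_names[dim]!r}"
                )

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def valence(self) -> np.ndarray:
        """Per-trial valence ratings."""
        try:
            col = self.dimension_names.index("valence")
        except ValueError:
            raise ArchiveValidationError(
                f"archive has no 'valence' dimension: {self.dimension_names}"
            ) from None
        return self.ratings[:, col]


def get_channel_pair(
    archive: TrialArchive, a: str, b: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial sample series of channels ``a`` and ``b``, order preserved.

    Returns two ``[n_trials x n_samples]`` arrays. Lookup is
    case-insensitive on the letter part of the 10/20 label.
    """
    ia = archive.montage.index_of(a)
    ib = archive.montage.index_of(b)
    return archive.data[:, ia, :], archive.data[:, ib, :]


# ---------------------------------------------------------------------------
# Native container: <stem>.npz + <stem>.json sidecar


def save_trial_archive(archive: TrialArchive, path: str | Path) -> Path:
    """Write an archive as ``<stem>.npz`` plus a ``<stem>.json`` sidecar."""
    stem = Path(path)
    if stem.suffix in {".npz", ".json"}:
        stem = stem.with_suffix("")
    np.savez(stem.with_suffix(".npz"), data=archive.data, ratings=archive.ratings)
    sidecar = {
        "subject_id": archive.subject_id,
        "fs": archive.fs,
        "baseline_s": archive.baseline_s,
        "dimension_names": list(archive.dimension_names),
        "montage": {
            "channel_names": list(archive.montage.channel_names),
            "reference_note": archive.montage.reference_note,
        },
    }
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return stem.with_suffix(".npz")


def load_trial_archive(
    path: str | Path,
    montage: Montage | None = None,
    fs: float | None = None,
    baseline_s: float | None = None,
) -> TrialArchive:
    """Load a native archive, validating shapes and rating bounds.

    Metadata comes from the JSON sidecar when present; explicit ``montage``,
    ``fs`` and ``baseline_s`` arguments override it (and are required when
    no sidecar exists). No resampling or rescaling is performed.
    """
    stem = Path(path)
    if stem.suffix in {".npz", ".json"}:
        stem = stem.with_suffix("")
    npz_path = stem.with_suffix(".npz")
    if not npz_path.exists():
        raise FileNotFoundError(npz_path)
    with np.load(npz_path) as payload:
        data = payload["data"]
        ratings = payload["ratings"]

    sidecar: dict = {}
    sidecar_path = stem.with_suffix(".json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
    if montage is None:
        if "montage" not in sidecar:
            raise ArchiveValidationError(
                f"no montage given and no sidecar at {sidecar_path}"
            )
        montage = Montage(
            sidecar["montage"]["channel_names"],
            sidecar["montage"].get("reference_note", ""),
        )
    if fs is None:
        fs = sidecar.get("fs")
        if fs is None:
            raise ArchiveValidationError("no sampling rate given or stored")
    if baseline_s is None:
        baseline_s = sidecar.get("baseline_s", 0.0)
    dimension_names = tuple(sidecar.get("dimension_names", ())) or tuple(
        f"dim{i}" for i in range(ratings.shape[1] if ratings.ndim == 2 else 0)
    )
    return TrialArchive(
        subject_id=sidecar.get("subject_id", stem.name),
        data=data,
        ratings=ratings,
        dimension_names=dimension_names,
        montage=montage,
        fs=float(fs),
        baseline_s=float(baseline_s),
    )


# ---------------------------------------------------------------------------
# EDF/EDF+

_EDF_HEADER_LEN = 256
_EDF_SIGNAL_FIELDS = (  # (name, bytes per signal)
    ("label", 16),
    ("transducer", 80),
    ("dimension", 8),
    ("physical_min", 8),
    ("physical_max", 8),
    ("digital_min", 8),
    ("digital_max", 8),
    ("prefiltering", 80),
    ("samples_per_record", 8),
    ("reserved", 32),
)


def _scan_edf_header(path: Path) -> dict:
    """Parse just enough of the EDF header to validate layout up front.

    mne's reader papers over mixed per-channel sampling rates; the contract
    here is to reject them explicitly, so rates are checked from the raw
    header before the file is handed to mne.
    """
    raw = path.read_bytes()
    if len(raw) < _EDF_HEADER_LEN:
        raise EdfFormatError(f"{path}: too short to hold an EDF header")
    header = raw[:_EDF_HEADER_LEN]
    try:
        n_records = int(header[236:244].decode("ascii").strip())
        record_duration = float(header[244:252].decode("ascii").strip())
        n_signals = int(header[252:256].decode("ascii").strip())
    except (UnicodeDecodeError, ValueError) as exc:
        raise EdfFormatError(f"{path}: malformed EDF header ({exc})") from exc
    if n_signals < 1:
        raise EdfFormatError(f"{path}: EDF declares {n_signals} signals")
    sig_header_len = n_signals * sum(width for _, width in _EDF_SIGNAL_FIELDS)
    if len(raw) < _EDF_HEADER_LEN + sig_header_len:
        raise EdfFormatError(f"{path}: truncated EDF signal headers")
    block = raw[_EDF_HEADER_LEN : _EDF_HEADER_LEN + sig_header_len]
    offset = 0
    fields: dict[str, list[str]] = {}
    for name, width in _EDF_SIGNAL_FIELDS:
        vals = []
        for i in range(n_signals):
            chunk = block[offset + i * width : offset + (i + 1) * width]
            vals.append(chunk.decode("ascii", errors="replace").strip())
        fields[name] = vals
        offset += n_signals * width
    try:
        samples_per_record = [int(v) for v in fields["samples_per_record"]]
    except ValueError as exc:
        raise EdfFormatError(f"{path}: bad samples-per-record field") from exc
    labels = fields["label"]
    # EDF+ annotation channels carry no waveform and may use any rate.
    data_rates = {
        spr
        for lbl, spr in zip(labels, samples_per_record)
        if "EDF ANNOTATIONS" not in lbl.upper()
    }
    if record_duration <= 0:
        raise EdfFormatError(f"{path}: non-positive record duration")
    if len(data_rates) > 1:
        rates = sorted(s / record_duration for s in data_rates)
        raise UnsupportedEdfError(
            f"{path}: heterogeneous per-channel sampling rates {rates} Hz "
            "are not supported"
        )
    return {
        "n_records": n_records,
        "record_duration": record_duration,
        "n_signals": n_signals,
        "labels": labels,
    }


def load_edf(path: str | Path) -> TrialArchive:
    """Read an EDF/EDF+ recording as a one-trial archive (microvolts).

    Channel labels and the sampling rate come from the EDF headers; the
    ratings matrix is empty (feature-extraction-only mode). Files with
    heterogeneous per-channel sampling rates are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _scan_edf_header(path)

    import mne  # heavy import, deferred

    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # mne raises a mix of ValueError/OSError
        raise EdfFormatError(f"{path}: unreadable EDF ({exc})") from exc
    data_uv = raw.get_data(units="uV")
    return TrialArchive(
        subject_id=path.stem,
        data=data_uv[np.newaxis, :, :],
        ratings=np.empty((1, 0)),
        dimension_names=(),
        montage=Montage(raw.ch_names),
        fs=float(raw.info["sfreq"]),
        baseline_s=0.0,
    )


def write_edf(
    path: str | Path,
    data: np.ndarray,
    fs: float,
    labels: Sequence[str],
    physical_dimension: str = "uV",
) -> Path:
    """Write channels x samples data as a minimal EDF file.

    A deliberately small writer (1-second data records, 16-bit samples,
    per-channel physical scaling) sufficient for round-trip testing and for
    exporting synthetic recordings; no EDF+ annotations are produced. The
    sample count must be an integer number of 1-second records.
    """
    path = Path(path)
    data = np.atleast_2d(np.asarray(data, dtype=np.float64))
    n_channels, n_samples = data.shape
    if len(labels) != n_channels:
        raise ValueError(f"{len(labels)} labels for {n_channels} channels")
    spr = int(round(fs))
    if spr != fs or n_samples % spr:
        raise ValueError(
            "writer supports integer sampling rates and whole-second "
            f"durations; got fs={fs}, n_samples={n_samples}"
        )
    n_records = n_samples // spr

    def pad(value: str, width: int) -> bytes:
        encoded = value.encode("ascii")
        if len(encoded) > width:
            raise ValueError(f"field {value!r} exceeds {width} bytes")
        return encoded.ljust(width)

    # Round physical limits to what the 8-char ASCII fields can carry so the
    # scaling used for quantization matches what a reader will reconstruct.
    phys_min = np.array(
        [float(f"{v:.6g}") for v in np.minimum(data.min(axis=1) * 1.001, -1.0)]
    )
    phys_max = np.array(
        [float(f"{v:.6g}") for v in np.maximum(data.max(axis=1) * 1.001, 1.0)]
    )
    dig_min, dig_max = -32768, 32767

    header = b"".join(
        [
            pad("0", 8),  # version
            pad("X X X X", 80),  # patient id
            pad("Startdate X X X X", 80),  # recording id
            pad("01.01.00", 8),
            pad("00.00.00", 8),
            pad(str(_EDF_HEADER_LEN + n_channels * 256), 8),
            pad("", 44),
            pad(str(n_records), 8),
            pad("1", 8),  # record duration, seconds
            pad(str(n_channels), 4),
        ]
    )
    per_signal = {
        "label": [str(l) for l in labels],
        "transducer": [""] * n_channels,
        "dimension": [physical_dimension] * n_channels,
        "physical_min": [f"{v:.6g}" for v in phys_min],
        "physical_max": [f"{v:.6g}" for v in phys_max],
        "digital_min": [str(dig_min)] * n_channels,
        "digital_max": [str(dig_max)] * n_channels,
        "prefiltering": [""] * n_channels,
        "samples_per_record": [str(spr)] * n_channels,
        "reserved": [""] * n_channels,
    }
    signal_header = b"".join(
        pad(per_signal[name][i], width)
        for name, width in _EDF_SIGNAL_FIELDS
        for i in range(n_channels)
    )

    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.rint((data - phys_min[:, None]) * scale[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    with path.open("wb") as fh:
        fh.write(header)
        fh.write(signal_header)
        for rec in range(n_records):
            chunk = digital[:, rec * spr : (rec + 1) * spr]
            fh.write(chunk.tobytes())
    return path
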