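import numpy as np
import pytest

from valenscope import SimSpec, TrialArchive, Montage
from valenscope.features import extract_features
from valenscope.band_filters import get_band
from valenscope.synthetic import generate_subject, subject_seed


def sinusoid(freq: float, fs: float = 128.0, seconds: float = 60.0, amp: float = 1.0):
    n = int(round(seconds * fs))
    return amp * np.sin(2 * np.pi * freq * np.arange(n) / fs)


@pytest.fixture(scope="session")
def planted_subject() -> TrialArchive:
    """One synthetic subject with the default planted alpha asymmetry."""
    spec = SimSpec(seed=11)
    return generate_subject(spec, subject_seed(spec.seed, 0), "planted01")


@pytest.fixture(scope="session")
def planted_alpha_features(planted_subject):
    return extract_features(planted_subject, bands=[get_band("alpha")])


@pytest.fixture(scope="session")
def null_subject() -> TrialArchive:
    """A subject with no class effect (variance ratio 1)."""
    spec = SimSpec(effect_ratio=1.0, seed=12)
    return generate_subject(spec, subject_seed(spec.seed, 0), "null01")


@pytest.fixture()
def tiny_archive() -> TrialArchive:
    """A minimal two-channel archive with deterministic content."""
    rng = np.random.default_rng(5)
    data = rng.standard_normal((4, 2, 256))
    ratings = np.array([[2.0], [4.0], [6.5], [8.0]])
    return TrialArchive(
        subject_id="tiny",
        data=data,
        ratings=ratings,
        dimension_names=("valence",),
        montage=Montage(("Fp1", "Fp2")),
        fs=128.0,
        baseline_s=0.0,
    )
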