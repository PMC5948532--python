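import numpy as np
import pytest

from semgkit import classifiers as clf
from semgkit import synthetic as syn
from semgkit.features import rms_windows


@pytest.fixture(scope="session")
def muscle_model():
    return syn.MuscleModel()


@pytest.fixture(scope="session")
def clean_profile():
    """A well-coordinated, low-fat subject."""
    return syn.SubjectProfile(co_activation=0.15, attenuation=0.95)


@pytest.fixture(scope="session")
def clean_features(muscle_model, clean_profile):
    """Train/test RMS streams of a clean subject over all gestures."""
    seq = syn.standard_sequence(hold=2.0, rest=1.0, reps=2)
    train = syn.simulate_recording(muscle_model, clean_profile, seq, seed=11)
    test = syn.simulate_recording(muscle_model, clean_profile, seq, seed=12)
    return (
        rms_windows(train, drop_transitions=True),
        rms_windows(test, drop_transitions=True),
    )


@pytest.fixture(scope="session")
def trained_ann(clean_features):
    """ANN trained once on the clean subject, reused across tests."""
    f_train, f_test = clean_features
    encoding = clf.directional_encoding()
    model, report = clf.train_ann(f_train, f_test, encoding, seed=5)
    return model, report, encoding


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
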