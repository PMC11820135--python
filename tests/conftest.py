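"""Shared fixtures: synthetic subjects and (expensively) trained decoders.

The trained decoders are session-scoped because NumPy training is the
costly part of the suite; every consumer treats them as read-only.
"""

import numpy as np
import pytest

from miglove import evaluation, model, preprocessing, spectral, synthetic


@pytest.fixture(scope="session")
def strong_profile():
    """A subject with strong event-related desynchronization."""
    return synthetic.SubjectProfile(effect_size=0.8, seed=11)


@pytest.fixture(scope="session")
def strong_batch(strong_profile):
    return synthetic.generate_epoch_batch(strong_profile, n_per_class=200,
                                          seed=11)


@pytest.fixture(scope="session")
def strong_split(strong_batch):
    return preprocessing.split_by_group(strong_batch, group="trial",
                                        test_fraction=0.25, seed=11)


@pytest.fixture(scope="session")
def trained_decoder(strong_split):
    """Decoder trained on the strong-effect subject (held-out trial split)."""
    train_set, test_set = strong_split
    decoder = model.build_model(seed=11)
    model.train(decoder, train_set, test_set,
                schedule=model.TrainingSchedule(max_epochs=50, patience=10),
                seed=11)
    return decoder


@pytest.fixture(scope="session")
def strong_report(trained_decoder, strong_split):
    _, test_set = strong_split
    proba = trained_decoder.predict_proba(spectral.featurize_epochs(test_set))
    predicted = [model.CLASSES[i] for i in proba.argmax(axis=1)]
    return evaluation.evaluate_predictions(test_set.labels, predicted,
                                           scores=proba[:, 1])


@pytest.fixture(scope="session")
def null_result():
    """Decoder trained on a zero-effect subject, with its held-out report."""
    profile = synthetic.SubjectProfile(effect_size=0.0, seed=7)
    batch = synthetic.generate_epoch_batch(profile, n_per_class=150, seed=7)
    train_set, test_set = preprocessing.split_by_group(
        batch, group="trial", test_fraction=0.25, seed=7)
    decoder = model.build_model(seed=7)
    model.train(decoder, train_set, test_set,
                schedule=model.TrainingSchedule(max_epochs=30, patience=8),
                seed=7)
    proba = decoder.predict_proba(spectral.featurize_epochs(test_set))
    predicted = [model.CLASSES[i] for i in proba.argmax(axis=1)]
    report = evaluation.evaluate_predictions(test_set.labels, predicted,
                                             scores=proba[:, 1])
    return decoder, report


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
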