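"""End-to-end orchestration: recording -> filtered epochs -> trained decoder.

These helpers glue the stages together for the CLI and for programmatic
use; each stage remains individually importable and testable.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from . import evaluation, model, preprocessing, spectral
from .io import Recording
from .preprocessing import EpochSet, FilterSpec

__all__ = ["preprocess_recording", "train_eval"]


def preprocess_recording(recording: Recording, pp_cfg: dict) -> EpochSet:
    """Filter, crop and epoch one recording per a preprocessing config block."""
    spec = FilterSpec(
        band_low=pp_cfg.get("band_low", 0.5),
        band_high=pp_cfg.get("band_high", 45.0),
        notch_freq=pp_cfg.get("notch_freq", 60.0),
        filter_order=pp_cfg.get("filter_order", 4),
        notch_q=pp_cfg.get("notch_q", 30.0),
    )
    filtered = preprocessing.apply_filters(recording, spec)
    cropped = preprocessing.crop_phases(filtered, pp_cfg.get("trim_s", 3.0))
    return preprocessing.make_epochs(
        cropped,
        length_s=pp_cfg.get("epoch_length_s", 1.0),
        overlap_s=pp_cfg.get("overlap_s", 0.75),
    )


def train_eval(epochs: EpochSet, pp_cfg: dict, model_cfg: dict,
               seed: int = 0) -> tuple[model.MIDecoder,
                                       evaluation.MetricsReport]:
    """Split -> train -> evaluate; returns the decoder and the test report."""
    train_set, test_set = preprocessing.split_by_group(
        epochs,
        group=pp_cfg.get("split_group", "trial"),
        test_fraction=pp_cfg.get("test_fraction", 0.25),
        seed=seed,
    )
    cfg = model.ModelConfig(
        symmetric_blocks=model_cfg.get("symmetric_blocks", False),
    )
    decoder = model.build_model(cfg, seed=seed)
    schedule = model.TrainingSchedule(
        learning_rate=model_cfg.get("learning_rate", 1e-3),
        batch_size=model_cfg.get("batch_size", 32),
        max_epochs=model_cfg.get("max_epochs", 100),
        patience=model_cfg.get("patience", 10),
    )
    loss = model.FocalLossParams(
        gamma=model_cfg.get("gamma", 2.0),
        alpha=model.inverse_frequency_alpha(train_set.labels),
    )
    model.train(decoder, train_set, test_set, loss=loss, schedule=schedule,
                seed=seed)
    feats = spectral.featurize_epochs(test_set)
    proba = decoder.predict_proba(feats)
    predicted = [model.CLASSES[i] for i in proba.argmax(axis=1)]
    report = evaluation.evaluate_predictions(
        test_set.labels, predicted, scores=proba[:, 1])
    return decoder, report
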