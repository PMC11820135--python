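# miglove

Motor-imagery EEG decoding for a soft pneumatic rehabilitation glove —
from raw 16-channel EEG to a transformer classifier and a closed-loop
pressure controller, with a protocol-faithful synthetic EEG generator and a
simulated pneumatic plant in place of human subjects and hardware.

## Who this is for

Researchers prototyping EEG brain–computer interfaces for hand
rehabilitation: the package lets every stage — preprocessing, spectral
featurization, classification, closed-loop control — be developed and
tested end to end without recording a single subject, then applied
unchanged to real CSV/EDF recordings.

## The science in brief

During imagined hand movement, the mu (~10 Hz) and beta (~20 Hz) rhythms
over sensorimotor cortex drop in amplitude (event-related
desynchronization, ERD). The decoder exploits this: each 1 s epoch of
16-channel EEG is mapped by FFT to a magnitude spectrum at the integer
frequencies 1–44 Hz, giving a (44 × 16) matrix over the [1, 45) Hz band
that spans the canonical delta/theta/alpha/beta/gamma rhythms. A
transformer encoder treats the 44 frequency bins as sequence positions:
sinusoidal positional encoding is added, two self-attention blocks (4
heads of size 64, feed-forward width 128) extract cross-frequency,
cross-channel structure, global average pooling and a small dense head
produce P(rest), P(fist). Training minimizes focal loss

    FL(p_c) = −α_c (1 − p_c)^γ log p_c        (γ = 2, α ∝ inverse class frequency)

which down-weights easy examples so the minority "fist" class is not
swamped. The decoded intent s_t ∈ {0, 1} drives a bang-bang pneumatic
controller: intent with pressure inside (P_min, P_max) runs the
pressurizing pump (+ΔP per step); at P_max the vacuum pump pulls back;
overpressure triggers a vent-and-stop safety layer. The plant (pumps,
valves, sensor) is simulated first-order.

The synthetic generator produces 1/f background noise plus alpha/beta
oscillators per channel; during motor-imagery phases the oscillator
amplitudes on sensorimotor channels are multiplied by (1 − effect_size).
It follows a three-phase protocol (motor execution / motor imagery / rest,
16 s each, 6 trials × 3 sessions = 864 s per subject), and `effect_size=0`
yields an exact null for calibration.

## Worked example

```python
from miglove import synthetic, preprocessing, spectral, model, evaluation

profile = synthetic.SubjectProfile(effect_size=0.8, seed=11)
batch = synthetic.generate_epoch_batch(profile, n_per_class=200, seed=11)
train_set, test_set = preprocessing.split_by_group(batch, "trial", 0.25, seed=11)

decoder = model.build_model(seed=11)
model.train(decoder, train_set, test_set, seed=11)

proba = decoder.predict_proba(spectral.featurize_epochs(test_set))
pred = [model.CLASSES[i] for i in proba.argmax(axis=1)]
report = evaluation.evaluate_predictions(test_set.labels, pred, scores=proba[:, 1])
print(f"accuracy={report.accuracy:.3f} f1={report.f1:.3f} "
      f"kappa={report.kappa:.3f} auc={report.auc:.3f}")
```

With this strong-ERD subject (80% mu/beta suppression) the held-out
trial-level split is decoded essentially perfectly:

```
accuracy=1.000 f1=1.000 kappa=1.000 auc=1.000
```

With `effect_size=0.0` the same pipeline lands at chance (AUC ≈ 0.5),
confirming the decoder finds nothing when nothing was generated.

The same flow from the shell:

```
miglove generate   --config cfg.yaml --out data/
miglove train-eval --config cfg.yaml --data data/ --out run/
miglove simulate   --config cfg.yaml --checkpoint run/subject1.decoder.zip \
                   --script intents.txt --out trajectory.csv
```

where `intents.txt` holds lines like `fist 10` / `rest 5` (label and
duration in seconds).

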