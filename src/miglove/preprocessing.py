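"""Signal chain for motor-imagery EEG: filtering, cropping, epoching, splits.

The chain mirrors a standard MI protocol: zero-phase 0.5-45 Hz bandpass plus
a 60 Hz notch, removal of the first and last 3 s of every task phase (the
transition period where subjects start/stop the task), segmentation into 1 s
windows with 0.75 s overlap (0.25 s hop), and a leakage-safe train/test
split.  Because neighbouring windows share 75% of their samples, any split
that separates windows from the same trial into train and test inflates test
metrics; the split therefore operates on whole trials (or sessions).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import signal as sps

from .io import Annotation, Recording

__all__ = [
    "FilterSpec",
    "EpochSet",
    "DEFAULT_LABEL_MAP",
    "apply_filters",
    "crop_phases",
    "make_epochs",
    "split_by_group",
    "n_epochs_in_interval",
]

#: Motor-imagery epochs become the actionable "fist" class; executed-movement
#: epochs are excluded so the decoder sees imagination only.
DEFAULT_LABEL_MAP: Mapping[str, str | None] = {
    "motor_imagery": "fist",
    "rest": "rest",
    "motor_execution": None,
}


@dataclass(frozen=True)
class FilterSpec:
    """Bandpass + notch filter parameters.

    Defaults: 0.5-45 Hz 4th-order Butterworth bandpass and a 60 Hz notch of
    quality 30, both applied forward-backward (zero phase).
    """

    band_low: float = 0.5
    band_high: float = 45.0
    notch_freq: float = 60.0
    filter_order: int = 4
    notch_q: float = 30.0

    def validate(self, fs: float) -> None:
        nyq = fs / 2.0
        if not (0 < self.band_low < self.band_high):
            raise ValueError("require 0 < band_low < band_high")
        if self.band_high >= nyq:
            raise ValueError(
                f"band_high {self.band_high} Hz >= Nyquist {nyq} Hz"
            )
        if not (self.band_low < self.notch_freq < nyq):
            raise ValueError(
                f"notch_freq {self.notch_freq} Hz outside (band_low, Nyquist)"
            )


@dataclass
class EpochSet:
    """Labeled fixed-length windows with per-epoch provenance.

    ``windows`` has shape ``(n_epochs, n_channels, n_samples_per_epoch)`` in
    microvolts; ``provenance[i]`` records the trial, session, phase and onset
    each window was cut from, which the group split relies on.
    """

    windows: np.ndarray
    labels: list[str]
    fs: float
    provenance: list[dict] = field(default_factory=list)
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=np.float64)
        if self.windows.ndim != 3:
            raise ValueError("windows must be (n_epochs, n_channels, n_samples)")
        n = self.windows.shape[0]
        if len(self.labels) != n:
            raise ValueError("one label per epoch required")
        if self.provenance and len(self.provenance) != n:
            raise ValueError("one provenance record per epoch required")
        if not self.provenance:
            self.provenance = [
                {"trial": 0, "session": 0, "phase": "", "onset_s": 0.0}
                for _ in range(n)
            ]

    def __len__(self) -> int:
        return self.windows.shape[0]

    def subset(self, idx: Sequence[int]) -> "EpochSet":
        idx = list(idx)
        return EpochSet(
            self.windows[idx],
            [self.labels[i] for i in idx],
            self.fs,
            [self.provenance[i] for i in idx],
            list(self.channel_names),
        )

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for lab in self.labels:
            counts[lab] = counts.get(lab, 0) + 1
        return counts


def apply_filters(recording: Recording, spec: FilterSpec | None = None) -> Recording:
    """Zero-phase bandpass + notch filter; shape and annotations unchanged."""
    spec = spec or FilterSpec()
    spec.validate(recording.fs)
    sos = sps.butter(spec.filter_order, [spec.band_low, spec.band_high],
                     btype="bandpass", fs=recording.fs, output="sos")
    b_notch, a_notch = sps.iirnotch(spec.notch_freq, spec.notch_q, fs=recording.fs)
    out = sps.sosfiltfilt(sos, recording.samples, axis=1)
    out = sps.filtfilt(b_notch, a_notch, out, axis=1)
    return Recording(out, recording.fs, list(recording.channel_names),
                     list(recording.annotations))


def crop_phases(recording: Recording, trim_s: float = 3.0) -> Recording:
    """Shrink every phase annotation by ``trim_s`` at both ends.

    The continuous signal is untouched; only epoch eligibility changes, so
    filters always see uninterrupted data and the transition transients land
    outside every eligible interval.
    """
    if trim_s < 0:
        raise ValueError("trim_s must be non-negative")
    cropped: list[Annotation] = []
    for a in recording.annotations:
        new_dur = a.duration_s - 2 * trim_s
        if new_dur <= 0:
            raise ValueError(
                f"phase {a.phase!r} of trial {a.trial} (session {a.session}) "
                f"lasts {a.duration_s}s, too short to trim {trim_s}s per end"
            )
        cropped.append(Annotation(a.onset_s + trim_s, new_dur, a.phase,
                                  a.trial, a.session))
    return Recording(recording.samples, recording.fs,
                     list(recording.channel_names), cropped)


def n_epochs_in_interval(duration_s: float, length_s: float, hop_s: float,
                         fs: float) -> int:
    """Number of windows of ``length_s`` at hop ``hop_s`` inside an interval.

    Computed in integer samples: ``floor((T - L)/hop) + 1`` for T >= L,
    else 0.
    """
    t = int(round(duration_s * fs))
    ln = int(round(length_s * fs))
    hop = int(round(hop_s * fs))
    if t < ln:
        return 0
    return (t - ln) // hop + 1


def make_epochs(recording: Recording, length_s: float = 1.0,
                overlap_s: float = 0.75,
                label_map: Mapping[str, str | None] | None = None) -> EpochSet:
    """Cut sliding windows from every annotated (eligible) interval.

    Phases mapping to ``None`` in ``label_map`` are excluded.  Windows never
    cross an interval boundary; intervals shorter than one window yield zero
    epochs.
    """
    if label_map is None:
        label_map = DEFAULT_LABEL_MAP
    if not (0 <= overlap_s < length_s):
        raise ValueError("require 0 <= overlap_s < length_s")
    fs = recording.fs
    len_n = int(round(length_s * fs))
    hop_n = int(round((length_s - overlap_s) * fs))
    if hop_n < 1:
        raise ValueError("hop shorter than one sample")
    windows, labels, prov = [], [], []
    for a in recording.annotations:
        if a.phase not in label_map:
            raise KeyError(f"label_map has no entry for phase {a.phase!r}")
        cls = label_map[a.phase]
        if cls is None:
            continue
        start_n = int(round(a.onset_s * fs))
        stop_n = start_n + int(round(a.duration_s * fs))
        pos = start_n
        while pos + len_n <= stop_n:
            windows.append(recording.samples[:, pos:pos + len_n])
            labels.append(cls)
            prov.append({"trial": a.trial, "session": a.session,
                         "phase": a.phase, "onset_s": pos / fs})
            pos += hop_n
    arr = (np.stack(windows) if windows
           else np.zeros((0, recording.n_channels, len_n)))
    return EpochSet(arr, labels, fs, prov, list(recording.channel_names))


def _group_key(p: dict, group: str):
    if group == "trial":
        return (p["session"], p["trial"])
    if group == "session":
        return p["session"]
    raise ValueError(f"group must be 'trial' or 'session', got {group!r}")


def split_by_group(epochs: EpochSet, group: str = "trial",
                   test_fraction: float = 0.25,
                   seed: int = 0) -> tuple[EpochSet, EpochSet]:
    """Leakage-safe train/test split: whole groups go to one partition.

    Groups are stratified by their majority class so both classes appear on
    both sides; the split is deterministic in ``seed``.
    """
    if not (0 < test_fraction < 1):
        raise ValueError("test_fraction must lie in (0, 1)")
    keys = [_group_key(p, group) for p in epochs.provenance]
    unique = sorted(set(keys))
    if len(unique) < 2:
        raise ValueError(
            f"need >= 2 {group} groups to split, found {len(unique)}"
        )
    # majority class per group, for stratification
    by_class: dict[str, list] = {}
    for g in unique:
        labs = [epochs.labels[i] for i, k in enumerate(keys) if k == g]
        maj = max(sorted(set(labs)), key=labs.count)
        by_class.setdefault(maj, []).append(g)

    rng = np.random.default_rng(seed)
    n_test_total = max(1, int(round(len(unique) * test_fraction)))
    test_groups: set = set()
    for cls in sorted(by_class):
        groups = by_class[cls]
        share = max(0, int(round(len(groups) * test_fraction)))
        share = min(share, len(groups) - 1) if len(groups) > 1 else share
        perm = rng.permutation(len(groups))
        test_groups.update(groups[i] for i in perm[:share])
    # top up if rounding left the test side empty
    while len(test_groups) < min(n_test_total, len(unique) - 1) and \
            len(test_groups) < len(unique) - 1:
        remaining = [g for g in unique if g not in test_groups]
        test_groups.add(remaining[int(rng.integers(len(remaining)))])

    test_idx = [i for i, k in enumerate(keys) if k in test_groups]
    train_idx = [i for i, k in enumerate(keys) if k not in test_groups]
    train, test = epochs.subset(train_idx), epochs.subset(test_idx)
    classes = set(epochs.labels)
    if len(classes) > 1:
        for part, name in ((train, "train"), (test, "test")):
            if set(part.labels) != classes:
                raise ValueError(
                    f"stratification impossible: {name} partition is missing "
                    f"class(es) {classes - set(part.labels)}"
                )
    return train, test
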