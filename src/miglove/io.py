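"""Read/write annotated multichannel EEG recordings and epoch sets.

The on-disk dialects are:

* **CSV** — one header row of channel names, one column per channel, one
  sample per row, values in microvolts.  Phase annotations travel in a
  sidecar file ``<name>.annotations.csv`` with columns
  ``onset_s,duration_s,phase,trial,session`` (plain CSV has no annotation
  standard, so the sidecar is this package's convention).
* **EDF+** — 16-bit European Data Format with annotations stored in the
  standard ``EDF Annotations`` channel, for interchange with common EEG
  tooling.  Reading goes through :mod:`mne`; writing is a minimal EDF+
  emitter (whole-second records, per-channel physical scaling).

Epoch sets round-trip through NumPy ``.npz`` archives.
"""

from __future__ import annotations

import csv
import io as _stdio
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "PHASE_LABELS",
    "Annotation",
    "Recording",
    "FormatError",
    "read_recording",
    "write_recording",
    "select_channels",
    "save_epochs",
    "load_epochs",
]

#: Valid phase labels for the three-phase rehabilitation protocol.
PHASE_LABELS = ("motor_execution", "motor_imagery", "rest")

#: Default 16-channel 10-20 montage (Cyton+Daisy ordering).
DEFAULT_MONTAGE = (
    "Fp1", "Fp2", "C3", "C4", "P7", "P8", "O1", "O2",
    "F7", "F8", "F3", "F4", "T7", "T8", "P3", "P4",
)


class FormatError(ValueError):
    """Raised when an on-disk recording violates the expected dialect."""


@dataclass(frozen=True)
class Annotation:
    """One phase interval: ``[onset_s, onset_s + duration_s)`` seconds."""

    onset_s: float
    duration_s: float
    phase: str
    trial: int
    session: int

    def __post_init__(self) -> None:
        if self.phase not in PHASE_LABELS:
            raise FormatError(
                f"unknown phase label {self.phase!r}; expected one of {PHASE_LABELS}"
            )
        if self.duration_s < 0:
            raise FormatError("annotation duration must be non-negative")


@dataclass
class Recording:
    """Continuous multichannel EEG in microvolts with phase annotations.

    Attributes
    ----------
    samples
        Array of shape ``(n_channels, n_samples)``, units microvolts.
    fs
        Sampling rate in Hz.
    channel_names
        10-20 labels, one per row of ``samples``.
    annotations
        Phase intervals; onsets are seconds from recording start, sample
        index ranges are half-open ``[start, end)``.
    """

    samples: np.ndarray
    fs: float
    channel_names: Sequence[str]
    annotations: list[Annotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a (n_channels, n_samples) matrix")
        if self.samples.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{self.samples.shape[0]} sample rows but "
                f"{len(self.channel_names)} channel names"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")
        self.channel_names = list(self.channel_names)
        dur = self.duration_s
        for ann in self.annotations:
            if ann.onset_s < -1e-9 or ann.onset_s + ann.duration_s > dur + 1e-9:
                raise ValueError(
                    f"annotation at {ann.onset_s}s (+{ann.duration_s}s) lies outside "
                    f"the recording of {dur}s"
                )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.samples.shape[1] / self.fs

    def copy(self) -> "Recording":
        return Recording(
            self.samples.copy(), self.fs, list(self.channel_names),
            list(self.annotations),
        )


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    stem = path.name[: -len(path.suffix)] if path.suffix else path.name
    return path.parent / f"{stem}.annotations.csv"


def _write_csv(rec: Recording, path: Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(rec.channel_names)
        for row in rec.samples.T:
            writer.writerow([repr(float(v)) for v in row])
    with open(_sidecar_path(path), "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["onset_s", "duration_s", "phase", "trial", "session"])
        for a in rec.annotations:
            writer.writerow([repr(float(a.onset_s)), repr(float(a.duration_s)),
                             a.phase, a.trial, a.session])
    # fs travels in a tiny sidecar header so the CSV stays a plain matrix
    with open(path.parent / f"{path.name[: -len(path.suffix)] if path.suffix else path.name}.meta.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["fs_hz"])
        writer.writerow([repr(float(rec.fs))])


def _read_csv(path: Path, fs: float | None) -> Recording:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        names = [h.strip() for h in header]
        rows: list[list[float]] = []
        for i, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(names):
                raise FormatError(
                    f"{path}: line {i} has {len(row)} values but the header "
                    f"names {len(names)} channels"
                )
            try:
                rows.append([float(v) for v in row])
            except ValueError as exc:
                raise FormatError(f"{path}: line {i}: {exc}") from None
    stem = path.name[: -len(path.suffix)] if path.suffix else path.name
    meta = path.parent / f"{stem}.meta.csv"
    if fs is None:
        if not meta.exists():
            raise FormatError(
                f"{path}: sampling rate unknown (no {meta.name} sidecar and no "
                "fs argument)"
            )
        with open(meta, newline="") as fh:
            reader = csv.reader(fh)
            next(reader)
            fs = float(next(reader)[0])
    annotations: list[Annotation] = []
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        with open(sidecar, newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader)
            for i, row in enumerate(reader, start=2):
                if not row:
                    continue
                try:
                    annotations.append(Annotation(
                        float(row[0]), float(row[1]), row[2],
                        int(row[3]), int(row[4]),
                    ))
                except (IndexError, ValueError, FormatError) as exc:
                    raise FormatError(f"{sidecar}: record {i}: {exc}") from None
    data = np.array(rows, dtype=np.float64).T if rows else np.zeros((len(names), 0))
    return Recording(data, fs, names, annotations)


# ---------------------------------------------------------------------------
# EDF+ dialect
# ---------------------------------------------------------------------------

_EDF_DIGITAL_MIN, _EDF_DIGITAL_MAX = -32768, 32767


def _edf_field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _write_edf(rec: Recording, path: Path) -> None:
    """Emit an EDF+C file: 1-second records, int16 samples, annotation channel.

    Recordings are padded with zeros to a whole number of records; the
    synthetic protocol always produces whole-second recordings so the pad is
    normally empty.
    """
    fs = rec.fs
    spr = int(round(fs))
    if abs(fs - spr) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_records = int(np.ceil(rec.n_samples / spr)) if rec.n_samples else 1
    data = np.zeros((rec.n_channels, n_records * spr))
    data[:, : rec.n_samples] = rec.samples

    # physical scaling per channel, symmetric around zero
    phys_max = np.maximum(np.abs(data).max(axis=1), 1.0)
    digital = np.empty_like(data, dtype=np.int16)
    for c in range(rec.n_channels):
        scaled = data[c] / phys_max[c] * _EDF_DIGITAL_MAX
        digital[c] = np.clip(np.round(scaled), _EDF_DIGITAL_MIN,
                             _EDF_DIGITAL_MAX).astype(np.int16)

    # annotation TALs, all in the first record
    tals = bytearray()
    for a in rec.annotations:
        text = f"{a.phase}@trial={a.trial}@session={a.session}"
        tals += (f"+{a.onset_s:.6g}\x15{a.duration_s:.6g}\x14{text}\x14\x00"
                 .encode("utf-8"))
    ann_bytes_per_record = max(64, 2 * ((len(tals) + 32) // 2 + 16))
    ann_spr = ann_bytes_per_record // 2

    n_signals = rec.n_channels + 1
    header_bytes = 256 * (n_signals + 1)

    def records() -> bytes:
        out = bytearray()
        for r in range(n_records):
            for c in range(rec.n_channels):
                out += digital[c, r * spr:(r + 1) * spr].astype("<i2").tobytes()
            ann = bytearray(f"+{r}\x14\x14\x00".encode("ascii"))
            if r == 0:
                ann += tals
            ann += b"\x00" * (ann_bytes_per_record - len(ann))
            out += bytes(ann)
        return bytes(out)

    with open(path, "wb") as fh:
        fh.write(_edf_field("0", 8))
        fh.write(_edf_field("X X X X", 80))                  # patient id
        fh.write(_edf_field("Startdate 01-JAN-2000 X X X", 80))
        fh.write(_edf_field("01.01.00", 8))
        fh.write(_edf_field("00.00.00", 8))
        fh.write(_edf_field(str(header_bytes), 8))
        fh.write(_edf_field("EDF+C", 44))
        fh.write(_edf_field(str(n_records), 8))
        fh.write(_edf_field("1", 8))                         # record duration s
        fh.write(_edf_field(str(n_signals), 4))
        labels = list(rec.channel_names) + ["EDF Annotations"]
        for lab in labels:
            fh.write(_edf_field(lab, 16))
        for _ in labels:
            fh.write(_edf_field("", 80))                     # transducer
        for i in range(n_signals):
            fh.write(_edf_field("uV" if i < rec.n_channels else "", 8))
        for i in range(n_signals):
            pm = -phys_max[i] if i < rec.n_channels else -1
            fh.write(_edf_field(f"{pm:.6g}"[:8], 8))
        for i in range(n_signals):
            pm = phys_max[i] if i < rec.n_channels else 1
            fh.write(_edf_field(f"{pm:.6g}"[:8], 8))
        for _ in range(n_signals):
            fh.write(_edf_field(str(_EDF_DIGITAL_MIN), 8))
        for _ in range(n_signals):
            fh.write(_edf_field(str(_EDF_DIGITAL_MAX), 8))
        for _ in range(n_signals):
            fh.write(_edf_field("", 80))                     # prefiltering
        for i in range(n_signals):
            fh.write(_edf_field(str(spr if i < rec.n_channels else ann_spr), 8))
        for _ in range(n_signals):
            fh.write(_edf_field("", 32))                     # reserved
        fh.write(records())


def _read_edf(path: Path) -> Recording:
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    picks = [i for i, name in enumerate(raw.ch_names)]
    data = raw.get_data() * 1e6  # mne returns volts
    fs = float(raw.info["sfreq"])
    annotations: list[Annotation] = []
    for onset, duration, desc in zip(raw.annotations.onset,
                                     raw.annotations.duration,
                                     raw.annotations.description):
        parts = desc.split("@")
        phase = parts[0]
        if phase not in PHASE_LABELS:
            continue  # timestamp/bookkeeping annotations
        trial = session = 0
        for p in parts[1:]:
            key, _, val = p.partition("=")
            if key == "trial":
                trial = int(val)
            elif key == "session":
                session = int(val)
        annotations.append(Annotation(float(onset), float(duration), phase,
                                      trial, session))
    return Recording(data, fs, list(raw.ch_names), annotations)


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def write_recording(recording: Recording, path: str | Path,
                    format: str | None = None) -> None:
    """Write a recording as CSV (+sidecars) or EDF+."""
    path = Path(path)
    fmt = format or ("edf" if path.suffix.lower() == ".edf" else "csv")
    if fmt == "csv":
        _write_csv(recording, path)
    elif fmt == "edf":
        _write_edf(recording, path)
    else:
        raise ValueError(f"unknown format {fmt!r}; expected 'csv' or 'edf'")


def read_recording(path: str | Path, format: str | None = None,
                   fs: float | None = None) -> Recording:
    """Read a recording written by :func:`write_recording`.

    ``fs`` overrides the sidecar sampling rate for bare CSV matrices.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("edf" if path.suffix.lower() == ".edf" else "csv")
    if fmt == "csv":
        return _read_csv(path, fs)
    if fmt == "edf":
        return _read_edf(path)
    raise ValueError(f"unknown format {fmt!r}; expected 'csv' or 'edf'")


def select_channels(recording: Recording, names: Sequence[str]) -> Recording:
    """Restrict a recording to the named channels, in the requested order."""
    index = {n: i for i, n in enumerate(recording.channel_names)}
    missing = [n for n in names if n not in index]
    if missing:
        raise KeyError(
            f"unknown channel(s) {missing}; available: {list(recording.channel_names)}"
        )
    rows = [index[n] for n in names]
    return Recording(recording.samples[rows].copy(), recording.fs,
                     list(names), list(recording.annotations))


_EPOCHS_VERSION = 1


def save_epochs(epochs, path: str | Path) -> None:
    """Persist an :class:`~miglove.preprocessing.EpochSet` losslessly (.npz)."""
    path = Path(path)
    prov = epochs.provenance
    np.savez(
        path,
        version=np.array([_EPOCHS_VERSION]),
        windows=epochs.windows,
        labels=np.array(epochs.labels, dtype="U16"),
        fs=np.array([epochs.fs]),
        trial=np.array([p["trial"] for p in prov], dtype=np.int64),
        session=np.array([p["session"] for p in prov], dtype=np.int64),
        phase=np.array([p["phase"] for p in prov], dtype="U24"),
        onset_s=np.array([p["onset_s"] for p in prov], dtype=np.float64),
        channel_names=np.array(epochs.channel_names, dtype="U16"),
    )


def load_epochs(path: str | Path):
    """Load an epoch set written by :func:`save_epochs`."""
    from .preprocessing import EpochSet

    path = Path(path)
    try:
        with np.load(path, allow_pickle=False) as z:
            version = int(z["version"][0])
            if version != _EPOCHS_VERSION:
                raise FormatError(
                    f"{path}: epoch archive version {version}, expected "
                    f"{_EPOCHS_VERSION}"
                )
            prov = [
                {"trial": int(t), "session": int(s), "phase": str(p),
                 "onset_s": float(o)}
                for t, s, p, o in zip(z["trial"], z["session"], z["phase"],
                                      z["onset_s"])
            ]
            return EpochSet(
                windows=z["windows"],
                labels=[str(x) for x in z["labels"]],
                fs=float(z["fs"][0]),
                provenance=prov,
                channel_names=[str(c) for c in z["channel_names"]],
            )
    except (OSError, KeyError, ValueError) as exc:
        if isinstance(exc, FormatError):
            raise
        raise FormatError(f"{path}: not a readable epoch archive ({exc})") from exc
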