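"""Protocol-faithful synthetic motor-imagery EEG.

Real sensorimotor EEG during imagined movement shows event-related
desynchronization (ERD): the mu (~10 Hz) and beta (~20 Hz) rhythms over
motor cortex drop in amplitude while the subject imagines the movement.
The generator emulates exactly that contrast on top of a 1/f-amplitude
background:

* every channel carries 1/f (pink-ish) noise plus band-limited alpha and
  beta oscillators with random phase and slow amplitude jitter;
* during motor-imagery phases the oscillator amplitudes on a configurable
  sensorimotor channel set are multiplied by ``1 - effect_size``;
* during rest phases the alpha amplitude may be boosted by
  ``rest_alpha_gain`` (default 1, i.e. off).

With ``effect_size = 0`` (and unit rest gain) the two conditions are drawn
from the same distribution, giving an exact null for calibration tests.
The session/trial/phase layout follows a three-phase rehabilitation
protocol: motor execution, motor imagery and rest, 16 s each, six trials
per session, three sessions (18 trials, 864 s of task data per subject).
Identical (profile, protocol, seed) inputs produce bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import DEFAULT_MONTAGE, Annotation, Recording
from .preprocessing import EpochSet

__all__ = [
    "SubjectProfile",
    "ProtocolSpec",
    "DEFAULT_FS",
    "SENSORIMOTOR_CHANNELS",
    "generate_recording",
    "generate_epoch_batch",
    "inject_artifacts",
]

#: OpenBCI Cyton+Daisy 16-channel sampling rate.
DEFAULT_FS = 125.0

#: Channels carrying the ERD contrast by default (frontal-central).
SENSORIMOTOR_CHANNELS = ("C3", "C4", "F3", "F4")

_ALPHA_FREQ = 10.0   # Hz, mu/alpha oscillator
_BETA_FREQ = 20.0    # Hz, beta oscillator
_ALPHA_AMP = 6.0     # uV baseline oscillator amplitude
_BETA_AMP = 3.0      # uV


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject generative parameters.

    effect_size
        Fractional mu/beta amplitude suppression on sensorimotor channels
        during motor imagery (0 = no ERD, 1 = full suppression).
    noise_scale
        Amplitude of the 1/f background, microvolts.
    rest_alpha_gain
        Multiplicative alpha boost during rest (>= 1; 1 disables it).
    """

    effect_size: float = 0.5
    noise_scale: float = 5.0
    rest_alpha_gain: float = 1.0
    seed: int = 0
    sensorimotor_channels: tuple[str, ...] = SENSORIMOTOR_CHANNELS

    def __post_init__(self) -> None:
        for name in ("effect_size", "noise_scale", "rest_alpha_gain"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        if self.rest_alpha_gain < 1:
            raise ValueError("rest_alpha_gain must be >= 1")


@dataclass(frozen=True)
class ProtocolSpec:
    """Trial/session layout of the three-phase rehabilitation protocol."""

    phase_order: tuple[str, ...] = ("motor_execution", "motor_imagery", "rest")
    phase_duration_s: float = 16.0
    n_trials_per_session: int = 6
    n_sessions: int = 3
    randomize_order: bool = False

    def __post_init__(self) -> None:
        if self.phase_duration_s <= 0:
            raise ValueError("phase_duration_s must be positive")
        if self.n_trials_per_session < 1 or self.n_sessions < 1:
            raise ValueError("need >= 1 trial per session and >= 1 session")

    @property
    def total_duration_s(self) -> float:
        return (len(self.phase_order) * self.phase_duration_s
                * self.n_trials_per_session * self.n_sessions)


def _pink_noise(rng: np.random.Generator, n: int, fs: float,
                scale: float) -> np.ndarray:
    """1/f-amplitude Gaussian noise of length n (flat below 1 Hz)."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.ones_like(freqs)
    nz = freqs >= 1.0
    shaping[nz] = 1.0 / freqs[nz]
    spectrum = (rng.standard_normal(len(freqs))
                + 1j * rng.standard_normal(len(freqs))) * shaping
    x = np.fft.irfft(spectrum, n=n)
    sd = x.std()
    return x / sd * scale if sd > 0 else x


def _oscillator(rng: np.random.Generator, n: int, fs: float, freq: float,
                amp: float) -> np.ndarray:
    """Band-limited rhythm: sinusoid with random phase and slow AM jitter."""
    t = np.arange(n) / fs
    phase = rng.uniform(0, 2 * np.pi)
    # slow lognormal amplitude envelope (~1 Hz smoothness)
    env_pts = max(2, int(np.ceil(n / fs)) + 1)
    env = np.exp(rng.normal(0.0, 0.25, size=env_pts))
    envelope = np.interp(t, np.linspace(0, t[-1] if n > 1 else 1.0, env_pts),
                         env)
    return amp * envelope * np.sin(2 * np.pi * freq * t + phase)


def _phase_segment(rng: np.random.Generator, n: int, fs: float,
                   profile: SubjectProfile, phase: str,
                   montage: Sequence[str]) -> np.ndarray:
    seg = np.empty((len(montage), n))
    sm = set(profile.sensorimotor_channels)
    for c, name in enumerate(montage):
        alpha_amp, beta_amp = _ALPHA_AMP, _BETA_AMP
        if phase in ("motor_imagery", "motor_execution") and name in sm:
            alpha_amp *= 1.0 - min(profile.effect_size, 1.0)
            beta_amp *= 1.0 - min(profile.effect_size, 1.0)
        if phase == "rest":
            alpha_amp *= profile.rest_alpha_gain
        seg[c] = (
            _pink_noise(rng, n, fs, profile.noise_scale)
            + _oscillator(rng, n, fs, _ALPHA_FREQ, alpha_amp)
            + _oscillator(rng, n, fs, _BETA_FREQ, beta_amp)
        )
    return seg


def generate_recording(profile: SubjectProfile,
                       protocol: ProtocolSpec | None = None,
                       fs: float = DEFAULT_FS,
                       montage: Sequence[str] = DEFAULT_MONTAGE) -> Recording:
    """Generate one subject's continuous annotated recording.

    Every sample belongs to exactly one phase annotation; phases are laid
    out back-to-back per trial, trials per session, sessions consecutively.
    """
    protocol = protocol or ProtocolSpec()
    if fs < 100:
        raise ValueError("fs must be >= 100 Hz to cover the 45 Hz band")
    if len(montage) != 16:
        raise ValueError(f"montage must have 16 channels, got {len(montage)}")
    rng = np.random.default_rng(profile.seed)
    n_phase = int(round(protocol.phase_duration_s * fs))
    # annotated duration follows the realized sample count, so coverage
    # stays exact even when phase_duration_s * fs is not an integer
    phase_dur = n_phase / fs
    segments: list[np.ndarray] = []
    annotations: list[Annotation] = []
    onset = 0.0
    for session in range(protocol.n_sessions):
        for trial in range(protocol.n_trials_per_session):
            order = list(protocol.phase_order)
            if protocol.randomize_order:
                order = [order[i] for i in rng.permutation(len(order))]
            for phase in order:
                segments.append(_phase_segment(rng, n_phase, fs, profile,
                                               phase, montage))
                annotations.append(Annotation(onset, phase_dur,
                                              phase, trial, session))
                onset += phase_dur
    samples = np.concatenate(segments, axis=1)
    return Recording(samples, fs, list(montage), annotations)


def generate_epoch_batch(profile: SubjectProfile, n_per_class: int,
                         fs: float = DEFAULT_FS, seed: int | None = None,
                         montage: Sequence[str] = DEFAULT_MONTAGE,
                         n_pseudo_trials: int = 10) -> EpochSet:
    """Balanced 1 s labeled epochs, bypassing the continuous protocol.

    A shortcut for unit tests and quick end-to-end runs: ``n_per_class``
    epochs each of "fist" (motor-imagery statistics) and "rest".  Epochs are
    assigned round-robin to ``n_pseudo_trials`` pseudo-trials per class so
    the group-level train/test split remains applicable.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(profile.seed if seed is None else seed)
    n = int(round(fs))
    windows, labels, prov = [], [], []
    for cls, phase in (("fist", "motor_imagery"), ("rest", "rest")):
        for i in range(n_per_class):
            windows.append(_phase_segment(rng, n, fs, profile, phase,
                                          montage))
            labels.append(cls)
            trial = i % n_pseudo_trials + (0 if cls == "fist"
                                           else n_pseudo_trials)
            prov.append({"trial": trial, "session": 0, "phase": phase,
                         "onset_s": 0.0})
    return EpochSet(np.stack(windows), labels, fs, prov, list(montage))


def inject_artifacts(recording: Recording, line_freq: float = 60.0,
                     amplitude: float = 50.0) -> Recording:
    """Add mains-style sinusoidal interference at ``line_freq`` to all
    channels; the input recording is left unmodified."""
    if not (0 < line_freq < recording.fs / 2):
        raise ValueError(
            f"line_freq {line_freq} Hz would alias at fs={recording.fs} Hz "
            f"(Nyquist {recording.fs / 2} Hz)"
        )
    t = np.arange(recording.n_samples) / recording.fs
    interference = amplitude * np.sin(2 * np.pi * line_freq * t)
    return Recording(recording.samples + interference[None, :], recording.fs,
                     list(recording.channel_names), list(recording.annotations))
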