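"""Filtering, cropping, epoching arithmetic, leakage-safe splitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal as sps

from miglove import preprocessing, synthetic
from miglove.io import DEFAULT_MONTAGE, Recording
from miglove.preprocessing import (FilterSpec, apply_filters, crop_phases,
                                   make_epochs, n_epochs_in_interval,
                                   split_by_group)
from miglove.synthetic import ProtocolSpec, SubjectProfile

FS = 125.0


def tone_recording(freq, seconds=20, amplitude=1.0):
    t = np.arange(int(seconds * FS)) / FS
    wave = amplitude * np.sin(2 * np.pi * freq * t)
    return Recording(np.tile(wave, (16, 1)), FS, DEFAULT_MONTAGE)


def power_at(x, freq):
    f, p = sps.periodogram(x, fs=FS)
    return p[np.argmin(np.abs(f - freq))]


class TestApplyFilters:
    def test_60hz_interference_suppressed_below_one_percent(self):
        rec = synthetic.generate_recording(
            SubjectProfile(seed=0), ProtocolSpec(n_trials_per_session=1,
                                                 n_sessions=1))
        noisy = synthetic.inject_artifacts(rec, 60.0, 50.0)
        out = apply_filters(noisy)
        assert (power_at(out.samples[0], 60.0)
                <= 0.01 * power_at(noisy.samples[0], 60.0))

    def test_10hz_passband_amplitude_preserved_within_5_percent(self):
        rec = tone_recording(10.0)
        out = apply_filters(rec)
        mid = slice(500, 2000)  # away from filtfilt edges
        ratio = out.samples[0][mid].std() / rec.samples[0][mid].std()
        assert abs(ratio - 1.0) < 0.05

    def test_dc_removed_by_highpass(self):
        rec = Recording(np.full((16, 2000), 10.0), FS, DEFAULT_MONTAGE)
        out = apply_filters(rec)
        assert np.abs(out.samples).max() < 0.1

    def test_10hz_injected_line_passes_notch_nearly_unattenuated(self):
        """A 'mains' tone at 10 Hz sits in the passband: < 5% loss."""
        rec = tone_recording(0.0, amplitude=0.0)
        noisy = synthetic.inject_artifacts(rec, 10.0, 50.0)
        out = apply_filters(noisy)
        mid = slice(500, 2000)
        ratio = out.samples[0][mid].std() / noisy.samples[0][mid].std()
        assert ratio > 0.95

    def test_stopband_idempotence(self):
        noisy = synthetic.inject_artifacts(tone_recording(0, amplitude=0),
                                           60.0, 50.0)
        once = apply_filters(noisy)
        twice = apply_filters(once)
        p_in = power_at(noisy.samples[0], 60.0)
        delta = abs(power_at(twice.samples[0], 60.0)
                    - power_at(once.samples[0], 60.0))
        assert delta < 0.01 * p_in

    def test_band_above_nyquist_rejected(self):
        rec = tone_recording(10.0)
        with pytest.raises(ValueError):
            apply_filters(rec, FilterSpec(band_high=70.0))

    def test_annotations_and_shape_preserved(self):
        rec = synthetic.generate_recording(
            SubjectProfile(seed=0), ProtocolSpec(n_trials_per_session=1,
                                                 n_sessions=1))
        out = apply_filters(rec)
        assert out.samples.shape == rec.samples.shape
        assert out.annotations == rec.annotations


class TestCropPhases:
    def test_16s_phase_trimmed_to_10s_eligible(self):
        rec = synthetic.generate_recording(
            SubjectProfile(seed=0), ProtocolSpec(n_trials_per_session=1,
                                                 n_sessions=1))
        out = crop_phases(rec, 3.0)
        for a, orig in zip(out.annotations, rec.annotations):
            assert a.duration_s == pytest.approx(10.0)
            assert a.onset_s == pytest.approx(orig.onset_s + 3.0)

    def test_zero_trim_is_identity(self):
        rec = synthetic.generate_recording(
            SubjectProfile(seed=0), ProtocolSpec(n_trials_per_session=1,
                                                 n_sessions=1))
        assert crop_phases(rec, 0.0).annotations == rec.annotations

    def test_phase_too_short_names_the_trial(self):
        rec = synthetic.generate_recording(
            SubjectProfile(seed=0),
            ProtocolSpec(phase_duration_s=5.0, n_trials_per_session=1,
                         n_sessions=1))
        with pytest.raises(ValueError, match="trial 0"):
            crop_phases(rec, 3.0)


class TestMakeEpochs:
    def test_exact_fit_yields_single_epoch(self):
        rec = synthetic.generate_recording(
            SubjectProfile(seed=0),
            ProtocolSpec(phase_duration_s=1.0, n_trials_per_session=1,
                         n_sessions=1))
        eps = make_epochs(rec, length_s=1.0, overlap_s=0.75)
        # one eligible 1 s interval per included phase (MI + rest)
        assert len(eps) == 2

    def test_10s_interval_yields_37_epochs(self):
        assert n_epochs_in_interval(10.0, 1.0, 0.25, FS) == 37
        rec = synthetic.generate_recording(
            SubjectProfile(seed=0), ProtocolSpec(n_trials_per_session=1,
                                                 n_sessions=1))
        eps = make_epochs(crop_phases(rec, 3.0))
        assert eps.class_counts() == {"fist": 37, "rest": 37}

    def test_default_protocol_yields_666_epochs_per_class(self):
        rec = synthetic.generate_recording(SubjectProfile(seed=0))
        eps = make_epochs(crop_phases(rec, 3.0))
        assert eps.class_counts() == {"fist": 666, "rest": 666}

    def test_no_epoch_crosses_a_phase_boundary(self):
        rec = synthetic.generate_recording(
            SubjectProfile(seed=0), ProtocolSpec(n_trials_per_session=2,
                                                 n_sessions=1))
        cropped = crop_phases(rec, 3.0)
        eps = make_epochs(cropped)
        intervals = {(a.phase, a.trial, a.session):
                     (a.onset_s, a.onset_s + a.duration_s)
                     for a in cropped.annotations}
        for i, p in enumerate(eps.provenance):
            lo, hi = intervals[(p["phase"], p["trial"], p["session"])]
            assert p["onset_s"] >= lo - 1e-9
            assert p["onset_s"] + 1.0 <= hi + 1e-9

    def test_interval_shorter_than_window_yields_zero_epochs(self):
        rec = synthetic.generate_recording(
            SubjectProfile(seed=0),
            ProtocolSpec(phase_duration_s=0.5, n_trials_per_session=1,
                         n_sessions=1))
        assert len(make_epochs(rec)) == 0

    def test_invalid_overlap_rejected(self):
        rec = synthetic.generate_recording(
            SubjectProfile(seed=0), ProtocolSpec(n_trials_per_session=1,
                                                 n_sessions=1))
        with pytest.raises(ValueError):
            make_epochs(rec, length_s=1.0, overlap_s=1.0)

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(
        t=st.integers(min_value=1, max_value=400),       # duration, samples
        ln=st.integers(min_value=1, max_value=200),      # window, samples
        hop=st.integers(min_value=1, max_value=100),     # hop, samples
    )
    def test_closed_form_matches_brute_force_enumeration(self, t, ln, hop):
        starts = [s for s in range(0, t + 1) if s + ln <= t and s % hop == 0]
        brute = len([s for s in range(0, t - ln + 1, hop)])
        closed = n_epochs_in_interval(t / FS, ln / FS, hop / FS, FS)
        assert closed == brute == len(starts)


class TestSplitByGroup:
    def test_18_trials_at_22_percent_gives_4_test_trials(self):
        rec = synthetic.generate_recording(SubjectProfile(seed=0))
        eps = make_epochs(crop_phases(rec, 3.0))
        train, test = split_by_group(eps, "trial", 0.22, seed=0)
        test_groups = {(p["session"], p["trial"]) for p in test.provenance}
        train_groups = {(p["session"], p["trial"]) for p in train.provenance}
        assert len(test_groups) == 4
        assert len(train_groups) == 14
        assert not test_groups & train_groups

    def test_same_seed_identical_partition(self, strong_batch):
        a = split_by_group(strong_batch, "trial", 0.25, seed=5)
        b = split_by_group(strong_batch, "trial", 0.25, seed=5)
        assert a[0].labels == b[0].labels
        assert np.array_equal(a[1].windows, b[1].windows)

    def test_both_classes_present_in_both_partitions(self, strong_batch):
        train, test = split_by_group(strong_batch, "trial", 0.25, seed=1)
        assert set(train.labels) == set(test.labels) == {"fist", "rest"}

    def test_single_group_rejected(self):
        rec = synthetic.generate_recording(
            SubjectProfile(seed=0), ProtocolSpec(n_trials_per_session=1,
                                                 n_sessions=1))
        eps = make_epochs(crop_phases(rec, 3.0))
        with pytest.raises(ValueError, match="groups"):
            split_by_group(eps, "trial", 0.25, seed=0)
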