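"""Filtering, windowing, relabelling and the chronological split."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import emgtremor as et
from emgtremor.preprocess import (
    FilterSpec, SCHEMES, TASK5, TASK6, TREMOR3, relabel, segment,
)
from emgtremor.synth import EMGRecording


def _recording(samples, task="1a", tremor="resting", fs=200.0):
    return EMGRecording("s1", task, tremor, fs, samples)


def _sinusoid_recording(freq, n=4000, fs=200.0):
    t = np.arange(n) / fs
    return _recording(np.tile(np.sin(2 * np.pi * freq * t), (8, 1)))


def test_filter_dc_gain_unity():
    rec = _recording(np.full((8, 1000), 3.7))
    out = et.lowpass_filter(rec, FilterSpec())
    np.testing.assert_allclose(out.samples, rec.samples, rtol=1e-6)


def test_filter_cutoff_attenuation():
    """Zero-phase pass squares the magnitude: 0.5 at the 20 Hz cutoff."""
    out = et.lowpass_filter(_sinusoid_recording(20.0), FilterSpec())
    mid = out.samples[0, 1000:3000]  # steady state away from edges
    ratio = np.sqrt(2) * np.std(mid)  # amplitude via RMS, exact on whole cycles
    assert abs(ratio - 0.5) <= 0.02


def test_filter_stopband_attenuation():
    """At 40 Hz the analytic two-pass magnitude is 1/257; allow margin."""
    out = et.lowpass_filter(_sinusoid_recording(40.0), FilterSpec())
    assert np.abs(out.samples[0, 1000:3000]).max() <= 0.01


@settings(deadline=None, derandomize=True)
@given(st.floats(min_value=-100, max_value=100).filter(lambda a: abs(a) > 1e-6))
def test_filter_linearity(a):
    rng = np.random.default_rng(0)
    x = rng.standard_normal((8, 500))
    fx = et.lowpass_filter(_recording(x)).samples
    fax = et.lowpass_filter(_recording(a * x)).samples
    np.testing.assert_allclose(fax, a * fx, rtol=1e-9, atol=1e-12 * abs(a))


def test_filter_forward_mode_is_causal_variant():
    rec = _sinusoid_recording(5.0)
    zp = et.lowpass_filter(rec, FilterSpec(mode="zero_phase")).samples
    fw = et.lowpass_filter(rec, FilterSpec(mode="forward")).samples
    assert not np.allclose(zp, fw)  # forward pass has group delay


def test_filter_argument_errors():
    with pytest.raises(ValueError, match="Nyquist"):
        FilterSpec(cutoff_hz=100.0, fs_hz=200.0)
    short = _recording(np.zeros((8, 10)))
    with pytest.raises(ValueError, match="samples"):
        et.lowpass_filter(short, FilterSpec())


@pytest.mark.parametrize(
    "n_samples, expected",
    [(12000, 479), (50, 1), (75, 2), (100, 3)],
)
def test_segment_window_count(n_samples, expected):
    rec = _recording(np.random.default_rng(0).standard_normal((8, n_samples)))
    ds = segment(rec)
    assert len(ds) == expected
    assert ds.window_len == 50


def test_segment_too_short_names_recording():
    rec = _recording(np.zeros((8, 49)))
    with pytest.raises(ValueError, match="s1/task1a"):
        segment(rec)


def test_segment_content_conservation():
    """Concatenating the non-overlapping even windows rebuilds the signal."""
    rng = np.random.default_rng(1)
    x = rng.standard_normal((8, 12000))
    ds = segment(_recording(x))
    rebuilt = np.concatenate([ds.windows[i] for i in range(0, len(ds), 2)]).T
    np.testing.assert_array_equal(rebuilt, x[:, : rebuilt.shape[1]])


def test_segment_labels_and_order(subject_windows):
    ds = subject_windows
    assert set(ds.task_labels) == {"1a", "1b", "2", "3", "4", "5"}
    for rec_id in set(ds.recording_ids):
        idx = ds.chrono_index[ds.recording_ids == rec_id]
        assert (np.diff(idx) == 1).all()


def test_relabel_task5_merges_three_and_four():
    labels = np.array(["1a", "1b", "2", "3", "4", "5"], dtype=object)
    assert [TASK5.mapping[l] for l in labels] == ["1a", "1b", "2", "3or4", "3or4", "5"]


def test_relabel_applies_mapping(subject_windows):
    out = relabel(subject_windows, TASK5)
    assert out.classes == ("1a", "1b", "2", "3or4", "5")
    merged = np.isin(subject_windows.task_labels.astype(str), ["3", "4"])
    assert (out.labels[merged] == "3or4").all()
    assert (out.labels[~merged] == subject_windows.task_labels[~merged]).all()
    # window content untouched
    np.testing.assert_array_equal(out.windows, subject_windows.windows)


def test_relabel_idempotent(subject_windows):
    once = relabel(subject_windows, TASK5)
    twice = relabel(once, TASK5)
    np.testing.assert_array_equal(once.labels, twice.labels)
    tri_once = relabel(subject_windows, TREMOR3)
    tri_twice = relabel(tri_once, TREMOR3)
    np.testing.assert_array_equal(tri_once.labels, tri_twice.labels)


def test_relabel_tremor_class_counts():
    tasks = ["1a", "1b", "2", "3", "4", "5"]
    mapped = [TREMOR3.mapping[t] for t in tasks]
    assert mapped.count("resting") == 2
    assert mapped.count("postural") == 1
    assert mapped.count("action") == 3


def test_relabel_unknown_label_error(subject_windows):
    ds = subject_windows.subset(np.arange(4))
    ds.labels = np.array(["1a", "xx", "2", "3"], dtype=object)
    with pytest.raises(KeyError, match="xx"):
        relabel(ds, TASK5)


def test_chrono_split_counts(subject_windows):
    rec = _recording(np.random.default_rng(0).standard_normal((8, 12000)))
    ds = segment(rec)
    train, test = et.chrono_split(ds)
    assert (len(train), len(test)) == (383, 96)
    small = ds.subset(np.arange(10))
    tr, te = et.chrono_split(small)
    assert (len(tr), len(te)) == (8, 2)


def test_chrono_split_ordering_and_partition(subject_windows):
    train, test = et.chrono_split(subject_windows)
    assert len(train) + len(test) == len(subject_windows)
    for rec_id in set(subject_windows.recording_ids):
        tr_idx = train.chrono_index[train.recording_ids == rec_id]
        te_idx = test.chrono_index[test.recording_ids == rec_id]
        assert tr_idx.max() < te_idx.min()
    # both partitions see every class
    assert set(train.labels) == set(test.labels) == set(subject_windows.labels)


def test_chrono_split_errors(subject_windows):
    one = subject_windows.subset(np.arange(1))
    with pytest.raises(ValueError, match="at least 2"):
        et.chrono_split(one)
    with pytest.raises(ValueError, match="train_frac"):
        et.chrono_split(subject_windows, train_frac=1.0)


def test_windowed_dataset_round_trip(tmp_path, subject_windows):
    path = tmp_path / "ds"
    subject_windows.save(path)
    loaded = subject_windows.load(path)
    np.testing.assert_array_equal(loaded.windows, subject_windows.windows)
    assert list(loaded.labels) == list(subject_windows.labels)
    assert loaded.classes == subject_windows.classes
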