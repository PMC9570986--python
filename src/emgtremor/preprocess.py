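"""Filtering, windowing, label schemes and the chronological split.

Raw 8-channel recordings are low-pass filtered (4th-order Butterworth,
20 Hz cut-off by default — the useful content of forearm sEMG during slow
hand tasks sits well below the 100 Hz Nyquist limit of a 200 Hz armband),
cut into 250 ms windows with 50 % overlap, and split chronologically into
train (first 80 %) and test (final 20 %) partitions per recording, since
the data are a time series and models must be tested on the future.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sps

from emgtremor.synth import EMGRecording, N_CHANNELS, TASKS, TASK_TO_TREMOR


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth low-pass filter settings.

    ``zero_phase`` applies the filter forward and backward (squared
    magnitude response, no lag) and is the default for offline analysis;
    ``forward`` is a causal single pass for streaming use.
    """

    order: int = 4
    cutoff_hz: float = 20.0
    fs_hz: float = 200.0
    mode: str = "zero_phase"

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("filter order must be a positive integer")
        if not 0 < self.cutoff_hz < self.fs_hz / 2:
            raise ValueError(
                f"cutoff_hz must lie in (0, Nyquist={self.fs_hz / 2} Hz), "
                f"got {self.cutoff_hz}"
            )
        if self.mode not in ("zero_phase", "forward"):
            raise ValueError(f"unknown filter mode {self.mode!r}")


def lowpass_filter(recording: EMGRecording, spec: FilterSpec = FilterSpec()) -> EMGRecording:
    """Low-pass filter every channel of a recording.

    Raises a length error if the recording is too short for the filter's
    padding requirement (3 x (order + 1) samples in zero-phase mode).
    """
    b, a = sps.butter(spec.order, spec.cutoff_hz, btype="low", fs=spec.fs_hz)
    padlen = 3 * max(len(a), len(b))
    if recording.n_samples <= padlen:
        raise ValueError(
            f"recording has {recording.n_samples} samples; zero-phase filtering "
            f"of a {spec.order}th-order filter needs more than {padlen}"
        )
    if spec.mode == "zero_phase":
        filtered = sps.filtfilt(b, a, recording.samples, axis=1)
    else:
        filtered = sps.lfilter(b, a, recording.samples, axis=1)
    return replace(recording, samples=filtered)


@dataclass
class WindowedDataset:
    """Segmented, labelled fixed-length windows ready for training.

    ``windows`` has shape ``(n, l, 8)``: ``n`` windows of ``l`` samples by
    8 channels — each window is the input matrix S = (S1, ..., S8) of the
    classifier.  ``labels`` is the active classification target (initially
    the task labels); ``task_labels`` and ``tremor_labels`` keep the
    ground truth.  ``chrono_index`` is the window's time-order index
    within its source recording.
    """

    windows: np.ndarray
    labels: np.ndarray
    task_labels: np.ndarray
    tremor_labels: np.ndarray
    classes: Tuple[str, ...]
    recording_ids: np.ndarray
    chrono_index: np.ndarray
    window_ms: float = 250.0
    overlap_frac: float = 0.5
    fs_hz: float = 200.0

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=float)
        if self.windows.ndim != 3 or self.windows.shape[2] != N_CHANNELS:
            raise ValueError(f"windows must be (n, l, 8), got {self.windows.shape}")
        n = self.windows.shape[0]
        for name in ("labels", "task_labels", "tremor_labels", "recording_ids", "chrono_index"):
            arr = np.asarray(getattr(self, name))
            if arr.shape[0] != n:
                raise ValueError(f"{name} length {arr.shape[0]} != number of windows {n}")
            setattr(self, name, arr)

    def __len__(self) -> int:
        return self.windows.shape[0]

    @property
    def window_len(self) -> int:
        return self.windows.shape[1]

    def subset(self, idx: np.ndarray) -> "WindowedDataset":
        return WindowedDataset(
            windows=self.windows[idx],
            labels=self.labels[idx],
            task_labels=self.task_labels[idx],
            tremor_labels=self.tremor_labels[idx],
            classes=self.classes,
            recording_ids=self.recording_ids[idx],
            chrono_index=self.chrono_index[idx],
            window_ms=self.window_ms,
            overlap_frac=self.overlap_frac,
            fs_hz=self.fs_hz,
        )

    @staticmethod
    def concatenate(parts: Sequence["WindowedDataset"]) -> "WindowedDataset":
        if not parts:
            raise ValueError("nothing to concatenate")
        first = parts[0]
        return WindowedDataset(
            windows=np.concatenate([p.windows for p in parts]),
            labels=np.concatenate([p.labels for p in parts]),
            task_labels=np.concatenate([p.task_labels for p in parts]),
            tremor_labels=np.concatenate([p.tremor_labels for p in parts]),
            classes=first.classes,
            recording_ids=np.concatenate([p.recording_ids for p in parts]),
            chrono_index=np.concatenate([p.chrono_index for p in parts]),
            window_ms=first.window_ms,
            overlap_frac=first.overlap_frac,
            fs_hz=first.fs_hz,
        )

    def save(self, path: Path) -> None:
        """Persist as a binary array container plus a JSON sidecar."""
        path = Path(path)
        np.savez(
            path.with_suffix(".npz"),
            windows=self.windows,
            labels=self.labels.astype(str),
            task_labels=self.task_labels.astype(str),
            tremor_labels=self.tremor_labels.astype(str),
            recording_ids=self.recording_ids.astype(str),
            chrono_index=self.chrono_index.astype(int),
        )
        sidecar = {
            "classes": list(self.classes),
            "window_ms": self.window_ms,
            "overlap_frac": self.overlap_frac,
            "fs_hz": self.fs_hz,
            "n_windows": len(self),
            "window_len": self.window_len,
        }
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump(sidecar, fh, indent=2)

    @staticmethod
    def load(path: Path) -> "WindowedDataset":
        path = Path(path)
        with np.load(path.with_suffix(".npz")) as arc:
            arrays = {k: arc[k] for k in arc.files}
        with open(path.with_suffix(".json")) as fh:
            sidecar = json.load(fh)
        return WindowedDataset(
            windows=arrays["windows"],
            labels=arrays["labels"],
            task_labels=arrays["task_labels"],
            tremor_labels=arrays["tremor_labels"],
            classes=tuple(sidecar["classes"]),
            recording_ids=arrays["recording_ids"],
            chrono_index=arrays["chrono_index"],
            window_ms=sidecar["window_ms"],
            overlap_frac=sidecar["overlap_frac"],
            fs_hz=sidecar["fs_hz"],
        )


def segment(
    recording: EMGRecording,
    window_ms: float = 250.0,
    overlap_frac: float = 0.5,
) -> WindowedDataset:
    """Cut a recording into fixed-length overlapped windows.

    Window length l = round(window_ms / 1000 * fs) samples (50 at
    defaults), hop = l * (1 - overlap).  The number of windows is
    floor((N - l) / hop) + 1; a trailing partial window is discarded.
    Every window inherits the recording's task and tremor labels.
    """
    if not 0 <= overlap_frac < 1:
        raise ValueError("overlap_frac must lie in [0, 1)")
    l = int(round(window_ms / 1000.0 * recording.fs_hz))
    hop = int(round(l * (1.0 - overlap_frac)))
    if hop < 1:
        raise ValueError("overlap too large: hop must be at least one sample")
    n_samples = recording.n_samples
    if n_samples < l:
        raise ValueError(
            f"recording {recording.subject_id}/task{recording.task} has "
            f"{n_samples} samples, shorter than one {l}-sample window"
        )
    n_windows = (n_samples - l) // hop + 1
    starts = np.arange(n_windows) * hop
    # (n, l, 8): windows of channel-last samples
    windows = np.stack([recording.samples[:, s : s + l].T for s in starts])
    rec_id = f"{recording.subject_id}/task{recording.task}"
    return WindowedDataset(
        windows=windows,
        labels=np.full(n_windows, recording.task, dtype=object),
        task_labels=np.full(n_windows, recording.task, dtype=object),
        tremor_labels=np.full(n_windows, recording.tremor_type, dtype=object),
        classes=TASKS,
        recording_ids=np.full(n_windows, rec_id, dtype=object),
        chrono_index=np.arange(n_windows),
        window_ms=window_ms,
        overlap_frac=overlap_frac,
        fs_hz=recording.fs_hz,
    )


def segment_study(
    recordings: Sequence[EMGRecording],
    window_ms: float = 250.0,
    overlap_frac: float = 0.5,
) -> WindowedDataset:
    """Segment and concatenate a list of recordings."""
    return WindowedDataset.concatenate(
        [segment(r, window_ms, overlap_frac) for r in recordings]
    )


@dataclass(frozen=True)
class LabelScheme:
    """A total mapping from task labels to classification classes."""

    name: str
    classes: Tuple[str, ...]
    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        missing = [t for t in TASKS if t not in self.mapping]
        if missing:
            raise ValueError(f"scheme {self.name!r} does not map tasks {missing}")
        bad = [c for c in self.mapping.values() if c not in self.classes]
        if bad:
            raise ValueError(f"scheme {self.name!r} maps into unknown classes {bad}")
        # idempotence: the scheme is identity on its own output classes
        full = dict(self.mapping)
        for c in self.classes:
            full.setdefault(c, c)
        object.__setattr__(self, "mapping", full)


TASK6 = LabelScheme("task6", TASKS, {t: t for t in TASKS})
TASK5 = LabelScheme(
    "task5",
    ("1a", "1b", "2", "3or4", "5"),
    {"1a": "1a", "1b": "1b", "2": "2", "3": "3or4", "4": "3or4", "5": "5"},
)
TREMOR3 = LabelScheme("tremor3", ("resting", "postural", "action"), dict(TASK_TO_TREMOR))

SCHEMES: Dict[str, LabelScheme] = {"task6": TASK6, "task5": TASK5, "tremor3": TREMOR3}


def relabel(dataset: WindowedDataset, scheme: LabelScheme) -> WindowedDataset:
    """Replace the active labels according to a label scheme.

    Window content is untouched.  Unknown labels raise a mapping error.
    """
    unknown = sorted({l for l in dataset.labels if l not in scheme.mapping})
    if unknown:
        raise KeyError(f"scheme {scheme.name!r} has no mapping for labels {unknown}")
    new_labels = np.array([scheme.mapping[l] for l in dataset.labels], dtype=object)
    out = dataset.subset(np.arange(len(dataset)))
    out.labels = new_labels
    out.classes = scheme.classes
    return out


def chrono_split(
    dataset: WindowedDataset,
    train_frac: float = 0.8,
) -> Tuple[WindowedDataset, WindowedDataset]:
    """Chronological train/test split applied per source recording.

    Within each recording the first floor(n * train_frac) windows go to
    the train partition and the remainder to test, so no test window
    precedes any train window of the same recording.
    """
    if len(dataset) == 0:
        raise ValueError("cannot split an empty dataset")
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must lie strictly between 0 and 1")
    train_idx, test_idx = [], []
    for rec_id in dict.fromkeys(dataset.recording_ids):  # preserves order
        idx = np.flatnonzero(dataset.recording_ids == rec_id)
        idx = idx[np.argsort(dataset.chrono_index[idx], kind="stable")]
        if len(idx) < 2:
            raise ValueError(
                f"recording {rec_id!r} has {len(idx)} window(s); "
                "need at least 2 to split"
            )
        n_train = int(np.floor(len(idx) * train_frac))
        n_train = min(max(n_train, 1), len(idx) - 1)
        train_idx.append(idx[:n_train])
        test_idx.append(idx[n_train:])
    return (
        dataset.subset(np.concatenate(train_idx)),
        dataset.subset(np.concatenate(test_idx)),
    )
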