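"""Synthetic surface-EMG session generator.

Real sEMG from people with Parkinson's disease is rarely shareable, so this
module generates labelled synthetic sessions that emulate a six-task
clinical tremor-assessment protocol recorded with an 8-channel forearm
armband at 200 Hz:

- tasks ``1a`` / ``1b``: hand at rest, palm down / palm up (resting tremor),
  one minute each;
- task ``2``: postural hold against gravity (postural tremor), one minute;
- tasks ``3`` / ``4``: repeated reach-pinch-return movements, five
  repetitions each (action tremor);
- task ``5``: spiral drawing, one trial (action tremor).

The generative model is a tremor-modulated muscle-synergy mixture: each
channel is a non-negative weighted sum of a small number of muscle
"primitives", each primitive follows a task-specific sub-20 Hz activation
envelope, and the whole voluntary envelope is multiplicatively modulated by
a subject-specific tremor oscillation (4-7 Hz) whose amplitude depends on
the tremor type elicited by the task.  White sensor noise is added on top.
All discriminative structure (envelopes and tremor) lies below 20 Hz so
that it survives the downstream low-pass filter.

Randomness is counter-based (Philox) keyed on ``(profile.seed,
trial_seed)``, so every subject and every trial is independently and
bit-exactly reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

FS_HZ = 200.0
N_CHANNELS = 8
N_PRIMITIVES = 4

TASKS = ("1a", "1b", "2", "3", "4", "5")
TREMOR_TYPES = ("resting", "postural", "action")

#: fixed protocol map from task to the tremor type it elicits
TASK_TO_TREMOR: Dict[str, str] = {
    "1a": "resting",
    "1b": "resting",
    "2": "postural",
    "3": "action",
    "4": "action",
    "5": "action",
}

# per-type tremor amplitude defaults (relative modulation depth)
DEFAULT_TREMOR_AMP: Dict[str, float] = {
    "resting": 0.8,
    "postural": 0.5,
    "action": 0.3,
}

DEFAULT_NOISE_SD = 0.05

#: fraction of the task-3 primitive mix shared with task 4; the two tasks
#: involve near-identical muscle activity, which makes them confusable by
#: design in the 6-class problem
TASK34_MIX_OVERLAP = 0.7


@dataclass(frozen=True)
class TaskScript:
    """One entry of the recording protocol.

    ``duration_s`` is the duration of a single repetition; the recording
    length is ``duration_s * repetitions``.
    """

    task: str
    duration_s: float
    repetitions: int
    tremor_type: str

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}; expected one of {TASKS}")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.repetitions < 1:
            raise ValueError("repetitions must be a positive integer")
        if self.tremor_type not in TREMOR_TYPES:
            raise ValueError(f"unknown tremor type {self.tremor_type!r}")

    @property
    def total_duration_s(self) -> float:
        return self.duration_s * self.repetitions


#: default protocol: one minute for 1a/1b/2, five 4-second repetitions for
#: 3/4, one 15-second spiral for 5
DEFAULT_SCRIPTS: Dict[str, TaskScript] = {
    "1a": TaskScript("1a", 60.0, 1, "resting"),
    "1b": TaskScript("1b", 60.0, 1, "resting"),
    "2": TaskScript("2", 60.0, 1, "postural"),
    "3": TaskScript("3", 4.0, 5, "action"),
    "4": TaskScript("4", 4.0, 5, "action"),
    "5": TaskScript("5", 15.0, 1, "action"),
}


@dataclass(frozen=True)
class SubjectProfile:
    """Subject-specific generative parameters.

    Attributes
    ----------
    tremor_freq_hz:
        Dominant tremor frequency (typically 4-7 Hz for parkinsonian rest
        tremor).
    tremor_amp:
        Relative tremor modulation depth per tremor type.
    synergy:
        ``(8, P)`` non-negative channel-weight matrix mapping muscle
        primitives to electrode channels; each column sums to 1.
    noise_sd:
        Standard deviation of additive white sensor noise.
    """

    subject_id: str
    tremor_freq_hz: float
    tremor_amp: Mapping[str, float]
    synergy: np.ndarray
    noise_sd: float
    seed: int

    def __post_init__(self) -> None:
        syn = np.asarray(self.synergy, dtype=float)
        if syn.shape[0] != N_CHANNELS:
            raise ValueError(f"synergy must have {N_CHANNELS} rows, got {syn.shape}")
        if (syn < 0).any():
            raise ValueError("synergy weights must be non-negative")
        if self.tremor_freq_hz <= 0:
            raise ValueError("tremor_freq_hz must be positive")
        for ttype in TREMOR_TYPES:
            if ttype not in self.tremor_amp:
                raise ValueError(f"tremor_amp missing type {ttype!r}")
            if self.tremor_amp[ttype] < 0:
                raise ValueError("tremor amplitudes must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        object.__setattr__(self, "synergy", syn)
        object.__setattr__(self, "tremor_amp", dict(self.tremor_amp))


@dataclass(frozen=True)
class EMGRecording:
    """One task performance: ``(8, N)`` sample matrix plus ground truth."""

    subject_id: str
    task: str
    tremor_type: str
    fs_hz: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        if s.ndim != 2 or s.shape[0] != N_CHANNELS:
            raise ValueError(f"samples must be (8, N), got {s.shape}")
        if not np.isfinite(s).all():
            raise ValueError("samples contain non-finite values")
        object.__setattr__(self, "samples", s)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz


_OVERRIDABLE = {"tremor_freq_hz", "tremor_amp", "noise_sd", "synergy"}


def _apply_overrides(fields: dict, overrides: Mapping) -> dict:
    """Apply flat or dotted overrides (e.g. ``"tremor_amp.resting"``)."""
    fields = dict(fields)
    for key, value in overrides.items():
        if "." in key:
            top, sub = key.split(".", 1)
            if top != "tremor_amp" or sub not in TREMOR_TYPES:
                raise KeyError(f"unknown override parameter {key!r}")
            amp = dict(fields["tremor_amp"])
            amp[sub] = float(value)
            fields["tremor_amp"] = amp
        elif key in _OVERRIDABLE:
            if key == "tremor_amp":
                fields[key] = {**fields[key], **value}
            else:
                fields[key] = value
        else:
            raise KeyError(f"unknown override parameter {key!r}")
    return fields


def _default_synergy(rng: np.random.Generator) -> np.ndarray:
    """Draw an (8, P) column-stochastic synergy matrix.

    Each primitive concentrates on a different ring sector of the armband
    (Dirichlet with a shifted bump), mimicking electrodes sitting over
    different muscle groups.
    """
    cols = []
    for p in range(N_PRIMITIVES):
        alpha = np.full(N_CHANNELS, 0.4)
        centre = (p * N_CHANNELS) // N_PRIMITIVES
        for off in (-1, 0, 1):
            alpha[(centre + off) % N_CHANNELS] += 2.5 if off == 0 else 1.2
        cols.append(rng.dirichlet(alpha))
    return np.stack(cols, axis=1)


def make_subject(
    subject_id: str,
    seed: int,
    overrides: Optional[Mapping] = None,
) -> SubjectProfile:
    """Create a reproducible subject profile.

    Unspecified parameters are drawn from documented default ranges:
    tremor frequency uniform on 4-7 Hz, tremor amplitudes 0.8/0.5/0.3 for
    resting/postural/action, noise_sd 0.05, and a random ring-structured
    synergy matrix.  Identical ``(subject_id, seed, overrides)`` yield
    identical profiles.
    """
    if seed < 0:
        raise ValueError("seed must be a non-negative integer")
    rng = np.random.Generator(np.random.Philox(key=[np.uint64(seed), np.uint64(0)]))
    fields = {
        "tremor_freq_hz": float(rng.uniform(4.0, 7.0)),
        "tremor_amp": dict(DEFAULT_TREMOR_AMP),
        "noise_sd": DEFAULT_NOISE_SD,
        "synergy": _default_synergy(rng),
    }
    if overrides:
        fields = _apply_overrides(fields, overrides)
    return SubjectProfile(subject_id=subject_id, seed=int(seed), **fields)


# ---------------------------------------------------------------------------
# task envelopes


def _trapezoid(u: np.ndarray, rise: float, hold: float, fall: float) -> np.ndarray:
    """Trapezoidal burst on normalized repetition time u in [0, 1).

    rise/hold/fall are fractions of the repetition; the remainder is a
    rest gap between repetitions.
    """
    env = np.zeros_like(u)
    m = u < rise
    env[m] = u[m] / rise
    m = (u >= rise) & (u < rise + hold)
    env[m] = 1.0
    m = (u >= rise + hold) & (u < rise + hold + fall)
    env[m] = 1.0 - (u[m] - rise - hold) / fall
    return env


def _task_mixes() -> Dict[str, np.ndarray]:
    o = TASK34_MIX_OVERLAP
    return {
        "1a": np.array([1.0, 0.0, 0.0, 0.0]),
        "1b": np.array([0.0, 1.0, 0.0, 0.0]),
        "2": np.array([0.0, 0.15, 0.85, 0.0]),
        "3": np.array([0.0, 0.0, o, 1.0 - o]),
        "4": np.array([0.0, 0.0, 1.0 - o, o]),
        "5": np.array([0.4, 0.0, 0.3, 0.3]),
    }


def _task_profile(task: str, t: np.ndarray, script: TaskScript) -> np.ndarray:
    """Scalar voluntary-activation profile g(t) for a task (all < 20 Hz)."""
    if task in ("1a", "1b"):
        # resting muscle tone: low constant
        return np.full_like(t, 0.3)
    if task == "2":
        # sustained postural hold: strong constant with slow fatigue sag
        return 0.9 - 0.1 * (t / max(t[-1], 1e-9))
    if task in ("3", "4"):
        u = (t / script.duration_s) % 1.0
        if task == "3":
            burst = _trapezoid(u, rise=0.20, hold=0.45, fall=0.15)
        else:
            # same muscles, different movement timing
            burst = _trapezoid(u, rise=0.40, hold=0.20, fall=0.20)
        return 0.08 + 0.92 * burst
    if task == "5":
        # slow spiral-drawing oscillation (~0.6 Hz)
        return 0.55 + 0.35 * np.sin(2.0 * np.pi * 0.6 * t)
    raise ValueError(f"unknown task {task!r}")


def generate_recording(
    profile: SubjectProfile,
    script: TaskScript,
    trial_seed: int,
) -> EMGRecording:
    """Generate one synthetic recording for a subject and task script.

    Channel ``c`` at time ``t`` is::

        noise + sum_p synergy[c, p] * m_p * g(t) * (1 + a * sin(2*pi*f*t + phi))

    where ``m`` is the task's primitive mix, ``g`` the task activation
    profile, ``a`` the subject's tremor amplitude for the task's tremor
    type, ``f`` the subject's tremor frequency and ``phi`` a trial-specific
    phase.  Deterministic given ``(profile, script, trial_seed)``.
    """
    n = int(round(FS_HZ * script.total_duration_s))
    if n < 1:
        raise ValueError("script duration too short for any samples")
    rng = np.random.Generator(
        np.random.Philox(key=[np.uint64(profile.seed), np.uint64(trial_seed)])
    )
    t = np.arange(n) / FS_HZ
    phi = rng.uniform(0.0, 2.0 * np.pi)
    amp = profile.tremor_amp[script.tremor_type]
    tremor = 1.0 + amp * np.sin(2.0 * np.pi * profile.tremor_freq_hz * t + phi)

    mix = _task_mixes()[script.task]
    g = _task_profile(script.task, t, script)
    # (8,) channel gains for this task's primitive mix
    gains = profile.synergy @ mix
    signal = gains[:, None] * (g * tremor)[None, :]
    noise = profile.noise_sd * rng.standard_normal((N_CHANNELS, n))
    return EMGRecording(
        subject_id=profile.subject_id,
        task=script.task,
        tremor_type=script.tremor_type,
        fs_hz=FS_HZ,
        samples=signal + noise,
    )


def generate_study(
    profiles: Sequence[SubjectProfile],
    scripts: Optional[Mapping[str, TaskScript]] = None,
) -> List[EMGRecording]:
    """Generate one recording per task for each subject.

    The trial seed of each recording is the task's index in the protocol,
    so a study is fully determined by its profiles.
    """
    if len(profiles) == 0:
        raise ValueError("profile list must be non-empty")
    ids = [p.subject_id for p in profiles]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate subject_id(s): {dup}")
    scripts = dict(scripts) if scripts is not None else DEFAULT_SCRIPTS
    recordings = []
    for profile in profiles:
        for trial_seed, task in enumerate(TASKS):
            if task in scripts:
                recordings.append(generate_recording(profile, scripts[task], trial_seed))
    return recordings


# ---------------------------------------------------------------------------
# session store: one CSV per recording + one JSON manifest per subject


def save_session(
    recordings: Sequence[EMGRecording],
    out_dir: Path,
    profiles: Optional[Sequence[SubjectProfile]] = None,
) -> None:
    """Persist recordings as delimited text plus per-subject JSON manifests."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = {p.subject_id: p.seed for p in profiles} if profiles else {}
    by_subject: Dict[str, list] = {}
    for i, rec in enumerate(recordings):
        fname = f"{rec.subject_id}_task{rec.task}.csv"
        df = pd.DataFrame(
            rec.samples.T, columns=[f"ch{c + 1}" for c in range(N_CHANNELS)]
        )
        df.to_csv(out_dir / fname, index=False, float_format="%.6g")
        by_subject.setdefault(rec.subject_id, []).append(
            {
                "file": fname,
                "task": rec.task,
                "tremor_type": rec.tremor_type,
                "fs_hz": rec.fs_hz,
                "n_samples": rec.n_samples,
            }
        )
    for subject_id, entries in by_subject.items():
        manifest = {
            "subject_id": subject_id,
            "seed": seeds.get(subject_id),
            "recordings": entries,
        }
        with open(out_dir / f"{subject_id}_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)


def load_session(out_dir: Path, subject_id: str) -> List[EMGRecording]:
    """Load a subject's recordings back from a session directory."""
    out_dir = Path(out_dir)
    manifest_path = out_dir / f"{subject_id}_manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest for subject {subject_id!r} in {out_dir}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    recordings = []
    for entry in manifest["recordings"]:
        df = pd.read_csv(out_dir / entry["file"])
        recordings.append(
            EMGRecording(
                subject_id=subject_id,
                task=entry["task"],
                tremor_type=entry["tremor_type"],
                fs_hz=entry["fs_hz"],
                samples=df.to_numpy().T,
            )
        )
    return recordings
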