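"""Study orchestration: simulate -> filter -> segment -> split -> train -> evaluate.

A study is described by a :class:`StudyConfig` (serialisable to YAML) and
run with :func:`run_pipeline`, which produces one personalized model per
subject and label scheme, mirroring a subject-specific training protocol:
each subject's windows are split chronologically, hyperparameters are
either fixed or searched per subject with aging evolution, and test-set
confusion matrices and metrics are written alongside a JSON run record.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import yaml

from emgtremor import __version__ as _pkg_version
from emgtremor.synth import make_subject, generate_study, save_session
from emgtremor.preprocess import (
    FilterSpec,
    SCHEMES,
    lowpass_filter,
    segment_study,
    relabel,
    chrono_split,
)
from emgtremor.bilstm import BiLSTMClassifier, save_model
from emgtremor.nas import (
    NASConfig, SearchSpace, TABLE1_SPACE, evolve, validation_fitness,
)
from emgtremor.metrics import confusion_matrix, metrics

DEFAULT_HYPER = {
    "n_neurons": 20,
    "learning_rate": 1e-3,
    "n_epochs": 50,
    "batch_size": 128,
    "optimizer": "Adam",
    "activation": "tanh",
}


@dataclass
class StudyConfig:
    """Everything needed to reproduce a run: generator, preprocessing,
    model/search settings and output paths."""

    n_subjects: int = 3
    base_seed: int = 0
    subject_overrides: Dict = field(default_factory=dict)
    filter_order: int = 4
    filter_cutoff_hz: float = 20.0
    filter_mode: str = "zero_phase"
    window_ms: float = 250.0
    overlap_frac: float = 0.5
    train_frac: float = 0.8
    schemes: Sequence[str] = ("task5", "tremor3")
    hyper: Dict = field(default_factory=lambda: dict(DEFAULT_HYPER))
    cell_mode: str = "standard"
    use_nas: bool = False
    nas: Dict = field(default_factory=dict)
    nas_max_epochs: Optional[int] = 10
    nas_max_windows: Optional[int] = 512
    nas_space: Optional[Dict] = None
    out_dir: str = "emgtremor_run"

    @staticmethod
    def from_yaml(path: Path) -> "StudyConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in StudyConfig.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        return StudyConfig(**data)

    def to_yaml(self, path: Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self._as_plain(), fh, sort_keys=False)

    def _as_plain(self) -> dict:
        d = asdict(self)
        d["schemes"] = list(self.schemes)
        return d


@dataclass
class RunRecord:
    """Snapshot of a finished run: config, artefact paths, final metrics."""

    config: dict
    version: str
    timings_s: Dict[str, float]
    artefacts: Dict[str, str]
    results: Dict[str, Dict]

    def save(self, path: Path) -> None:
        tmp = Path(str(path) + ".tmp")
        with open(tmp, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)
        tmp.replace(path)  # atomic finalize


def _subject_windows(config: StudyConfig, subject_idx: int, log=print):
    """Generate, filter and segment one subject's session."""
    subject_id = f"s{subject_idx + 1:02d}"
    profile = make_subject(
        subject_id, seed=config.base_seed + subject_idx,
        overrides=config.subject_overrides or None,
    )
    recordings = generate_study([profile])
    spec = FilterSpec(
        order=config.filter_order,
        cutoff_hz=config.filter_cutoff_hz,
        mode=config.filter_mode,
    )
    filtered = [lowpass_filter(r, spec) for r in recordings]
    windows = segment_study(filtered, config.window_ms, config.overlap_frac)
    log(f"[{subject_id}] {len(windows)} windows from {len(recordings)} recordings")
    return subject_id, profile, windows


def run_pipeline(config: StudyConfig, log=print) -> RunRecord:
    """Execute the full study described by ``config``.

    For every subject and every label scheme, trains a personalized model
    (fixed hyperparameters or per-subject aging-evolution search) on the
    chronologically first portion of the windows and evaluates on the
    final portion.  Fails loudly with the stage and subject on error.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    timings: Dict[str, float] = {}
    artefacts: Dict[str, str] = {}
    results: Dict[str, Dict] = {}

    for s in range(config.n_subjects):
        t0 = time.perf_counter()
        stage = "simulate"
        subject_id = f"s{s + 1:02d}"
        try:
            subject_id, profile, windows = _subject_windows(config, s, log)
            timings[f"{subject_id}/prepare"] = time.perf_counter() - t0
            results[subject_id] = {}
            for scheme_name in config.schemes:
                stage = f"scheme:{scheme_name}"
                scheme = SCHEMES[scheme_name]
                ds = relabel(windows, scheme)
                train_ds, test_ds = chrono_split(ds, config.train_frac)

                hyper = dict(config.hyper)
                if config.use_nas:
                    stage = f"nas:{scheme_name}"
                    t_nas = time.perf_counter()
                    fitness = validation_fitness(
                        train_ds.windows, train_ds.labels,
                        cell_mode=config.cell_mode,
                        seed=config.base_seed,
                        max_epochs=config.nas_max_epochs,
                        max_windows=config.nas_max_windows,
                    )
                    space = (
                        SearchSpace(config.nas_space)
                        if config.nas_space
                        else TABLE1_SPACE
                    )
                    nas_cfg = NASConfig(seed=config.base_seed + s, **config.nas)
                    best, search_log = evolve(space, nas_cfg, fitness)
                    hyper = best.hyper.as_dict()
                    log_path = out_dir / f"{subject_id}_{scheme_name}_nas.jsonl"
                    search_log.to_jsonl(log_path)
                    artefacts[f"{subject_id}/{scheme_name}/nas_log"] = str(log_path)
                    timings[f"{subject_id}/{scheme_name}/nas"] = (
                        time.perf_counter() - t_nas
                    )
                    log(f"[{subject_id}] {scheme_name} NAS best: {hyper}")

                stage = f"train:{scheme_name}"
                t_train = time.perf_counter()
                hyper["batch_size"] = min(int(hyper["batch_size"]), len(train_ds))
                clf = BiLSTMClassifier(
                    cell_mode=config.cell_mode,
                    random_state=config.base_seed + s,
                    **hyper,
                )
                clf.fit(train_ds.windows, train_ds.labels)
                timings[f"{subject_id}/{scheme_name}/train"] = (
                    time.perf_counter() - t_train
                )

                stage = f"evaluate:{scheme_name}"
                cm = confusion_matrix(
                    test_ds.labels, clf.predict(test_ds.windows), scheme.classes
                )
                m = metrics(cm)
                ckpt = out_dir / f"{subject_id}_{scheme_name}_model"
                save_model(clf.model_, ckpt)
                cm_path = out_dir / f"{subject_id}_{scheme_name}_confusion.csv"
                cm.to_csv(cm_path)
                metrics_path = out_dir / f"{subject_id}_{scheme_name}_metrics.csv"
                m.to_frame().to_csv(metrics_path, index=False)
                artefacts[f"{subject_id}/{scheme_name}/model"] = str(ckpt)
                artefacts[f"{subject_id}/{scheme_name}/confusion"] = str(cm_path)
                artefacts[f"{subject_id}/{scheme_name}/metrics"] = str(metrics_path)
                results[subject_id][scheme_name] = {
                    "accuracy": m.accuracy,
                    "hyper": hyper,
                    "n_train": len(train_ds),
                    "n_test": len(test_ds),
                }
                log(
                    f"[{subject_id}] {scheme_name}: test accuracy "
                    f"{m.accuracy:.3f} ({len(test_ds)} windows)"
                )
        except Exception as err:
            raise RuntimeError(
                f"pipeline failed at stage {stage!r} for subject {subject_id}: {err}"
            ) from err

    record = RunRecord(
        config=config._as_plain(),
        version=_pkg_version,
        timings_s=timings,
        artefacts=artefacts,
        results=results,
    )
    record.save(out_dir / "run_record.json")
    return record
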