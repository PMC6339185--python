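"""Windowed sensor-segment data model, loaders, normalization and a synthetic
multi-subject population simulator.

A *window* is a fixed-length [T, C] array of multi-channel sensor readings
(e.g. 3-axis accelerometer + 3-axis gyroscope) already segmented from the
continuous stream.  A :class:`WindowSet` stacks the windows of one subject
together with integer activity labels.  Cross-subject transfer tasks are
expressed as a :class:`DomainSplit`: a labeled source subject, an unlabeled
portion of the target subject used during adaptation, and a held-out labeled
target portion used only for evaluation.

The simulator emulates the structure of public daily-activity datasets
(several subjects, a shared activity vocabulary, balanced fixed-length
windows) with an explicit, controllable cross-subject covariate shift:
per-subject amplitude gain, frequency warp, per-channel DC offset, and
independent phase draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.model_selection import train_test_split

__all__ = [
    "WindowSet",
    "DomainSplit",
    "SimulatorConfig",
    "simulate_population",
    "load_segment_directory",
    "zscore_normalize",
    "make_domain_split",
    "save_population",
    "load_population",
]


@dataclass
class WindowSet:
    """A labeled, subject-tagged stack of fixed-length sensor windows.

    Parameters
    ----------
    data
        Array of shape ``[N, T, C]``: N windows of T time steps and C channels.
    labels
        Integer activity labels in ``[0, A)``, one per window.
    subject_id
        Identifier of the subject the windows came from.
    sample_rate_hz
        Sampling rate of the time axis.
    class_names
        Names of the A activity classes; ``len(class_names)`` defines A.
    """

    data: np.ndarray
    labels: np.ndarray
    subject_id: str
    sample_rate_hz: float
    class_names: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.data.ndim != 3:
            raise ValueError(f"data must be [N, T, C], got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains NaN or Inf")
        if self.labels.shape != (self.data.shape[0],):
            raise ValueError(
                f"labels length {self.labels.shape} does not match N={self.data.shape[0]}"
            )
        a = len(self.class_names)
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= a):
            raise ValueError(f"labels must lie in [0, {a})")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")

    @property
    def n_windows(self) -> int:
        return self.data.shape[0]

    @property
    def n_timesteps(self) -> int:
        return self.data.shape[1]

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def subset(self, idx: np.ndarray) -> "WindowSet":
        """Return a new WindowSet restricted to the given window indices."""
        return replace(self, data=self.data[idx], labels=self.labels[idx])


@dataclass
class DomainSplit:
    """One cross-subject transfer task.

    ``source_train`` is labeled; ``target_train`` carries labels for bookkeeping
    but no training path may read them; ``target_test`` is evaluation-only.
    """

    source_train: WindowSet
    target_train: WindowSet
    target_test: WindowSet
    description: str = ""

    def __post_init__(self) -> None:
        ws = (self.source_train, self.target_train, self.target_test)
        shapes = {(w.n_timesteps, w.n_channels, w.n_classes) for w in ws}
        if len(shapes) != 1:
            raise ValueError(f"source/target WindowSets disagree on (T, C, A): {shapes}")


@dataclass
class SimulatorConfig:
    """Parameters of the synthetic multi-subject population.

    Each activity is a harmonic series at a class-specific base frequency;
    each subject perturbs it with a multiplicative gain (log-normal,
    ``subject_amp_sd`` on the log scale), a frequency warp (normal around 1,
    ``subject_freq_sd``), a per-channel DC offset (``subject_offset_sd``) and
    fresh phase draws.  White Gaussian noise of ``noise_sd`` is added on top.
    """

    n_subjects: int = 8
    n_activities: int = 19
    windows_per_class: int = 60
    T: int = 128
    C: int = 6
    sample_rate_hz: float = 25.0
    base_freqs_hz: Sequence[float] | None = None
    n_harmonics: int = 3
    subject_amp_sd: float = 0.4
    subject_freq_sd: float = 0.1
    subject_offset_sd: float = 0.5
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.n_activities < 2:
            raise ValueError("n_activities must be >= 2")
        if self.windows_per_class < 1:
            raise ValueError("windows_per_class must be >= 1")
        if self.base_freqs_hz is None:
            # cadence-like activity frequencies, spread across [0.8, 3.5] Hz
            self.base_freqs_hz = list(
                np.linspace(0.8, 3.5, self.n_activities)
            )
        self.base_freqs_hz = [float(f) for f in self.base_freqs_hz]
        if len(self.base_freqs_hz) != self.n_activities:
            raise ValueError(
                f"base_freqs_hz has {len(self.base_freqs_hz)} entries for "
                f"{self.n_activities} activities"
            )
        if len(set(self.base_freqs_hz)) != self.n_activities:
            raise ValueError("distinct activities need distinct base frequencies")
        nyquist = self.sample_rate_hz / 2.0
        if max(self.base_freqs_hz) * self.n_harmonics >= nyquist:
            raise ValueError(
                f"max base frequency x n_harmonics = "
                f"{max(self.base_freqs_hz) * self.n_harmonics:g} Hz violates the "
                f"Nyquist limit {nyquist:g} Hz"
            )
        for name in ("subject_amp_sd", "subject_freq_sd", "subject_offset_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def simulate_population(config: SimulatorConfig) -> list[WindowSet]:
    """Draw a synthetic multi-subject population, one WindowSet per subject.

    The window for subject *s*, activity *a*, channel *c* is

    ``sum_h (g_s * w_{c,h} / h) * sin(2 pi h f_a r_s t + phi) + b_{s,c} + eps``

    with gain ``g_s = exp(N(0, subject_amp_sd))``, frequency warp
    ``r_s = 1 + N(0, subject_freq_sd)``, offset ``b_{s,c} ~ N(0, subject_offset_sd)``,
    phases ``phi`` independent per window and harmonic, and white noise ``eps``.
    Channel/harmonic weights ``w_{c,h}`` are population-level (shared by all
    subjects).  Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    A, H, T, C = config.n_activities, config.n_harmonics, config.T, config.C
    t = np.arange(T) / config.sample_rate_hz

    # population-level structure: how strongly each channel carries harmonic h
    chan_weights = rng.uniform(0.3, 1.0, size=(C, H))
    harm_decay = 1.0 / np.arange(1, H + 1)

    # per-subject shift parameters
    gains = np.exp(rng.normal(0.0, config.subject_amp_sd, size=config.n_subjects))
    warps = np.clip(
        1.0 + rng.normal(0.0, config.subject_freq_sd, size=config.n_subjects), 0.1, None
    )
    offsets = rng.normal(0.0, config.subject_offset_sd, size=(config.n_subjects, C))

    class_names = [f"activity_{a}" for a in range(A)]
    population: list[WindowSet] = []
    for s in range(config.n_subjects):
        n = A * config.windows_per_class
        data = np.empty((n, T, C))
        labels = np.repeat(np.arange(A), config.windows_per_class)
        for a in range(A):
            freqs = np.arange(1, H + 1) * config.base_freqs_hz[a] * warps[s]  # [H]
            phases = rng.uniform(
                0.0, 2.0 * np.pi, size=(config.windows_per_class, H)
            )
            # [W, T, H] harmonic waveforms, then mix into channels
            waves = np.sin(
                2.0 * np.pi * freqs[None, None, :] * t[None, :, None]
                + phases[:, None, :]
            )
            amp = gains[s] * harm_decay  # [H]
            block = np.einsum("wth,ch,h->wtc", waves, chan_weights, amp)
            lo = a * config.windows_per_class
            data[lo : lo + config.windows_per_class] = block
        data += offsets[s][None, None, :]
        if config.noise_sd > 0:
            data += rng.normal(0.0, config.noise_sd, size=data.shape)
        population.append(
            WindowSet(
                data=data,
                labels=labels,
                subject_id=f"S{s}",
                sample_rate_hz=config.sample_rate_hz,
                class_names=class_names,
            )
        )
    return population


def zscore_normalize(target: WindowSet, stats_from: WindowSet) -> WindowSet:
    """Z-score ``target`` per channel using mean/sd computed from ``stats_from``.

    Normalizing a set by its own statistics yields per-channel mean 0 and sd 1.
    Raises if any channel of ``stats_from`` has zero variance.
    """
    flat = stats_from.data.reshape(-1, stats_from.n_channels)
    mean = flat.mean(axis=0)
    sd = flat.std(axis=0)
    dead = np.flatnonzero(sd == 0.0)
    if dead.size:
        raise ValueError(f"zero-variance channel(s) in stats_from: {dead.tolist()}")
    return replace(target, data=(target.data - mean) / sd)


def make_domain_split(
    source: WindowSet,
    target: WindowSet,
    target_train_fraction: float = 2.0 / 3.0,
    seed: int = 0,
    description: str | None = None,
) -> DomainSplit:
    """Partition ``target`` into adaptation/evaluation halves and build a task.

    The partition is stratified by class at the requested fraction and is
    deterministic under ``seed``.  All of the labeled source set is used for
    training (the standard protocol keeps the source split fixed).
    """
    if not 0.0 < target_train_fraction < 1.0:
        raise ValueError("target_train_fraction must be in (0, 1)")
    counts = np.bincount(target.labels, minlength=target.n_classes)
    small = np.flatnonzero(counts < 2)
    if small.size:
        raise ValueError(
            f"target classes with fewer than 2 windows cannot be split: {small.tolist()}"
        )
    idx = np.arange(target.n_windows)
    train_idx, test_idx = train_test_split(
        idx,
        train_size=target_train_fraction,
        random_state=seed,
        stratify=target.labels,
    )
    train_idx.sort()
    test_idx.sort()
    if description is None:
        description = f"{source.subject_id}~{target.subject_id}"
    return DomainSplit(
        source_train=source,
        target_train=target.subset(train_idx),
        target_test=target.subset(test_idx),
        description=description,
    )


def load_segment_directory(
    path: str | Path,
    sample_rate_hz: float = 25.0,
    class_names: Sequence[str] | None = None,
    label_merge: dict[int, int] | None = None,
) -> list[WindowSet]:
    """Read a directory of per-activity/per-subject plain-text segment files.

    Expected layout ``<activity>/<subject>/<segment>.txt`` where each segment
    file is one window: T rows of C comma-separated numbers.  Activity folders
    sorted lexicographically define the class order unless ``class_names``
    overrides it.  ``label_merge`` maps class indices onto others (e.g. merging
    two near-identical activities), compacting the label range afterwards.

    Returns one WindowSet per subject.  Files that do not parse to the common
    T x C shape raise an error naming the offending file.
    """
    root = Path(path)
    if not root.is_dir():
        raise FileNotFoundError(f"{root} is not a directory")
    act_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if not act_dirs:
        raise ValueError(f"no activity folders found under {root}")
    if class_names is None:
        class_names = [d.name for d in act_dirs]
    else:
        class_names = list(class_names)
        missing = set(class_names) - {d.name for d in act_dirs}
        if missing:
            raise ValueError(f"class folders not found: {sorted(missing)}")
        act_dirs = [root / c for c in class_names]

    per_subject: dict[str, list[tuple[np.ndarray, int]]] = {}
    shape: tuple[int, int] | None = None
    for label, act_dir in enumerate(act_dirs):
        for subj_dir in sorted(d for d in act_dir.iterdir() if d.is_dir()):
            for seg in sorted(subj_dir.iterdir()):
                if seg.is_dir():
                    continue
                try:
                    mat = np.loadtxt(seg, delimiter=",", ndmin=2)
                except Exception as exc:  # ragged rows, non-numeric, ...
                    raise ValueError(f"failed to parse segment file {seg}: {exc}") from exc
                if shape is None:
                    shape = mat.shape
                elif mat.shape != shape:
                    raise ValueError(
                        f"segment file {seg} has shape {mat.shape}, expected {shape}"
                    )
                per_subject.setdefault(subj_dir.name, []).append((mat, label))
    if not per_subject:
        raise ValueError(f"no segment files found under {root}")

    merged_names = list(class_names)
    if label_merge:
        keep = sorted(set(range(len(class_names))) - set(label_merge))
        remap = {old: new for new, old in enumerate(keep)}
        for src, dst in label_merge.items():
            if dst in label_merge:
                raise ValueError(f"label_merge target {dst} is itself merged away")
            remap[src] = remap[dst]
        merged_names = [class_names[old] for old in keep]
    out = []
    for subject in sorted(per_subject):
        mats, labels = zip(*per_subject[subject])
        labels = np.asarray(labels)
        if label_merge:
            labels = np.asarray([remap[int(l)] for l in labels])
        out.append(
            WindowSet(
                data=np.stack(mats),
                labels=labels,
                subject_id=subject,
                sample_rate_hz=sample_rate_hz,
                class_names=merged_names,
            )
        )
    return out


def save_population(population: list[WindowSet], out_dir: str | Path, config: SimulatorConfig | None = None) -> None:
    """Persist a population as one .npz per subject plus a JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta: dict = {"subjects": []}
    for ws in population:
        np.savez(
            out / f"{ws.subject_id}.npz",
            data=ws.data,
            labels=ws.labels,
        )
        meta["subjects"].append(
            {
                "subject_id": ws.subject_id,
                "sample_rate_hz": ws.sample_rate_hz,
                "class_names": ws.class_names,
            }
        )
    if config is not None:
        meta["simulator_config"] = {
            k: (list(v) if isinstance(v, (list, tuple)) else v)
            for k, v in vars(config).items()
        }
    (out / "population.json").write_text(json.dumps(meta, indent=2))


def load_population(in_dir: str | Path) -> list[WindowSet]:
    """Load a population previously written by :func:`save_population`."""
    root = Path(in_dir)
    meta = json.loads((root / "population.json").read_text())
    out = []
    for entry in meta["subjects"]:
        with np.load(root / f"{entry['subject_id']}.npz") as z:
            out.append(
                WindowSet(
                    data=z["data"],
                    labels=z["labels"],
                    subject_id=entry["subject_id"],
                    sample_rate_hz=entry["sample_rate_hz"],
                    class_names=entry["class_names"],
                )
            )
    return out
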