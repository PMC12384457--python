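"""Loading, epoching, normalisation and splitting of motor-imagery EEG.

The pipeline currency is the :class:`TrialSet`: an (n_trials, n_channels,
n_samples) array with integer class labels and per-trial subject/session
metadata.  Real recordings come in as GDF files (the BCI Competition IV
container, read through :mod:`mne`); synthetic ones from
:mod:`gahtnet.synth`.  TrialSets can be cached to HDF5.

Epochs are cue-locked: each trial spans ``[cue - t_pre, cue + t_post)``
(half-open, 0-based sample indices), so 250 Hz with t_pre=0.5 and
t_post=4.0 yields 1125 samples.  Channel-wise z-scoring uses population
statistics computed on the training partition only and applied to both
partitions, which keeps the test set out of the normalisation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "RawRecording",
    "TrialSet",
    "EEGIOError",
    "load_gdf_recording",
    "extract_epochs",
    "zscore_channels",
    "subject_dependent_split",
    "loso_folds",
    "concat_trialsets",
    "save_trialset",
    "load_trialset",
]


class EEGIOError(ValueError):
    """Raised for unreadable files, bad windows and degenerate inputs."""


@dataclass
class RawRecording:
    """A continuous multichannel recording plus its event stream."""

    signal: np.ndarray  # (channels, samples), microvolt
    fs: float
    events: list[tuple[int, int]]  # (sample_index, event_code)
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.fs <= 0:
            raise EEGIOError(f"sampling rate must be positive, got {self.fs}")
        n = self.signal.shape[1]
        for s, _code in self.events:
            if not 0 <= s < n:
                raise EEGIOError(f"event at sample {s} outside recording of {n}")


@dataclass
class TrialSet:
    """Labelled epoched EEG with sampling and provenance metadata."""

    data: np.ndarray  # (trials, channels, samples)
    labels: np.ndarray  # (trials,) int in [0, n_classes)
    fs: float
    subjects: np.ndarray | None = None  # (trials,) int
    sessions: np.ndarray | None = None  # (trials,) int, 1-based
    class_names: tuple[str, ...] = ()

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.data.ndim != 3:
            raise EEGIOError(f"data must be 3-D, got shape {self.data.shape}")
        if len(self.labels) != self.data.shape[0]:
            raise EEGIOError("labels length must match the number of trials")
        if self.subjects is None:
            self.subjects = np.zeros(len(self.labels), dtype=np.int64)
        else:
            self.subjects = np.asarray(self.subjects, dtype=np.int64)
        if self.sessions is None:
            self.sessions = np.ones(len(self.labels), dtype=np.int64)
        else:
            self.sessions = np.asarray(self.sessions, dtype=np.int64)
        if len(self.subjects) != len(self.labels) or len(self.sessions) != len(self.labels):
            raise EEGIOError("subject/session metadata must be per trial")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def n_classes(self) -> int:
        return len(self.class_names) if self.class_names else int(self.labels.max()) + 1

    def select(self, idx: np.ndarray) -> "TrialSet":
        idx = np.asarray(idx)
        return TrialSet(
            data=self.data[idx],
            labels=self.labels[idx],
            fs=self.fs,
            subjects=self.subjects[idx],
            sessions=self.sessions[idx],
            class_names=self.class_names,
        )


def concat_trialsets(parts: list[TrialSet]) -> TrialSet:
    if not parts:
        raise EEGIOError("nothing to concatenate")
    fs = parts[0].fs
    if any(p.fs != fs for p in parts):
        raise EEGIOError("sampling rates differ across parts")
    return TrialSet(
        data=np.concatenate([p.data for p in parts]),
        labels=np.concatenate([p.labels for p in parts]),
        fs=fs,
        subjects=np.concatenate([p.subjects for p in parts]),
        sessions=np.concatenate([p.sessions for p in parts]),
        class_names=parts[0].class_names,
    )


def load_gdf_recording(path: str | Path) -> RawRecording:
    """Read a GDF file (BCI Competition IV dialect) into a RawRecording.

    Event codes come from the GDF annotation stream; signal values are
    returned in microvolts.
    """
    path = Path(path)
    if not path.exists():
        raise EEGIOError(f"GDF file not found: {path}")
    import mne

    try:
        raw = mne.io.read_raw_gdf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises several types for corrupt files
        raise EEGIOError(f"unreadable GDF file {path}: {exc}") from exc
    events, event_id = mne.events_from_annotations(raw, verbose="error")
    # map mne's arbitrary integer ids back to the original GDF codes
    id_to_code = {}
    for desc, mne_id in event_id.items():
        try:
            id_to_code[mne_id] = int(desc)
        except ValueError:
            id_to_code[mne_id] = mne_id
    ev = [(int(s), id_to_code[int(i)]) for s, _prev, i in events]
    return RawRecording(
        signal=raw.get_data() * 1e6,
        fs=float(raw.info["sfreq"]),
        events=ev,
        channel_names=list(raw.ch_names),
    )


def extract_epochs(
    rec: RawRecording,
    t_pre: float,
    t_post: float,
    event_codes: dict[int, int] | list[int],
    fs_override: float | None = None,
    class_names: tuple[str, ...] = (),
) -> TrialSet:
    """Cut cue-locked epochs ``[cue - t_pre, cue + t_post)`` from a recording.

    ``event_codes`` maps event code -> class label; a plain list assigns
    labels by position.  Epochs that would run past either end of the
    recording are dropped with a warning.
    """
    if t_pre + t_post <= 0:
        raise EEGIOError("epoch window must have positive duration")
    if isinstance(event_codes, dict):
        code_to_label = dict(event_codes)
    else:
        code_to_label = {c: i for i, c in enumerate(event_codes)}
    fs = fs_override if fs_override is not None else rec.fs
    n_pre = int(round(fs * t_pre))
    n_len = int(round(fs * (t_pre + t_post)))
    n_total = rec.signal.shape[1]
    trials, labels = [], []
    n_matching = 0
    for sample, code in rec.events:
        if code not in code_to_label:
            continue
        n_matching += 1
        start = sample - n_pre
        stop = start + n_len
        if start < 0 or stop > n_total:
            logger.warning(
                "dropping epoch at sample %d (window [%d, %d) outside recording)",
                sample, start, stop,
            )
            continue
        trials.append(rec.signal[:, start:stop])
        labels.append(code_to_label[code])
    if n_matching == 0:
        raise EEGIOError(
            f"no events matching codes {sorted(code_to_label)} in recording"
        )
    data = (
        np.stack(trials)
        if trials
        else np.empty((0, rec.signal.shape[0], n_len))
    )
    return TrialSet(
        data=data, labels=np.array(labels, dtype=np.int64), fs=fs,
        class_names=class_names,
    )


def zscore_channels(trials: TrialSet, stats_from: TrialSet | None = None) -> TrialSet:
    """Channel-wise z-scoring: z = (x - mu) / sigma.

    mu and sigma**2 are population statistics per channel pooled over all
    trials and samples of ``stats_from`` (the training partition; defaults
    to ``trials`` itself) and then applied to ``trials``.
    """
    ref = stats_from if stats_from is not None else trials
    if ref.n_trials == 0:
        raise EEGIOError("cannot compute statistics from an empty TrialSet")
    if ref.n_channels != trials.n_channels:
        raise EEGIOError(
            f"channel count mismatch: {ref.n_channels} vs {trials.n_channels}"
        )
    mu = ref.data.mean(axis=(0, 2))
    sigma = ref.data.std(axis=(0, 2))  # population (divide by n)
    zero = np.flatnonzero(sigma == 0)
    if zero.size:
        raise EEGIOError(f"zero variance on channel index {int(zero[0])}")
    z = (trials.data - mu[None, :, None]) / sigma[None, :, None]
    return TrialSet(
        data=z, labels=trials.labels.copy(), fs=trials.fs,
        subjects=trials.subjects.copy(), sessions=trials.sessions.copy(),
        class_names=trials.class_names,
    )


_PROTOCOL_SESSIONS = {
    "2a": ({1}, {2}),
    "2b": ({1, 2, 3}, {4, 5}),
}


def subject_dependent_split(
    sessions: TrialSet, protocol: str = "2a"
) -> tuple[TrialSet, TrialSet]:
    """Session-based train/test split of one subject's trials.

    Protocol "2a": session 1 trains, session 2 tests.  Protocol "2b":
    sessions 1-3 train, sessions 4-5 test.
    """
    if protocol not in _PROTOCOL_SESSIONS:
        raise EEGIOError(f"unknown protocol {protocol!r}; choose '2a' or '2b'")
    train_ids, test_ids = _PROTOCOL_SESSIONS[protocol]
    present = set(int(s) for s in np.unique(sessions.sessions))
    missing = (train_ids | test_ids) - present
    if missing:
        raise EEGIOError(
            f"protocol {protocol!r} needs sessions {sorted(train_ids | test_ids)}, "
            f"missing {sorted(missing)}"
        )
    train_mask = np.isin(sessions.sessions, sorted(train_ids))
    test_mask = np.isin(sessions.sessions, sorted(test_ids))
    return sessions.select(np.flatnonzero(train_mask)), sessions.select(
        np.flatnonzero(test_mask)
    )


def loso_folds(all_subjects: TrialSet) -> list[tuple[TrialSet, TrialSet]]:
    """Leave-one-subject-out folds: fold i tests subject i, trains on the rest."""
    ids = np.unique(all_subjects.subjects)
    if len(ids) < 2:
        raise EEGIOError(f"LOSO needs >= 2 subjects, got {len(ids)}")
    folds = []
    for sid in ids:
        test_mask = all_subjects.subjects == sid
        folds.append(
            (
                all_subjects.select(np.flatnonzero(~test_mask)),
                all_subjects.select(np.flatnonzero(test_mask)),
            )
        )
    return folds


def save_trialset(trials: TrialSet, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=trials.data)
        f.create_dataset("labels", data=trials.labels)
        f.create_dataset("subjects", data=trials.subjects)
        f.create_dataset("sessions", data=trials.sessions)
        f.attrs["fs"] = trials.fs
        f.attrs["class_names"] = list(trials.class_names)


def load_trialset(path: str | Path) -> TrialSet:
    path = Path(path)
    if not path.exists():
        raise EEGIOError(f"TrialSet cache not found: {path}")
    with h5py.File(path, "r") as f:
        return TrialSet(
            data=f["data"][()],
            labels=f["labels"][()],
            fs=float(f.attrs["fs"]),
            subjects=f["subjects"][()],
            sessions=f["sessions"][()],
            class_names=tuple(str(c) for c in f.attrs["class_names"]),
        )
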