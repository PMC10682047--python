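"""From labeled recordings to the fixed-size window dataset the classifier eats.

A recording's four channels (ax, ay, az, semg — fixed stacking order) are
z-scored per recording, then cut into ``n_sequences`` windows of ``length``
samples each.  Window starts are drawn at random but the final set is adjusted
so the union of windows covers every sample of the recording; windows may
overlap.  Labels become one-hot rows; train/test splits are subject-disjoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .synth import CLASSIFIER_KINDS, Recording, recording_label

DEFAULT_WINDOW_LEN = 1000
DEFAULT_N_SEQUENCES = 100
CHANNEL_ORDER = ("ax", "ay", "az", "semg")


@dataclass
class SequenceWindow:
    """One C x L labeled segment cut from a recording."""

    values: np.ndarray  # (C, L) float32
    label: int
    subject_id: str
    source_offset: int
    role: str = "train"  # train | heldout | test


@dataclass
class Dataset:
    """Windowed, labeled, subject-partitioned data for training and evaluation.

    ``split`` maps each subject id to "train" or "test"; windows from a train
    subject's held-back recordings carry role "heldout" and are never used for
    fitting.  ``one_hot`` rows sum to one by construction.
    """

    windows: list[SequenceWindow]
    n_classes: int
    class_names: list[str]
    split: dict[str, str]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        train_subj = {s for s, v in self.split.items() if v == "train"}
        test_subj = {s for s, v in self.split.items() if v == "test"}
        if train_subj & test_subj:
            raise ValueError("train and test subject sets must be disjoint")
        for w in self.windows:
            if not 0 <= w.label < self.n_classes:
                raise ValueError(f"label {w.label} outside [0, {self.n_classes})")

    def _select(self, role: str) -> np.ndarray:
        return np.array([i for i, w in enumerate(self.windows) if w.role == role],
                        dtype=int)

    def tensors(self, role: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(X, y, subject_ids) for the windows with the given role."""
        idx = self._select(role)
        X = np.stack([self.windows[i].values for i in idx]) if idx.size else \
            np.empty((0, 0, 0), dtype=np.float32)
        y = np.array([self.windows[i].label for i in idx], dtype=int)
        subj = np.array([self.windows[i].subject_id for i in idx])
        return X, y, subj

    @property
    def one_hot_matrix(self) -> np.ndarray:
        return one_hot([w.label for w in self.windows], self.n_classes)

    def summary(self) -> str:
        roles = {}
        for w in self.windows:
            roles[w.role] = roles.get(w.role, 0) + 1
        parts = ", ".join(f"{k}={v}" for k, v in sorted(roles.items()))
        return (
            f"Dataset: {len(self.windows)} windows ({parts}), "
            f"{self.n_classes} classes, "
            f"{sum(v == 'train' for v in self.split.values())} train / "
            f"{sum(v == 'test' for v in self.split.values())} test subjects"
        )


def normalize(recording: Recording) -> Recording:
    """Per-channel z-score over the whole recording (streaming-style stats).

    Constant channels map to zeros with a warning rather than dividing by
    zero.  Idempotent up to floating-point tolerance and invariant to channel
    scaling.
    """
    if recording.n_samples == 0:
        raise ValueError("cannot normalize an empty recording")
    channels = {}
    for name in Recording.CHANNEL_NAMES:
        x = getattr(recording, name)
        sd = float(np.std(x))
        if sd == 0.0:
            warnings.warn(f"channel {name} is constant; normalized to zeros",
                          stacklevel=2)
            channels[name] = np.zeros_like(x)
        else:
            channels[name] = (x - float(np.mean(x))) / sd
    return Recording(
        fs=recording.fs,
        annotations=list(recording.annotations),
        subject=recording.subject,
        seed=recording.seed,
        **channels,
    )


def _coverage_counts(offsets: np.ndarray, length: int, n: int) -> np.ndarray:
    cov = np.zeros(n + 1, dtype=np.int64)
    np.add.at(cov, offsets, 1)
    np.add.at(cov, offsets + length, -1)
    return np.cumsum(cov[:-1])


def _enforce_coverage(
    offsets: np.ndarray, length: int, n: int, max_passes: int = 64
) -> np.ndarray:
    """Re-position the fewest windows needed so the union covers [0, n).

    Greedy left-to-right: at the first uncovered index, move the most
    redundant un-pinned window (largest minimum coverage over its span) to
    start there; pinned windows never move again.  Because a pinned window
    covers ``length`` samples past each gap, at most ceil(n/length) pins are
    needed, which ``n_sequences * length >= n`` guarantees to be available.
    """
    offsets = offsets.copy()
    pinned: set[int] = set()
    for _ in range(max_passes):
        cov = _coverage_counts(offsets, length, n)
        uncovered = np.flatnonzero(cov == 0)
        if uncovered.size == 0:
            return offsets
        pos = int(uncovered[0])
        target = min(pos, n - length)
        movable = [i for i in range(offsets.size) if i not in pinned]
        if not movable:
            break
        scores = [int(cov[offsets[i]: offsets[i] + length].min()) for i in movable]
        j = movable[int(np.argmax(scores))]
        offsets[j] = target
        pinned.add(j)
    raise RuntimeError("coverage enforcement failed to converge")  # pragma: no cover


def segment_sequences(
    recording: Recording,
    label: int,
    n_sequences: int = DEFAULT_N_SEQUENCES,
    length: int = DEFAULT_WINDOW_LEN,
    seed: int = 0,
    role: str = "train",
) -> list[SequenceWindow]:
    """Cut a recording into ``n_sequences`` covering windows of ``length`` samples.

    Start offsets are drawn uniformly with a seeded generator, then the fewest
    windows necessary are re-positioned so every sample index of the recording
    belongs to at least one window.  All windows carry the recording's label
    and subject id.
    """
    n = recording.n_samples
    if n < length:
        raise ValueError(
            f"recording of {n} samples is shorter than the window length {length}"
        )
    if n_sequences * length < n:
        raise ValueError(
            f"{n_sequences} windows of {length} samples cannot cover {n} samples"
        )
    rng = np.random.default_rng(seed)
    if n == length:
        offsets = np.zeros(n_sequences, dtype=int)
    else:
        offsets = rng.integers(0, n - length + 1, size=n_sequences)
        offsets = _enforce_coverage(offsets, length, n)
    mat = recording.channel_matrix().astype(np.float32)
    sid = recording.subject.subject_id if recording.subject else ""
    return [
        SequenceWindow(
            values=mat[:, o: o + length].copy(),
            label=label,
            subject_id=sid,
            source_offset=int(o),
            role=role,
        )
        for o in offsets
    ]


def one_hot(labels, n_classes: int) -> np.ndarray:
    """Indicator matrix, one row per label, rows summing to one."""
    labels = np.asarray(labels, dtype=int)
    if labels.size and (labels.min() < 0 or labels.max() >= n_classes):
        bad = labels[(labels < 0) | (labels >= n_classes)][0]
        raise ValueError(f"label {bad} out of range for {n_classes} classes")
    out = np.zeros((labels.size, n_classes))
    out[np.arange(labels.size), labels] = 1.0
    return out


def identity_class_map() -> dict[str, str]:
    """The 13-class map: every classifier kind keeps its own name."""
    return {k: k for k in CLASSIFIER_KINDS}


def reduced_class_map() -> dict[str, str]:
    """The 13-to-4 reduction: all ten acoustic classes merge into 'talk'."""
    m = {}
    for k in CLASSIFIER_KINDS:
        if k.startswith(("pinyin", "vowel")):
            m[k] = "talk"
        else:
            m[k] = k
    return m


def assemble_dataset(
    cohort: dict[str, list[Recording]],
    class_map: dict[str, str],
    split_rule: dict[str, str],
    n_sequences: int = DEFAULT_N_SEQUENCES,
    length: int = DEFAULT_WINDOW_LEN,
    seed: int = 0,
) -> Dataset:
    """Normalize, window and split a cohort into a training-ready Dataset.

    ``class_map`` maps event kinds to class names and may merge classes (the
    13-to-4 reduction).  ``split_rule`` maps subject ids to "train"/"test";
    a subject's windows appear in exactly one split.  For train subjects with
    more than one recording per class, the last repetition is held out
    (role "heldout") for within-subject evaluation.
    """
    missing = set(cohort) - set(split_rule)
    if missing:
        raise ValueError(f"split_rule misses subjects: {sorted(missing)}")
    bad = {s: v for s, v in split_rule.items() if v not in ("train", "test")}
    if bad:
        raise ValueError(f"split_rule values must be 'train' or 'test': {bad}")
    if "test" not in split_rule.values():
        raise ValueError("the test split must be non-empty")

    class_names: list[str] = []
    for name in class_map.values():
        if name not in class_names:
            class_names.append(name)
    name_to_idx = {c: i for i, c in enumerate(class_names)}

    rng = np.random.default_rng(seed)
    windows: list[SequenceWindow] = []
    for sid in sorted(cohort):
        side = split_rule[sid]
        by_class: dict[str, list[Recording]] = {}
        for rec in cohort[sid]:
            kind = recording_label(rec)
            if kind not in class_map:
                raise ValueError(f"recording kind {kind!r} missing from class_map")
            by_class.setdefault(kind, []).append(rec)
        for kind, recs in by_class.items():
            label = name_to_idx[class_map[kind]]
            for r_i, rec in enumerate(recs):
                if side == "test":
                    role = "test"
                elif len(recs) > 1 and r_i == len(recs) - 1:
                    role = "heldout"
                else:
                    role = "train"
                windows.extend(
                    segment_sequences(
                        normalize(rec),
                        label,
                        n_sequences=n_sequences,
                        length=length,
                        seed=int(rng.integers(0, 2**31 - 1)),
                        role=role,
                    )
                )
    return Dataset(
        windows=windows,
        n_classes=len(class_names),
        class_names=class_names,
        split=dict(split_rule),
        params={"n_sequences": n_sequences, "length": length, "seed": seed},
    )


def default_split(cohort: dict[str, list[Recording]], n_test: int = 2) -> dict[str, str]:
    """Hold out the last ``n_test`` subjects (sorted by id) as the test split."""
    sids = sorted(cohort)
    if n_test < 1 or n_test >= len(sids):
        raise ValueError("n_test must leave at least one training subject")
    return {s: ("test" if s in sids[-n_test:] else "train") for s in sids}
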