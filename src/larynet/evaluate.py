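"""Quantitative evaluation: confusion matrices, protocols, t-SNE diagnostics.

Four protocols mirror how a laryngeal monitoring model is stressed in
practice: windows from the training subjects' held-back recordings
(``within_subject``), untouched subjects with and without head adaptation
(``new_subject_zero_shot`` / ``new_subject_adapted``), and held-back windows
contaminated with chewing/nodding/choking motion artifacts
(``artifact_noise``).
"""

from __future__ import annotations

from dataclasses import dataclass
import json

import numpy as np

from . import synth
from .model import SFEResults
from .preprocess import Dataset

PROTOCOLS = (
    "within_subject",
    "new_subject_zero_shot",
    "new_subject_adapted",
    "artifact_noise",
)


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # K x K, rows = true, columns = predicted
    class_names: list[str]

    def __post_init__(self) -> None:
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if np.any(self.counts < 0):
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def overall_accuracy(self) -> float:
        return float(np.trace(self.counts) / max(self.total, 1))

    @property
    def per_class_accuracy(self) -> np.ndarray:
        row = self.counts.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(row > 0, np.diag(self.counts) / row, np.nan)

    def to_csv(self) -> str:
        header = "true\\pred," + ",".join(self.class_names)
        lines = [header]
        for name, row in zip(self.class_names, self.counts):
            lines.append(name + "," + ",".join(str(int(v)) for v in row))
        return "\n".join(lines) + "\n"


def confusion_matrix(
    true_labels, predicted_labels, n_classes: int, class_names=None
) -> ConfusionMatrix:
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if t.shape != p.shape:
        raise ValueError("true and predicted label vectors must align")
    if t.size and (t.min() < 0 or t.max() >= n_classes or p.min() < 0
                   or p.max() >= n_classes):
        raise ValueError("labels out of range")
    counts = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(counts, (t, p), 1)
    names = list(class_names) if class_names else [str(i) for i in range(n_classes)]
    return ConfusionMatrix(counts=counts, class_names=names)


def tsne_embed(
    feature_vectors: np.ndarray, seed: int = 0, perplexity: float = 30.0
) -> np.ndarray:
    """Seeded 2-D t-SNE embedding of feature vectors (for cluster diagnostics)."""
    from sklearn.manifold import TSNE

    X = np.asarray(feature_vectors, dtype=float)
    if X.shape[0] <= 3 * perplexity:
        raise ValueError(
            f"t-SNE needs n > 3 * perplexity; got n = {X.shape[0]}, "
            f"perplexity = {perplexity}"
        )
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed,
        init="pca",
        method="exact" if X.shape[0] < 600 else "barnes_hut",
    )
    return tsne.fit_transform(X)


def silhouette(embedding: np.ndarray, labels: np.ndarray) -> float:
    from sklearn.metrics import silhouette_score

    return float(silhouette_score(embedding, labels))


@dataclass
class EvaluationReport:
    overall_accuracy: float
    per_class_accuracy: np.ndarray
    confusion: ConfusionMatrix
    protocol: str
    n_windows: int
    embedding_2d: np.ndarray | None = None

    def to_text(self) -> str:
        lines = [
            f"protocol: {self.protocol}",
            f"windows evaluated: {self.n_windows}",
            f"overall accuracy: {self.overall_accuracy:.4f}",
            "per-class accuracy:",
        ]
        for name, acc in zip(self.confusion.class_names, self.per_class_accuracy):
            lines.append(f"  {name}: {acc:.4f}" if np.isfinite(acc) else
                         f"  {name}: n/a")
        lines.append("confusion matrix (rows true, cols predicted):")
        lines.append(self.confusion.to_csv().rstrip())
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        return json.dumps(
            {
                "protocol": self.protocol,
                "n_windows": self.n_windows,
                "overall_accuracy": self.overall_accuracy,
                "per_class_accuracy": [
                    None if not np.isfinite(a) else float(a)
                    for a in self.per_class_accuracy
                ],
                "class_names": self.confusion.class_names,
                "confusion": self.confusion.counts.tolist(),
            },
            indent=2,
            sort_keys=True,
        )


def _report(results: SFEResults, X, y, protocol: str,
            with_embedding: bool, seed: int) -> EvaluationReport:
    emb, _, pred = results.predict(X)
    cm = confusion_matrix(y, pred, results.model.dataset.n_classes,
                         results.model.dataset.class_names)
    embedding = None
    if with_embedding and len(X) > 3 * 30:
        embedding = tsne_embed(emb, seed=seed)
    return EvaluationReport(
        overall_accuracy=cm.overall_accuracy,
        per_class_accuracy=cm.per_class_accuracy,
        confusion=cm,
        protocol=protocol,
        n_windows=len(X),
        embedding_2d=embedding,
    )


def _inject_artifacts(
    X: np.ndarray, intensity: float, fs: float, seed: int
) -> np.ndarray:
    """Add chew/nod/choke contamination to normalized windows.

    Artifact acceleration deltas are synthesized in g, scaled to each
    window's per-channel standard deviation (the windows are z-scored), and
    multiplied by ``intensity``; intensity 0 returns the input unchanged.
    """
    if intensity == 0.0:
        return X
    rng = np.random.default_rng(seed)
    out = X.copy()
    kinds = list(synth.ARTIFACT_KINDS)
    profile = synth.SubjectProfile(subject_id="artifact")
    length = X.shape[2]
    duration = length / fs
    for i in range(len(out)):
        kind = kinds[int(rng.integers(len(kinds)))]
        accel, _ = synth.synthesize_event(
            kind, fs, duration, 1.0, profile, int(rng.integers(0, 2**31 - 1))
        )
        accel = accel[:, :length]
        peak = np.abs(accel).max()
        if peak > 0:
            sd = out[i, :3].std(axis=1, keepdims=True)
            out[i, :3] += (intensity * accel / peak * sd).astype(out.dtype)
    return out


def evaluate_protocol(
    results: SFEResults,
    protocol: str,
    seed: int = 0,
    artifact_intensity: float = 1.0,
    adapt_epochs: int = 20,
    adapt_fraction: float = 0.5,
    fs: float = synth.DEFAULT_FS,
    with_embedding: bool = False,
) -> EvaluationReport:
    """Evaluate a fitted model under one of the four protocols."""
    if protocol not in PROTOCOLS:
        raise ValueError(f"unknown protocol {protocol!r}; valid: {PROTOCOLS}")
    ds: Dataset = results.model.dataset
    if protocol in ("within_subject", "artifact_noise"):
        X, y, _ = ds.tensors("heldout")
        if len(X) == 0:
            raise ValueError(
                "no held-out recordings from training subjects; synthesize the "
                "cohort with reps_per_class >= 2"
            )
        if protocol == "artifact_noise":
            X = _inject_artifacts(X, artifact_intensity, fs, seed)
        return _report(results, X, y, protocol, with_embedding, seed)

    X, y, subj = ds.tensors("test")
    if len(X) == 0:
        raise ValueError("no held-out test subjects in the dataset")
    if protocol == "new_subject_zero_shot":
        return _report(results, X, y, protocol, with_embedding, seed)

    # new_subject_adapted: split each test subject's windows into an
    # adaptation half and an evaluation half, stratified by class
    rng = np.random.default_rng(seed)
    adapt_idx, eval_idx = [], []
    for s in np.unique(subj):
        for c in np.unique(y):
            idx = np.flatnonzero((subj == s) & (y == c))
            idx = idx[rng.permutation(idx.size)]
            k = max(1, int(round(adapt_fraction * idx.size)))
            adapt_idx.extend(idx[:k])
            eval_idx.extend(idx[k:])
    adapt_idx = np.array(sorted(adapt_idx), dtype=int)
    eval_idx = np.array(sorted(eval_idx), dtype=int)
    if eval_idx.size == 0:
        raise ValueError("adapt_fraction leaves no windows for evaluation")
    adapted = results.adapt(X[adapt_idx], y[adapt_idx], epochs_adapt=adapt_epochs,
                            seed=seed)
    return _report(adapted, X[eval_idx], y[eval_idx], "new_subject_adapted",
                   with_embedding, seed)
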