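"""Evaluation utilities: stratified k-fold CV, scene-wide classification
maps, and t-SNE embedding export for before/after-adaptation visualization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE
from sklearn.model_selection import KFold, StratifiedKFold

from .adapt import TrainConfig, train_source
from .errors import ValidationError
from .models import Classifier, Embedding, predict_labels
from .msio import LabelMask, MultispectralScene, PatchSet, extract_patches


@dataclass
class EvalReport:
    """Per-fold accuracies with pooled confusion matrix and scenario metadata."""

    fold_accuracies: list[float]
    confusion: np.ndarray  # rows = true class, columns = predicted
    metadata: dict = field(default_factory=dict)

    @property
    def mean(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def sd(self) -> float:
        return float(np.std(self.fold_accuracies, ddof=1)) if len(self.fold_accuracies) > 1 else 0.0

    @property
    def accuracy(self) -> float:
        """Overall accuracy pooled over folds: trace(confusion)/n."""
        return float(np.trace(self.confusion) / self.confusion.sum())

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "fold_accuracies": self.fold_accuracies, "mean": self.mean, "sd": self.sd,
            "confusion": self.confusion.tolist(), "metadata": self.metadata,
        }, indent=2))

    def to_frame(self) -> pd.DataFrame:
        rows = [{"fold": i + 1, "accuracy": a} for i, a in enumerate(self.fold_accuracies)]
        rows.append({"fold": "mean", "accuracy": self.mean})
        rows.append({"fold": "sd", "accuracy": self.sd})
        return pd.DataFrame(rows)


def kfold_split(labels: np.ndarray, k: int, seed: int | None = 0,
                class_names: tuple[str, ...] | None = None,
                stratify: bool = True) -> list[np.ndarray]:
    """k-fold test index sets: disjoint, exhaustive, stratified by class.

    With stratification, per-class sizes differ by at most one across folds
    and a class with fewer than k samples is a named error. ``stratify=False``
    gives a plain shuffled partition (needed e.g. for leave-one-out).
    """
    labels = np.asarray(labels, dtype=np.int64)
    n = len(labels)
    if k < 2:
        raise ValidationError("k must be >= 2")
    if n < k:
        raise ValidationError(f"cannot split {n} samples into {k} folds")
    if not stratify:
        kf = KFold(n_splits=k, shuffle=True, random_state=seed)
        return [test for _, test in kf.split(np.zeros(n))]
    counts = np.bincount(labels)
    short = np.nonzero((counts > 0) & (counts < k))[0]
    if short.size:
        cls = short[0]
        name = class_names[cls] if class_names and cls < len(class_names) else str(cls)
        raise ValidationError(f"class '{name}' has {counts[cls]} samples, fewer than k={k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros(n), labels)]


def kfold_cv(patches: PatchSet, k: int = 3, config: TrainConfig | None = None) -> EvalReport:
    """k-fold cross-validation of the source model within one labeled region.

    Trains a fresh embedding+classifier per fold and evaluates on the
    held-out part, so every sample is tested exactly once.
    """
    if patches.labels is None:
        raise ValidationError("kfold_cv needs a labeled PatchSet")
    config = config or TrainConfig()
    n_classes = len(patches.class_names)
    counts = np.bincount(patches.labels, minlength=n_classes)
    if counts[counts > 0].min() < k:
        # stratification impossible (e.g. leave-one-out); fall back to plain folds
        import warnings

        warnings.warn(f"cannot stratify {len(patches)} samples into {k} folds; "
                      "using unstratified folds", stacklevel=2)
        folds = kfold_split(patches.labels, k, config.seed, stratify=False)
    else:
        folds = kfold_split(patches.labels, k, config.seed, patches.class_names)
    confusion = np.zeros((n_classes, n_classes), dtype=np.int64)
    fold_acc = []
    all_idx = np.arange(len(patches))
    for test_idx in folds:
        train_idx = np.setdiff1d(all_idx, test_idx)
        G, C, _ = train_source(patches.subset(train_idx), config, n_classes)
        pred, _ = predict_labels(G, C, patches.subset(test_idx))
        true = patches.labels[test_idx]
        fold_acc.append(float((pred == true).mean()))
        np.add.at(confusion, (true, pred), 1)
    return EvalReport(fold_acc, confusion, {"k": k, "n": len(patches), "seed": config.seed})


def classify_scene(scene: MultispectralScene, G: Embedding, C: Classifier,
                   patch_size: int = 5, batch_size: int = 4096,
                   class_names: tuple[str, ...] | None = None) -> LabelMask:
    """Predict a class for every eligible pixel of a scene.

    Eligible pixels (full patch window inside bounds, no nodata) get labels
    1..N_c; border and nodata-adjacent pixels stay 0.
    """
    ps = extract_patches(scene, None, patch_size, labeled_only=False)
    out = np.zeros(scene.shape[:2], dtype=np.int64)
    if len(ps):
        pred, _ = predict_labels(G, C, ps, batch_size)
        out[ps.centers[:, 0], ps.centers[:, 1]] = pred + 1
    names = class_names or tuple(f"class_{i + 1}" for i in range(C.n_classes))
    return LabelMask(out, names)


def tsne_export(
    G_s: Embedding, G_t: Embedding,
    source: PatchSet, target: PatchSet,
    per_class: int = 400, seed: int | None = 0, perplexity: float = 30.0,
) -> pd.DataFrame:
    """2-D t-SNE coordinates of raw and embedded samples from both domains.

    Subsamples up to ``per_class`` labeled samples per class per domain,
    then runs t-SNE twice: on flattened raw patches (P·P·B dimensions,
    200 for 5×5×8) and on the embedded representations (G_s for source
    samples, G_t for target). Returns a tidy frame with columns
    (x, y, class, domain, stage).
    """
    if source.labels is None or target.labels is None:
        raise ValidationError("tsne_export needs labeled patch sets")
    rng = np.random.default_rng(seed)

    def pick(ps: PatchSet) -> PatchSet:
        keep = []
        for cls in np.unique(ps.labels):
            members = np.nonzero(ps.labels == cls)[0]
            if members.size > per_class:
                members = rng.choice(members, size=per_class, replace=False)
            keep.append(members)
        return ps.subset(np.sort(np.concatenate(keep)))

    src, tgt = pick(source), pick(target)
    n_src, n_tgt = len(src), len(tgt)
    if n_src + n_tgt < 5:
        raise ValidationError("too few samples for t-SNE")
    raw = np.concatenate([
        src.patches.reshape(n_src, -1), tgt.patches.reshape(n_tgt, -1)])
    embedded = np.concatenate([G_s.forward(src.patches), G_t.forward(tgt.patches)])
    labels = np.concatenate([src.labels, tgt.labels])
    domains = np.array(["source"] * n_src + ["target"] * n_tgt)
    frames = []
    for stage, X in (("raw", raw), ("embedded", embedded)):
        px = min(perplexity, (len(X) - 1) / 3.0)
        coords = TSNE(n_components=2, random_state=seed, perplexity=px,
                      init="pca").fit_transform(X)
        frames.append(pd.DataFrame({
            "x": coords[:, 0], "y": coords[:, 1],
            "class": labels, "domain": domains, "stage": stage,
        }))
    return pd.concat(frames, ignore_index=True)


def discriminator_accuracy(D, G_s: Embedding, G_t: Embedding,
                           source: PatchSet, target: PatchSet) -> float:
    """Balanced-batch accuracy of D at telling source from target embeddings."""
    n = min(len(source), len(target))
    ps = D.forward(G_s.forward(source.patches[:n]))
    pt = D.forward(G_t.forward(target.patches[:n]))
    return float(((ps >= 0.5).sum() + (pt < 0.5).sum()) / (2 * n))
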