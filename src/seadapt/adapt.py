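"""Training procedures of the two-step semi-supervised adaptation method.

The pipeline is:

1. ``train_source`` — supervised training of the source embedding G_s and
   classifier C_s on labeled source patches (classification loss).
2. ``adapt_marginal`` — unsupervised adversarial alignment: a discriminator D
   learns to separate source embeddings (label 1) from target embeddings
   (label 0) while the target embedding G_t (initialized from G_s, with G_s
   frozen) learns to fool it. Alternation is one D step then one G_t step per
   batch.
3. ``sample_pairs`` + ``adapt_conditional`` — few-shot contrastive semantic
   alignment: each labeled target "shot" is paired with a per-class pool of
   source samples; the joint objective combines the target and source
   classification losses with the semantic-alignment (same-class pull) and
   class-separation (different-class hinge push) terms, with gradients
   flowing into both G_s and G_t (the joint optimization can be ablated with
   ``joint=False``).

``run_two_step`` wires the stages together and also exposes the single-step
baselines (source-only, adversarial-only, fine-tuning, contrastive-only);
``run_benchmark`` runs the scenario × method × shot grid with replicates.

All randomness is drawn from generators derived from ``TrainConfig.seed``;
with a fixed thread count every procedure is bit-deterministic.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import losses
from ._nn import Adam, softmax
from .errors import ConfigurationError, ValidationError
from .models import (
    Classifier,
    Discriminator,
    Embedding,
    ModelSuite,
    build_classifier,
    build_discriminator,
    build_embedding,
    predict_labels,
)
from .msio import LabelMask, MultispectralScene, PatchSet, extract_patches
from .synthdata import BenchmarkScenario, generate_scene_pair

METHODS = ("source-only", "adda", "finetune", "ccsa", "proposed")


@dataclass
class TrainConfig:
    """Hyperparameters of the full pipeline.

    Defaults are the method's reference operating point: 50 source epochs, 300
    adversarial epochs, 240 contrastive epochs, batch size 128, learning rate
    2e-4, margin 1, and 400 source samples per class in the pairing pools.
    ``scaled`` produces a proportionally shortened schedule for small
    synthetic problems.
    """

    source_epochs: int = 50
    batch_size: int = 128
    adversarial_epochs: int = 300
    ccsa_epochs: int = 240
    learning_rate: float = 2e-4
    margin: float = 1.0
    pairs_per_class: int = 400
    shots: int = 1
    seed: int = 0
    loss_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    patch_size: int = 5
    normalize: bool = True
    joint: bool = True
    update_source_classifier: bool = True
    squared_distance: bool = False
    max_pair_batches: int | None = None
    reps: int = 3
    adversarial_beta1: float = 0.5  # first-moment decay for the minimax stage

    def __post_init__(self) -> None:
        for name in ("source_epochs", "batch_size", "ccsa_epochs", "pairs_per_class", "reps"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be positive")
        if self.adversarial_epochs < 0:
            raise ConfigurationError("adversarial_epochs must be >= 0")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be positive")
        if self.margin < 0:
            raise ConfigurationError("margin must be non-negative")
        if self.shots < 1:
            raise ConfigurationError("shots must be >= 1")
        self.loss_weights = tuple(float(w) for w in self.loss_weights)

    def scaled(self, factor: float) -> "TrainConfig":
        """Schedule shortened by ``factor`` (epoch counts divided, floor 1)."""
        return replace(
            self,
            source_epochs=max(1, round(self.source_epochs / factor)),
            adversarial_epochs=max(0, round(self.adversarial_epochs / factor)),
            ccsa_epochs=max(1, round(self.ccsa_epochs / factor)),
        )

    def to_dict(self) -> dict:
        return {
            "source_epochs": self.source_epochs, "batch_size": self.batch_size,
            "adversarial_epochs": self.adversarial_epochs, "ccsa_epochs": self.ccsa_epochs,
            "learning_rate": self.learning_rate, "margin": self.margin,
            "pairs_per_class": self.pairs_per_class, "shots": self.shots,
            "seed": self.seed, "loss_weights": list(self.loss_weights),
            "patch_size": self.patch_size, "normalize": self.normalize,
            "joint": self.joint, "update_source_classifier": self.update_source_classifier,
            "squared_distance": self.squared_distance,
            "max_pair_batches": self.max_pair_batches, "reps": self.reps,
            "adversarial_beta1": self.adversarial_beta1,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "TrainConfig":
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        unknown = set(data) - set(known)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "loss_weights" in known:
            known["loss_weights"] = tuple(known["loss_weights"])
        return cls(**known)

    @classmethod
    def from_file(cls, path: str | Path) -> "TrainConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls.from_dict(data or {})


@dataclass
class PairSet:
    """Cross-domain sample pairs (source index, target-shot index).

    Positives pair a target shot with drawn source samples of its own class;
    negatives pair it with the drawn samples of every other class. ``pools``
    records the per-class source indices actually drawn.
    """

    positives: np.ndarray  # (N_p, 2) int: columns (source index, target index)
    negatives: np.ndarray  # (N_n, 2)
    pools: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positives = np.asarray(self.positives, dtype=np.int64).reshape(-1, 2)
        self.negatives = np.asarray(self.negatives, dtype=np.int64).reshape(-1, 2)

    def __len__(self) -> int:
        return len(self.positives) + len(self.negatives)


@dataclass
class AdaptationResult:
    """Trained models plus per-epoch loss traces and the protocol record."""

    suite: ModelSuite
    history: dict[str, list[float]]
    config: TrainConfig
    method: str = "proposed"
    target_accuracy: float | None = None
    n_eval: int = 0
    shot_indices: np.ndarray | None = None
    seeds: dict[str, int] = field(default_factory=dict)


def _rng(config: TrainConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


def _require_all_classes(labels: np.ndarray, n_classes: int, where: str) -> None:
    counts = np.bincount(labels, minlength=n_classes)
    missing = np.nonzero(counts == 0)[0]
    if missing.size:
        raise ValidationError(f"{where}: no samples for class index {missing[0]}")


def _class_forward_backward(
    G: Embedding, C: Classifier, x: np.ndarray, y: np.ndarray, weight: float = 1.0
) -> float:
    """Accumulate classification-loss gradients into G and C; return the loss."""
    emb = G.forward(x)
    logits = C.net.forward(emb)
    probs = softmax(logits)
    loss = losses.classification_loss(probs, y)
    dlogits = probs.copy()
    dlogits[np.arange(len(y)), y] -= 1.0
    dlogits *= weight / len(y)
    demb = C.net.backward(dlogits)
    G.backward(demb)
    return loss


def _accuracy(G: Embedding, C: Classifier, patches: PatchSet) -> float:
    pred, _ = predict_labels(G, C, patches)
    return float((pred == patches.labels).mean())


# ---------------------------------------------------------------------------
# Stage 1: supervised source training
# ---------------------------------------------------------------------------

def train_source(
    patches: PatchSet, config: TrainConfig, n_classes: int | None = None
) -> tuple[Embedding, Classifier, dict]:
    """Train G_s and C_s on labeled source patches by mini-batch descent."""
    if patches.labels is None or len(patches) == 0:
        raise ValidationError("train_source needs a labeled, non-empty PatchSet")
    n_classes = n_classes or len(patches.class_names)
    _require_all_classes(patches.labels, n_classes, "train_source")
    rng = _rng(config, 0)
    G = build_embedding(patches.patches.shape[3], patches.patch_size,
                        seed=int(rng.integers(2**31)))
    G.set_normalization(patches.patches, enabled=config.normalize)
    C = build_classifier(G.embed_dim, n_classes, seed=int(rng.integers(2**31)))
    opt = Adam(G.net.params() + C.net.params(), lr=config.learning_rate)
    n = len(patches)
    trace: list[float] = []
    for _ in range(config.source_epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            G.net.zero_grad()
            C.net.zero_grad()
            loss = _class_forward_backward(G, C, patches.patches[idx], patches.labels[idx])
            opt.step()
            epoch_losses.append(loss)
        trace.append(float(np.mean(epoch_losses)))
    history = {"classification": trace, "train_accuracy": _accuracy(G, C, patches)}
    return G, C, history


# ---------------------------------------------------------------------------
# Stage 2: unsupervised adversarial alignment
# ---------------------------------------------------------------------------

def adapt_marginal(
    G_s: Embedding,
    source_patches: PatchSet,
    target_patches: PatchSet,
    config: TrainConfig,
) -> tuple[Embedding, Discriminator, dict]:
    """Adversarially align target embeddings with frozen source embeddings.

    G_t starts as a copy of G_s. Per batch: one discriminator update on the
    binary cross-entropy with source embeddings labeled 1 and target
    embeddings labeled 0, then one generator update of G_t on
    −E[log D(G_t(x_t))]. G_s is never modified. Labels are never read.
    """
    if len(source_patches) == 0 or len(target_patches) == 0:
        raise ValidationError("both domains must be non-empty for adversarial adaptation")
    rng = _rng(config, 1)
    G_t = G_s.copy()
    D = build_discriminator(G_s.embed_dim, seed=int(rng.integers(2**31)))
    opt_d = Adam(D.net.params(), lr=config.learning_rate, beta1=config.adversarial_beta1)
    opt_g = Adam(G_t.net.params(), lr=config.learning_rate, beta1=config.adversarial_beta1)
    xs, xt = source_patches.patches, target_patches.patches
    n_batches = max(len(xs), len(xt)) // config.batch_size or 1
    d_trace: list[float] = []
    g_trace: list[float] = []
    for _ in range(config.adversarial_epochs):
        src_order = rng.permutation(len(xs))
        tgt_order = rng.permutation(len(xt))
        d_losses, g_losses = [], []
        for b in range(n_batches):
            si = src_order[(b * config.batch_size) % len(xs):][: config.batch_size]
            ti = tgt_order[(b * config.batch_size) % len(xt):][: config.batch_size]
            if len(si) == 0 or len(ti) == 0:
                continue
            # discriminator step (G_s and G_t fixed)
            es = G_s.forward(xs[si])
            et = G_t.forward(xt[ti])
            D.net.zero_grad()
            zs = D.net.forward(es)[:, 0]
            ps = 1.0 / (1.0 + np.exp(-zs))
            d_loss_s = -np.log(np.maximum(ps, losses.EPS)).mean()
            dz_s = ((ps - 1.0) / len(ps))[:, None]
            D.net.backward(dz_s)
            zt = D.net.forward(et)[:, 0]
            pt = 1.0 / (1.0 + np.exp(-zt))
            d_loss_t = -np.log(np.maximum(1.0 - pt, losses.EPS)).mean()
            dz_t = (pt / len(pt))[:, None]
            D.net.backward(dz_t)
            opt_d.step()
            d_losses.append(d_loss_s + d_loss_t)
            # generator step (D fixed; its gradients are discarded)
            G_t.net.zero_grad()
            et = G_t.forward(xt[ti])
            D.net.zero_grad()
            zt = D.net.forward(et)[:, 0]
            pt = 1.0 / (1.0 + np.exp(-zt))
            g_losses.append(-np.log(np.maximum(pt, losses.EPS)).mean())
            demb = D.net.backward(((pt - 1.0) / len(pt))[:, None])
            D.net.zero_grad()
            G_t.net.backward(demb)
            opt_g.step()
        d_trace.append(float(np.mean(d_losses)) if d_losses else float("nan"))
        g_trace.append(float(np.mean(g_losses)) if g_losses else float("nan"))
    return G_t, D, {"discriminator": d_trace, "generator": g_trace}


# ---------------------------------------------------------------------------
# Stage 3: pair construction + few-shot contrastive alignment
# ---------------------------------------------------------------------------

def sample_pairs(
    source: PatchSet,
    target_shots: PatchSet,
    pairs_per_class: int = 400,
    seed: int | None = 0,
) -> PairSet:
    """Draw per-class source pools and pair every target shot with them.

    For each class present in the target shots, ``pairs_per_class`` source
    samples of that class are drawn (without replacement when the pool
    suffices, otherwise with replacement and a warning). Each target shot is
    then paired positively with every drawn sample of its own class and
    negatively with every drawn sample of every other class.
    """
    if source.labels is None or target_shots.labels is None:
        raise ValidationError("sample_pairs needs labeled source and target sets")
    if len(target_shots) == 0:
        raise ValidationError("no target shots given")
    rng = np.random.default_rng(seed)
    src_classes = np.unique(source.labels)
    pools: dict[int, np.ndarray] = {}
    for cls in np.unique(np.concatenate([source.labels, target_shots.labels])):
        members = np.nonzero(source.labels == cls)[0]
        if members.size == 0:
            raise ValidationError(f"class index {cls} present in target shots but absent in source")
        if members.size < pairs_per_class:
            warnings.warn(
                f"class index {cls}: only {members.size} source samples for "
                f"{pairs_per_class} pairs per class; drawing with replacement",
                stacklevel=2,
            )
            pools[int(cls)] = rng.choice(members, size=pairs_per_class, replace=True)
        else:
            pools[int(cls)] = rng.choice(members, size=pairs_per_class, replace=False)
    del src_classes
    positives, negatives = [], []
    for j, y in enumerate(target_shots.labels):
        for cls, pool in pools.items():
            pairs = np.stack([pool, np.full(len(pool), j, dtype=np.int64)], axis=1)
            (positives if cls == int(y) else negatives).append(pairs)
    return PairSet(np.concatenate(positives), np.concatenate(negatives), pools)


def _pair_gradients(
    es: np.ndarray, et: np.ndarray, positive: np.ndarray,
    margin: float, squared: bool, w_sa: float, w_cs: float,
) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Mean SA loss over positive rows, mean CS loss over negative rows,
    and gradients w.r.t. the source/target embedding rows."""
    diff = es - et
    norm = np.linalg.norm(diff, axis=1)
    des = np.zeros_like(es)
    n_pos = int(positive.sum())
    n_neg = len(positive) - n_pos
    sa = cs = 0.0
    if n_pos:
        d_pos = norm[positive]
        if squared:
            sa = float(0.5 * (d_pos**2).mean())
            des[positive] = diff[positive] / n_pos
        else:
            sa = float(0.5 * d_pos.mean())
            safe = np.maximum(d_pos, 1e-12)
            des[positive] = diff[positive] / (2.0 * safe * n_pos)[:, None]
        des[positive] *= w_sa
    if n_neg:
        neg = ~positive
        d_neg = norm[neg]
        gap = np.maximum(0.0, margin - d_neg)
        cs = float(0.5 * (gap**2).mean())
        safe = np.maximum(d_neg, 1e-12)
        des[neg] = (-gap / (safe * n_neg))[:, None] * diff[neg] * w_cs
    return sa, cs, des, -des


def adapt_conditional(
    G_s: Embedding,
    G_t: Embedding,
    C_s: Classifier,
    source: PatchSet,
    target_shots: PatchSet,
    pairs: PairSet,
    config: TrainConfig,
    epoch_callback=None,
) -> tuple[Embedding, Embedding, Classifier, dict]:
    """Jointly adapt G_s and G_t with the combined CCSA objective.

    Per pair mini-batch the loss is the target classification loss of
    G_t∘C_t on the shots, the source classification loss of G_s∘C_s on the
    drawn source pools, the mean semantic-alignment term over the batch's
    positive pairs and the mean class-separation term over its negative
    pairs. C_t starts from C_s. With ``config.joint=False`` the source side
    (G_s, C_s) is frozen, which is the "no joint optimization" ablation.
    Inputs are not mutated; updated copies are returned.
    """
    if len(pairs) == 0:
        raise ValidationError("empty PairSet")
    if target_shots.labels is None or source.labels is None:
        raise ValidationError("adapt_conditional needs labeled sets")
    rng = _rng(config, 3)
    G_s = G_s.copy() if config.joint else G_s
    G_t = G_t.copy()
    C_s = C_s.copy() if (config.joint and config.update_source_classifier) else C_s
    C_t = C_s.copy()
    trained = G_t.net.params() + C_t.net.params()
    if config.joint:
        trained += G_s.net.params()
        if config.update_source_classifier:
            trained += C_s.net.params()
    opt = Adam(trained, lr=config.learning_rate)
    w_c, w_sa, w_cs = config.loss_weights
    all_pairs = np.concatenate([pairs.positives, pairs.negatives])
    is_positive = np.concatenate([
        np.ones(len(pairs.positives), dtype=bool),
        np.zeros(len(pairs.negatives), dtype=bool),
    ])
    src_pool = np.unique(np.concatenate([p for p in pairs.pools.values()]))
    shots_x, shots_y = target_shots.patches, target_shots.labels
    history: dict[str, list[float]] = {k: [] for k in
                                       ("target_classification", "source_classification",
                                        "semantic_alignment", "class_separation")}
    n_batches_all = (len(all_pairs) + config.batch_size - 1) // config.batch_size
    n_batches = min(n_batches_all, config.max_pair_batches or n_batches_all)
    for _ in range(config.ccsa_epochs):
        order = rng.permutation(len(all_pairs))
        sums = np.zeros(4)
        for b in range(n_batches):
            idx = order[b * config.batch_size : (b + 1) * config.batch_size]
            batch, pos = all_pairs[idx], is_positive[idx]
            for net in (G_s, G_t):
                net.net.zero_grad()
            for net in (C_s, C_t):
                net.net.zero_grad()
            loss_t = _class_forward_backward(G_t, C_t, shots_x, shots_y, weight=w_c)
            src_idx = rng.choice(src_pool, size=min(config.batch_size, len(src_pool)),
                                 replace=False)
            loss_s = _class_forward_backward(
                G_s, C_s, source.patches[src_idx], source.labels[src_idx], weight=w_c)
            es = G_s.forward(source.patches[batch[:, 0]])
            et = G_t.forward(target_shots.patches[batch[:, 1]])
            sa, cs, des, det = _pair_gradients(
                es, et, pos, config.margin, config.squared_distance, w_sa, w_cs)
            if config.joint:
                G_s.backward(des)
            G_t.backward(det)
            opt.step()
            sums += (loss_t, loss_s, sa, cs)
        means = sums / n_batches
        for key, val in zip(history, means):
            history[key].append(float(val))
        if epoch_callback is not None:
            epoch_callback(len(history["semantic_alignment"]) - 1, G_t, C_t)
    return G_s, G_t, C_t, history


# ---------------------------------------------------------------------------
# Stage 4: end-to-end protocol and baselines
# ---------------------------------------------------------------------------

def select_shots(patches: PatchSet, n: int, seed: int | None,
                 n_classes: int | None = None) -> np.ndarray:
    """Indices of n labeled samples per class, drawn uniformly at random."""
    if patches.labels is None:
        raise ValidationError("select_shots needs a labeled PatchSet")
    n_classes = n_classes or len(patches.class_names)
    rng = np.random.default_rng(seed)
    picks = []
    for cls in range(n_classes):
        members = np.nonzero(patches.labels == cls)[0]
        if members.size < n:
            name = patches.class_names[cls] if cls < len(patches.class_names) else str(cls)
            raise ValidationError(
                f"class '{name}': only {members.size} labeled target samples for {n} shots")
        picks.append(rng.choice(members, size=n, replace=False))
    return np.concatenate(picks)


def _finetune(G_s: Embedding, C_s: Classifier, shots: PatchSet,
              config: TrainConfig) -> tuple[Embedding, Classifier, dict]:
    """Transfer-learning baseline: continue training the source model on the shots."""
    G, C = G_s.copy(), C_s.copy()
    opt = Adam(G.net.params() + C.net.params(), lr=config.learning_rate)
    rng = _rng(config, 6)
    trace = []
    for _ in range(config.ccsa_epochs):
        order = rng.permutation(len(shots))
        epoch = []
        for start in range(0, len(shots), config.batch_size):
            idx = order[start : start + config.batch_size]
            G.net.zero_grad()
            C.net.zero_grad()
            epoch.append(_class_forward_backward(G, C, shots.patches[idx], shots.labels[idx]))
            opt.step()
        trace.append(float(np.mean(epoch)))
    return G, C, {"classification": trace}


@dataclass
class ScenarioData:
    """Patch sets prepared once per (source, target) scene pair."""

    source_labeled: PatchSet
    target_labeled: PatchSet
    source_unlabeled: PatchSet
    target_unlabeled: PatchSet
    n_classes: int


def prepare_scenario(
    source_scene: MultispectralScene, source_mask: LabelMask,
    target_scene: MultispectralScene, target_mask: LabelMask,
    config: TrainConfig,
    max_per_class: int | None = None,
    max_unlabeled: int | None = None,
    seed: int | None = 0,
) -> ScenarioData:
    """Extract and (optionally) subsample the patch sets used by every method.

    ``target_unlabeled`` patches carry no labels and are the only target data
    the adversarial step sees.
    """
    rng = np.random.default_rng(seed)
    src = extract_patches(source_scene, source_mask, config.patch_size, labeled_only=True)
    tgt = extract_patches(target_scene, target_mask, config.patch_size, labeled_only=True)

    def cap_per_class(ps: PatchSet) -> PatchSet:
        if max_per_class is None:
            return ps
        keep = []
        for cls in np.unique(ps.labels):
            members = np.nonzero(ps.labels == cls)[0]
            if members.size > max_per_class:
                members = rng.choice(members, size=max_per_class, replace=False)
            keep.append(members)
        return ps.subset(np.sort(np.concatenate(keep)))

    src, tgt = cap_per_class(src), cap_per_class(tgt)
    src_u = extract_patches(source_scene, None, config.patch_size, labeled_only=False)
    tgt_u = extract_patches(target_scene, None, config.patch_size, labeled_only=False)

    def cap(ps: PatchSet, n: int | None) -> PatchSet:
        if n is None or len(ps) <= n:
            return ps
        return ps.subset(np.sort(rng.choice(len(ps), size=n, replace=False)))

    n_classes = max(len(source_mask.class_names), int(src.labels.max()) + 1)
    return ScenarioData(src, tgt, cap(src_u, max_unlabeled), cap(tgt_u, max_unlabeled), n_classes)


def run_method(
    data: ScenarioData,
    method: str,
    config: TrainConfig,
    source_model: tuple[Embedding, Classifier, dict] | None = None,
    marginal_model: tuple[Embedding, Discriminator, dict] | None = None,
) -> AdaptationResult:
    """Run one method end to end on prepared scenario data.

    ``source_model`` and ``marginal_model`` allow reusing the (identical)
    stage-1/stage-2 results across methods and shot counts within one
    replicate. Target accuracy is measured on the labeled target patches that
    were not used as shots.
    """
    if method not in METHODS:
        raise ValidationError(f"unknown method '{method}'; expected one of {METHODS}")
    G_s, C_s, src_hist = source_model or train_source(data.source_labeled, config, data.n_classes)
    history: dict = {"source": src_hist}
    suite = ModelSuite(G_s=G_s, C_s=C_s)
    shot_idx = None
    needs_shots = method in ("finetune", "ccsa", "proposed")
    if needs_shots:
        shot_idx = select_shots(data.target_labeled, config.shots,
                                np.random.default_rng([config.seed, 4]), data.n_classes)
        shots = data.target_labeled.subset(shot_idx)
    if method == "source-only":
        G_eval, C_eval = G_s, C_s
    elif method == "adda":
        G_t, D, adv_hist = marginal_model or adapt_marginal(
            G_s, data.source_unlabeled, data.target_unlabeled, config)
        history["adversarial"] = adv_hist
        suite.G_t, suite.D = G_t, D
        G_eval, C_eval = G_t, C_s
    elif method == "finetune":
        G_eval, C_eval, ft_hist = _finetune(G_s, C_s, shots, config)
        history["finetune"] = ft_hist
        suite.G_t, suite.C_t = G_eval, C_eval
    else:  # ccsa or proposed
        if method == "proposed":
            G_t, D, adv_hist = marginal_model or adapt_marginal(
                G_s, data.source_unlabeled, data.target_unlabeled, config)
            history["adversarial"] = adv_hist
            suite.D = D
        else:
            G_t = G_s.copy()
        pairs = sample_pairs(data.source_labeled, shots, config.pairs_per_class,
                             np.random.default_rng([config.seed, 2]))
        G_s2, G_t2, C_t, ccsa_hist = adapt_conditional(
            G_s, G_t, C_s, data.source_labeled, shots, pairs, config)
        history["ccsa"] = ccsa_hist
        suite.G_s, suite.C_s = G_s2, C_s
        suite.G_t, suite.C_t = G_t2, C_t
        G_eval, C_eval = G_t2, C_t
    eval_mask = np.ones(len(data.target_labeled), dtype=bool)
    if shot_idx is not None:
        eval_mask[shot_idx] = False
    eval_set = data.target_labeled.subset(np.nonzero(eval_mask)[0])
    acc = _accuracy(G_eval, C_eval, eval_set) if len(eval_set) else float("nan")
    return AdaptationResult(
        suite=suite, history=history, config=config, method=method,
        target_accuracy=acc, n_eval=len(eval_set), shot_indices=shot_idx,
        seeds={"seed": config.seed},
    )


def run_two_step(
    source_scene: MultispectralScene, source_mask: LabelMask,
    target_scene: MultispectralScene, target_mask: LabelMask,
    shots: int, config: TrainConfig, method: str = "proposed",
    max_per_class: int | None = None, max_unlabeled: int | None = None,
) -> AdaptationResult:
    """Full protocol on a scene pair: source training, adversarial marginal
    alignment, pair sampling, and joint contrastive alignment (or one of the
    baseline methods)."""
    config = replace(config, shots=shots)
    data = prepare_scenario(source_scene, source_mask, target_scene, target_mask,
                            config, max_per_class, max_unlabeled,
                            seed=np.random.default_rng([config.seed, 5]))
    return run_method(data, method, config)


def run_benchmark(
    scenarios: dict[str, BenchmarkScenario] | Sequence[BenchmarkScenario],
    config: TrainConfig,
    methods: Sequence[str] = METHODS,
    shot_counts: Sequence[int] = (1, 5),
    reps: int | None = None,
    base_seed: int = 0,
    max_unlabeled: int = 2500,
) -> pd.DataFrame:
    """Run the scenario × method × shot grid with replicates.

    Within a replicate the source model and the adversarially adapted G_t are
    trained once and shared by all methods that use them; shots and pairing
    pools are resampled per replicate. Returns one row per run with columns
    (scenario, method, shots, rep, seed, accuracy, n_eval).
    """
    if isinstance(scenarios, dict):
        scenarios = list(scenarios.values())
    reps = reps if reps is not None else config.reps
    rows = []
    for scen in scenarios:
        src_scene, src_mask, tgt_scene, tgt_mask, _ = generate_scene_pair(scen.config)
        data = prepare_scenario(
            src_scene, src_mask, tgt_scene, tgt_mask, config,
            max_per_class=scen.max_train_per_class, max_unlabeled=max_unlabeled,
            seed=np.random.default_rng([base_seed, scen.config.seed]),
        )
        for rep in range(reps):
            rep_seed = base_seed + 1009 * rep + 17
            cfg = replace(config, seed=rep_seed)
            src_model = train_source(data.source_labeled, cfg, data.n_classes)
            marginal = None
            if any(m in methods for m in ("adda", "proposed")) and cfg.adversarial_epochs > 0:
                marginal = adapt_marginal(src_model[0], data.source_unlabeled,
                                          data.target_unlabeled, cfg)
            for method in methods:
                per_shot = shot_counts if method in ("finetune", "ccsa", "proposed") else (0,)
                for n_shot in per_shot:
                    cfg_m = replace(cfg, shots=max(1, n_shot))
                    res = run_method(data, method, cfg_m, source_model=src_model,
                                     marginal_model=marginal)
                    rows.append({
                        "scenario": scen.name, "method": method, "shots": n_shot,
                        "rep": rep, "seed": rep_seed,
                        "accuracy": res.target_accuracy, "n_eval": res.n_eval,
                    })
    return pd.DataFrame(rows)


def summarize_benchmark(results: pd.DataFrame) -> pd.DataFrame:
    """Mean ± sd accuracy per (scenario, method, shots)."""
    grouped = results.groupby(["scenario", "method", "shots"])["accuracy"]
    out = grouped.agg(mean="mean", sd="std", n_reps="count").reset_index()
    out["sd"] = out["sd"].fillna(0.0)
    return out
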