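"""Loss terms of the two-step adaptation method, as pure functions.

All losses are plain functions of arrays so they can be checked against
brute-force oracles. Conventions:

* classification loss — mean negative log-probability of the true class;
* adversarial losses — binary cross-entropy with source labeled 1 and target
  labeled 0 for the discriminator, and −E[log D(G_t(x_t))] for the generator;
* pair distance d(u, v) = ½‖u−v‖ (Euclidean, unsquared as printed; a squared
  variant is available for comparison with the contrastive-loss literature);
* pair similarity k(u, v) = ½·max(0, m−‖u−v‖)², zero beyond the margin m;
* semantic alignment — sum (or mean) of d over all same-class cross-domain
  pairs; class separation — sum (or mean) of k over all different-class
  cross-domain pairs; the combined CCSA objective is their unweighted sum
  with the classification loss.

Logs are floored at ε = 1e-12, so losses are always finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ValidationError

EPS = 1e-12


@dataclass
class CSAConfig:
    """Settings of the contrastive semantic alignment terms."""

    margin: float = 1.0
    squared_distance: bool = False
    reduction: str = "sum"  # "sum" (as written) or "mean" (batch-size invariant)

    def __post_init__(self) -> None:
        if self.margin < 0:
            raise ValidationError("margin must be non-negative")
        if self.reduction not in ("sum", "mean"):
            raise ValidationError("reduction must be 'sum' or 'mean'")


def _floored_log(x: np.ndarray) -> np.ndarray:
    return np.log(np.maximum(x, EPS))


def classification_loss(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Mean negative log-probability of the true class over the batch."""
    p = np.asarray(probabilities, dtype=np.float64)
    y = np.asarray(labels, dtype=np.int64)
    if p.ndim != 2 or len(p) != len(y):
        raise ValidationError("probabilities must be N×N_c with N matching labels")
    if len(p) == 0:
        raise ValidationError("empty batch")
    if y.min() < 0 or y.max() >= p.shape[1]:
        raise ValidationError("labels out of range")
    return float(-_floored_log(p[np.arange(len(y)), y]).mean())


def _check_unit_interval(x: np.ndarray, what: str) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64).ravel()
    if x.size and (x.min() < 0 or x.max() > 1):
        raise ValidationError(f"{what} outputs must lie in [0, 1]")
    return x


def discriminator_loss(d_source: np.ndarray, d_target: np.ndarray) -> float:
    """Binary cross-entropy of D, source labeled 1 and target labeled 0.

    Empty sides contribute nothing (their term is dropped, not NaN).
    """
    ds = _check_unit_interval(d_source, "discriminator")
    dt = _check_unit_interval(d_target, "discriminator")
    if ds.size == 0 and dt.size == 0:
        raise ValidationError("at least one domain must be non-empty")
    loss = 0.0
    if ds.size:
        loss -= float(_floored_log(ds).mean())
    if dt.size:
        loss -= float(_floored_log(1.0 - dt).mean())
    return loss


def generator_loss(d_target: np.ndarray) -> float:
    """−E[log D(G_t(x_t))]: small when the discriminator is fooled."""
    dt = _check_unit_interval(d_target, "discriminator")
    if dt.size == 0:
        raise ValidationError("empty target batch")
    return float(-_floored_log(dt).mean())


def pair_distance(u: np.ndarray, v: np.ndarray, squared: bool = False) -> float:
    """d(u, v) = ½‖u−v‖ (or ½‖u−v‖² when ``squared``)."""
    u = np.asarray(u, dtype=np.float64).ravel()
    v = np.asarray(v, dtype=np.float64).ravel()
    if u.shape != v.shape:
        raise ValidationError("embedding dimensions differ")
    n = float(np.linalg.norm(u - v))
    return 0.5 * n * n if squared else 0.5 * n


def pair_similarity(u: np.ndarray, v: np.ndarray, margin: float = 1.0) -> float:
    """k(u, v) = ½·max(0, m−‖u−v‖)²; identically 0 once ‖u−v‖ ≥ m."""
    if margin < 0:
        raise ValidationError("margin must be non-negative")
    u = np.asarray(u, dtype=np.float64).ravel()
    v = np.asarray(v, dtype=np.float64).ravel()
    if u.shape != v.shape:
        raise ValidationError("embedding dimensions differ")
    gap = margin - float(np.linalg.norm(u - v))
    return 0.5 * max(0.0, gap) ** 2


def _pairwise(src_embeds, src_labels, tgt_embeds, tgt_labels):
    es = np.atleast_2d(np.asarray(src_embeds, dtype=np.float64))
    et = np.atleast_2d(np.asarray(tgt_embeds, dtype=np.float64))
    ys = np.asarray(src_labels, dtype=np.int64)
    yt = np.asarray(tgt_labels, dtype=np.int64)
    if len(es) != len(ys) or len(et) != len(yt):
        raise ValidationError("embeddings and labels must have equal length")
    if es.shape[1] != et.shape[1]:
        raise ValidationError("embedding dimensions differ between domains")
    dist = cdist(et, es)  # (N_t, N_s) Euclidean
    same = yt[:, None] == ys[None, :]
    return dist, same


def semantic_alignment_loss(
    src_embeds, src_labels, tgt_embeds, tgt_labels,
    squared: bool = False, reduction: str = "sum",
) -> float:
    """Sum of d over every same-class cross-domain pair (target × source).

    Classes absent from either domain contribute nothing. With
    ``reduction='mean'`` the total is divided by the number of same-class
    pairs (batch-size invariant form used by the optimizer).
    """
    dist, same = _pairwise(src_embeds, src_labels, tgt_embeds, tgt_labels)
    d = 0.5 * dist[same] ** 2 if squared else 0.5 * dist[same]
    if reduction == "mean":
        return float(d.mean()) if d.size else 0.0
    return float(d.sum())


def class_separation_loss(
    src_embeds, src_labels, tgt_embeds, tgt_labels,
    margin: float = 1.0, reduction: str = "sum",
) -> float:
    """Sum of k over every different-class cross-domain pair."""
    if margin < 0:
        raise ValidationError("margin must be non-negative")
    dist, same = _pairwise(src_embeds, src_labels, tgt_embeds, tgt_labels)
    gap = np.maximum(0.0, margin - dist[~same])
    k = 0.5 * gap ** 2
    if reduction == "mean":
        return float(k.mean()) if k.size else 0.0
    return float(k.sum())


def ccsa_loss(
    classification: float, alignment: float, separation: float,
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> float:
    """Combined objective L_C + L_SA + L_CS (unit weights by default)."""
    w = weights
    return float(w[0] * classification + w[1] * alignment + w[2] * separation)
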