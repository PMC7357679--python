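"""Network definitions: embedding G, classifier C, discriminator D.

The embedding is a two-layer CNN on P×P×B patches — 20 filters of 2×2×B then
100 filters of 4×4×20, both rectified, valid (unpadded) stride-1
convolutions, flattened. With the default P=5 the spatial extent collapses to
1×1, so the embedding dimension is 100. The classifier is one hidden dense
layer of 84 rectified units and an N_c-unit softmax output. The discriminator
is one hidden dense layer of 100 rectified units with a single logistic
output giving the probability that an embedding came from the source domain.

An optional per-band standardization (mean/sd estimated from the source
training patches) is carried on the embedding and applied identically to both
domains before the first convolution.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _nn
from .errors import ConfigurationError, ValidationError
from .msio import PatchSet


@dataclass
class Embedding:
    """Embedding function G: N×P×P×B patches -> N×E vectors."""

    net: _nn.Network
    bands: int
    patch_size: int
    embed_dim: int
    band_mean: np.ndarray | None = None
    band_std: np.ndarray | None = None

    def normalize(self, patches: np.ndarray) -> np.ndarray:
        if self.band_mean is None:
            return patches
        return (patches - self.band_mean) / self.band_std

    def forward(self, patches: np.ndarray) -> np.ndarray:
        patches = np.asarray(patches, dtype=np.float64)
        if patches.ndim != 4 or patches.shape[1:] != (self.patch_size, self.patch_size, self.bands):
            raise ValidationError(
                f"expected N×{self.patch_size}×{self.patch_size}×{self.bands} patches, got {patches.shape}"
            )
        if len(patches) == 0:
            return np.empty((0, self.embed_dim))
        return self.net.forward(self.normalize(patches))

    __call__ = forward

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return self.net.backward(grad_out)

    def set_normalization(self, patches: np.ndarray, enabled: bool = True) -> None:
        """Fit per-band standardization constants from training patches."""
        if not enabled:
            self.band_mean = self.band_std = None
            return
        mean = patches.mean(axis=(0, 1, 2))
        std = patches.std(axis=(0, 1, 2))
        std = np.where(std < 1e-12, 1.0, std)
        self.band_mean, self.band_std = mean, std

    def copy(self) -> "Embedding":
        return copy.deepcopy(self)


@dataclass
class Classifier:
    """Classifier C: N×E embeddings -> N×N_c class probabilities."""

    net: _nn.Network
    embed_dim: int
    n_classes: int

    def logits(self, embeddings: np.ndarray) -> np.ndarray:
        embeddings = np.asarray(embeddings, dtype=np.float64)
        if embeddings.ndim != 2 or embeddings.shape[1] != self.embed_dim:
            raise ValidationError(f"expected N×{self.embed_dim} embeddings, got {embeddings.shape}")
        if len(embeddings) == 0:
            return np.empty((0, self.n_classes))
        return self.net.forward(embeddings)

    def forward(self, embeddings: np.ndarray) -> np.ndarray:
        return _nn.softmax(self.logits(embeddings))

    __call__ = forward

    def copy(self) -> "Classifier":
        return copy.deepcopy(self)


@dataclass
class Discriminator:
    """Discriminator D: N×E embeddings -> N probabilities of being source."""

    net: _nn.Network
    embed_dim: int

    def logits(self, embeddings: np.ndarray) -> np.ndarray:
        embeddings = np.asarray(embeddings, dtype=np.float64)
        if embeddings.ndim != 2 or embeddings.shape[1] != self.embed_dim:
            raise ValidationError(f"expected N×{self.embed_dim} embeddings, got {embeddings.shape}")
        return self.net.forward(embeddings)[:, 0]

    def forward(self, embeddings: np.ndarray) -> np.ndarray:
        return _nn.sigmoid(self.logits(embeddings))

    __call__ = forward

    def copy(self) -> "Discriminator":
        return copy.deepcopy(self)


@dataclass
class ModelSuite:
    """All trainable pieces of the two-step adaptation pipeline."""

    G_s: Embedding
    G_t: Embedding | None = None
    C_s: Classifier | None = None
    C_t: Classifier | None = None
    D: Discriminator | None = None
    metadata: dict = field(default_factory=dict)


def embedding_dim(bands: int, patch_size: int) -> int:
    """Flattened output size of the two valid convolutions (2×2 then 4×4)."""
    spatial = patch_size - 1 - 3  # P -> P-1 -> P-4
    if spatial < 1:
        raise ConfigurationError(
            f"patch_size {patch_size} too small for 2×2 followed by 4×4 valid convolutions (need >= 5)"
        )
    return 100 * spatial * spatial


def build_embedding(bands: int, patch_size: int = 5, seed: int | None = 0) -> Embedding:
    if bands < 1:
        raise ConfigurationError("bands must be >= 1")
    e = embedding_dim(bands, patch_size)
    rng = np.random.default_rng(seed)
    net = _nn.Network([
        _nn.Conv2d(bands, 20, 2, rng),
        _nn.ReLU(),
        _nn.Conv2d(20, 100, 4, rng),
        _nn.ReLU(),
        _nn.Flatten(),
    ])
    return Embedding(net, bands, patch_size, e)


def build_classifier(embed_dim: int, n_classes: int, seed: int | None = 0) -> Classifier:
    if embed_dim < 1 or n_classes < 1:
        raise ConfigurationError("embed_dim and n_classes must be >= 1")
    rng = np.random.default_rng(seed)
    net = _nn.Network([
        _nn.Dense(embed_dim, 84, rng),
        _nn.ReLU(),
        _nn.Dense(84, n_classes, rng),
    ])
    return Classifier(net, embed_dim, n_classes)


def build_discriminator(embed_dim: int, seed: int | None = 0) -> Discriminator:
    if embed_dim < 1:
        raise ConfigurationError("embed_dim must be >= 1")
    rng = np.random.default_rng(seed)
    net = _nn.Network([
        _nn.Dense(embed_dim, 100, rng),
        _nn.ReLU(),
        _nn.Dense(100, 1, rng),
    ])
    return Discriminator(net, embed_dim)


def n_parameters(model: Embedding | Classifier | Discriminator) -> int:
    return sum(p.value.size for p in model.net.params())


def predict_labels(
    G: Embedding, C: Classifier, patches: PatchSet | np.ndarray, batch_size: int = 4096
) -> tuple[np.ndarray, np.ndarray]:
    """Predict 0-based class labels and probabilities for a patch set.

    The label is the argmax of the class-probability vector; ties break to the
    lowest class index (numpy argmax convention). Deterministic given
    parameters.
    """
    x = patches.patches if isinstance(patches, PatchSet) else np.asarray(patches, dtype=np.float64)
    labels = np.empty(len(x), dtype=np.int64)
    probs = np.empty((len(x), C.n_classes))
    for start in range(0, len(x), batch_size):
        sl = slice(start, start + batch_size)
        p = C.forward(G.forward(x[sl]))
        probs[sl] = p
        labels[sl] = np.argmax(p, axis=1)
    return labels, probs


# ---------------------------------------------------------------------------
# Checkpointing: one .npz holding named parameter arrays plus a JSON header.
# ---------------------------------------------------------------------------

def save_suite(suite: ModelSuite, path: str | Path) -> None:
    arrays: dict[str, np.ndarray] = {}
    header: dict = {"metadata": suite.metadata, "models": {}}
    for name in ("G_s", "G_t", "C_s", "C_t", "D"):
        model = getattr(suite, name)
        if model is None:
            continue
        desc: dict = {"n_arrays": len(model.net.params())}
        if isinstance(model, Embedding):
            desc.update(kind="embedding", bands=model.bands, patch_size=model.patch_size,
                        embed_dim=model.embed_dim, normalized=model.band_mean is not None)
            if model.band_mean is not None:
                arrays[f"{name}/band_mean"] = model.band_mean
                arrays[f"{name}/band_std"] = model.band_std
        elif isinstance(model, Classifier):
            desc.update(kind="classifier", embed_dim=model.embed_dim, n_classes=model.n_classes)
        else:
            desc.update(kind="discriminator", embed_dim=model.embed_dim)
        for i, arr in enumerate(model.net.state_arrays()):
            arrays[f"{name}/{i}"] = arr
        header["models"][name] = desc
    arrays["__header__"] = np.frombuffer(json.dumps(header).encode(), dtype=np.uint8)
    np.savez(str(path), **arrays)


def load_suite(path: str | Path) -> ModelSuite:
    with np.load(str(path)) as data:
        header = json.loads(bytes(data["__header__"]).decode())
        kwargs: dict = {"metadata": header.get("metadata", {})}
        for name, desc in header["models"].items():
            if desc["kind"] == "embedding":
                model: Embedding | Classifier | Discriminator = build_embedding(
                    desc["bands"], desc["patch_size"], seed=0)
                if desc.get("normalized"):
                    model.band_mean = data[f"{name}/band_mean"]
                    model.band_std = data[f"{name}/band_std"]
            elif desc["kind"] == "classifier":
                model = build_classifier(desc["embed_dim"], desc["n_classes"], seed=0)
            else:
                model = build_discriminator(desc["embed_dim"], seed=0)
            model.net.load_state_arrays([data[f"{name}/{i}"] for i in range(desc["n_arrays"])])
            kwargs[name] = model
    return ModelSuite(**kwargs)
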