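import numpy as np
import pytest

from seadapt import LabelMask, MultispectralScene, PatchSet, TrainConfig
from seadapt.synthdata import SyntheticDomainConfig, default_spectra, generate_scene_pair


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_scene(rng):
    """10×10×8 scene with reproducible random reflectance."""
    return MultispectralScene(rng.uniform(0.0, 0.6, size=(10, 10, 8)))


@pytest.fixture
def small_mask():
    labels = np.zeros((10, 10), dtype=np.int64)
    labels[2:8, 2:8] = 1
    labels[4:6, 4:6] = 2
    return LabelMask(labels)


@pytest.fixture
def tiny_config():
    """Short schedule for unit tests of the training loops."""
    return TrainConfig(source_epochs=2, batch_size=32, adversarial_epochs=2,
                       ccsa_epochs=2, seed=0)


@pytest.fixture(scope="session")
def tiny_scene_pair():
    """A small zero-shift scene pair (well-separated 3-class, 4-band world)."""
    cfg = SyntheticDomainConfig(
        n_classes=3, n_bands=4,
        class_mean_spectra=default_spectra(3, 4, seed=5),
        class_spread=0.01, blob_scale=6.0, scene_size=(36, 36),
        label_margin=2, seed=5,
        class_names=("seagrass", "sea", "sand"),
    )
    return generate_scene_pair(cfg)


def labeled_patchset(rng, n_per_class=30, n_classes=3, bands=4, patch_size=5,
                     separation=3.0):
    """Synthetic labeled patches with linearly separable per-band means."""
    patches, labels = [], []
    for c in range(n_classes):
        base = np.zeros(bands)
        base[c % bands] = separation
        x = rng.normal(base, 0.1, size=(n_per_class, patch_size, patch_size, bands))
        patches.append(x)
        labels.extend([c] * n_per_class)
    centers = np.stack([np.arange(n_per_class * n_classes)] * 2, axis=1) + patch_size
    return PatchSet(np.concatenate(patches), np.array(labels), centers, patch_size,
                    class_names=tuple(f"c{i}" for i in range(n_classes)))


@pytest.fixture
def separable_patches(rng):
    return labeled_patchset(rng)
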