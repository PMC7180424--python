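import numpy as np
import pytest

from polypscope.classifier import TrainConfig, hard_labels, train_patch_classifier
from polypscope.synthetic import DEFAULT_TEXTURES, render_texture


def make_texture_patches(n_per_class: int, patch_size: int = 224, seed: int = 0):
    """Seeded stack of pure-texture patches for every patch class."""
    rng = np.random.default_rng(seed)
    patches, labels = [], []
    for cls, spec in DEFAULT_TEXTURES.items():
        for _ in range(n_per_class):
            oy, ox = rng.integers(0, 10_000, size=2)
            patches.append(render_texture(spec, patch_size, patch_size, rng,
                                          int(oy), int(ox)))
            labels.append(cls)
    return np.stack(patches), np.array(labels)


@pytest.fixture(scope="session")
def texture_patches():
    """240 patches per class: 200 for training + 40 held out."""
    return make_texture_patches(240, seed=11)


@pytest.fixture(scope="session")
def trained_model(texture_patches):
    """Reference CNN trained on 200 patches/class of the default textures,
    plus its held-out patches/labels and held-out accuracy."""
    patches, labels = texture_patches
    rng = np.random.default_rng(7)
    train_idx, test_idx = [], []
    for cls in np.unique(labels):
        idx = rng.permutation(np.flatnonzero(labels == cls))
        train_idx.extend(idx[:200])
        test_idx.extend(idx[200:])
    train_idx, test_idx = np.array(train_idx), np.array(test_idx)
    model = train_patch_classifier(
        patches[train_idx], labels[train_idx], TrainConfig(epochs=20, seed=3))
    probs = model.predict_probs(patches[test_idx])
    acc = float(np.mean(hard_labels(probs) == labels[test_idx]))
    return {
        "model": model,
        "test_patches": patches[test_idx],
        "test_labels": labels[test_idx],
        "accuracy": acc,
    }
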