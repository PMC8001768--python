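import numpy as np
import pytest

from histocompare import synthetic as syn


@pytest.fixture(scope="session")
def benign_spec():
    return syn.default_benign_spec()


@pytest.fixture(scope="session")
def malignant_spec():
    return syn.default_malignant_spec()


@pytest.fixture(scope="session")
def tissue_image(malignant_spec):
    """One zero-jitter two-stain patch with plenty of tissue."""
    spec = syn.default_malignant_spec(stain_jitter=0.0)
    patch, truth = syn.generate_image(spec, (96, 96), seed=3)
    return patch, truth


@pytest.fixture(scope="session")
def small_binary_set():
    """40 benign + 40 malignant patches at 64x64 with labels."""
    imgs, labels = [], []
    for i in range(40):
        for spec, lab, off in [(syn.default_benign_spec(), "benign", 0),
                               (syn.default_malignant_spec(), "malignant", 1)]:
            p, _ = syn.generate_image(spec, (64, 64), 2 * i + off)
            imgs.append(p.pixels)
            labels.append(lab)
    return np.stack(imgs), np.array(labels)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
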