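import numpy as np
import pytest

from mammocad import (
    FeatureTable,
    GrayImage,
    TableSpec,
    benign_spec,
    extract_feature_table,
    generate_feature_table,
    generate_phantom_dataset,
    malignant_spec,
    preprocess_pipeline,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_image():
    rng = np.random.default_rng(7)
    return GrayImage(rng.integers(0, 256, size=(32, 32)), 8)


@pytest.fixture(scope="session")
def planted_table():
    """200 x 50 table with 5 informative features at effect size 2."""
    table, informative = generate_feature_table(TableSpec(seed=5))
    return table, informative


@pytest.fixture(scope="session")
def separable_table():
    """A small, trivially separable two-feature table."""
    rng = np.random.default_rng(0)
    n = 40
    labels = np.repeat([0, 1], n // 2)
    x = rng.normal(0, 0.3, size=(n, 2))
    x[labels == 1] += 4.0
    return FeatureTable(x, ["fa", "fb"], labels)


@pytest.fixture(scope="session")
def phantom_features():
    """Feature table extracted end-to-end from 40 phantoms (20 per class)."""
    samples = generate_phantom_dataset(20, seed=42)
    rois = [
        (sid, preprocess_pipeline(img, spec.roi), spec.label)
        for sid, img, _, spec in samples
    ]
    table, flagged = extract_feature_table(rois)
    assert not flagged
    return table
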