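import numpy as np
import pytest
from sklearn.datasets import load_breast_cancer

from tabready import MasterTable, SearchConfig, SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def wdbc() -> MasterTable:
    """The public 569 x 30 breast-cancer table bundled with scikit-learn."""
    data = load_breast_cancer()
    labels = np.where(data.target == 1, "benign", "malignant")
    return MasterTable(
        features=data.data,
        feature_names=list(data.feature_names),
        labels=labels,
        label_name="diagnosis",
    )


@pytest.fixture
def default_config() -> SearchConfig:
    return SearchConfig()


@pytest.fixture
def toy_master() -> MasterTable:
    """Tiny two-blob table: 12 rows, 3 features, 2 classes."""
    rng = np.random.default_rng(0)
    a = rng.normal(0.0, 0.3, size=(6, 3))
    b = rng.normal(5.0, 0.3, size=(6, 3))
    return MasterTable(
        features=np.vstack([a, b]),
        feature_names=["x", "y", "z"],
        labels=np.array(["a"] * 6 + ["b"] * 6),
        label_name="cls",
    )


@pytest.fixture(scope="session")
def junk_fixture():
    """Small planted-junk dataset used by the search tests."""
    spec = SyntheticSpec(
        n_rows=120,
        n_informative_features=5,
        n_classes=2,
        class_separation=4.0,
        n_duplicate_features=3,
        n_noise_features=4,
        missing_rate=0.08,
        outlier_rate=0.01,
        mislabel_rate=0.05,
        seed=20,
    )
    return generate_dataset(spec)
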