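import numpy as np
import pytest

from adctexture import synthetic


@pytest.fixture(scope="session")
def small_cohort():
    """40 well-separated slices on a small grid, shared across tests."""
    cfg = synthetic.SimConfig(
        n_slices=40,
        image_shape=(64, 64),
        class_params=synthetic.well_separated_class_params(),
        seed=11,
    )
    return synthetic.generate_cohort(cfg), cfg


@pytest.fixture(scope="session")
def small_feature_table(small_cohort):
    from adctexture import features

    cases, _ = small_cohort
    return features.extract_feature_table(cases)


def synthetic_feature_frame(n_rows, effect, seed, malignant_fraction=0.6):
    """A feature table with one planted informative feature and noise
    elsewhere; much faster than image-level simulation for selection and
    classifier tests."""
    from adctexture.features import FEATURE_COLUMNS, TABLE_COLUMNS
    import pandas as pd

    rng = np.random.default_rng(seed)
    n_mal = round(n_rows * malignant_fraction)
    labels = np.array(["malignant"] * n_mal + ["benign"] * (n_rows - n_mal))
    rng.shuffle(labels)
    y = (labels == "malignant").astype(float)
    data = {}
    for i, col in enumerate(FEATURE_COLUMNS):
        if col == "gender":
            data[col] = rng.integers(0, 2, size=n_rows)
        elif col == "mean_adc":  # the planted informative feature
            data[col] = rng.normal(0, 1, n_rows) + effect * y
        else:
            data[col] = rng.normal(0, 1, n_rows)
    frame = pd.DataFrame(data)
    frame.insert(0, "case_id", [f"row_{i:05d}" for i in range(n_rows)])
    frame["label"] = labels
    return frame[TABLE_COLUMNS]
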