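import numpy as np
import pytest

from mzmerge.feature_table import FeatureTable, ReplicateDesign


@pytest.fixture
def duplicate_design():
    """Four biological samples, two analytical replicates each."""
    return ReplicateDesign({
        "S1_r1": "S1", "S1_r2": "S1",
        "S2_r1": "S2", "S2_r2": "S2",
        "S3_r1": "S3", "S3_r2": "S3",
        "S4_r1": "S4", "S4_r2": "S4",
    })


@pytest.fixture
def profile_ids(duplicate_design):
    return list(duplicate_design.assignments)


def make_table(mz, rt, intensities, profile_ids, label="test"):
    return FeatureTable(
        mz=np.asarray(mz, dtype=float),
        rt=np.asarray(rt, dtype=float),
        intensities=np.asarray(intensities, dtype=float),
        profile_ids=profile_ids,
        setting_label=label,
    )


@pytest.fixture
def small_table(profile_ids):
    """Three well-separated features over 8 profiles, no missing values."""
    rng = np.random.default_rng(42)
    base = np.array([1e5, 5e4, 2e6])
    inten = base[:, None] * rng.lognormal(0.0, 0.05, size=(3, 8))
    return make_table([100.0, 200.0, 400.0], [50.0, 120.0, 300.0],
                      inten, profile_ids)


def random_table(rng, n_features, profile_ids, *, min_gap_ppm=20.0,
                 mz_range=(85.0, 850.0), rt_range=(0.0, 600.0), label="rand"):
    """Random table whose own features are mutually separated in m/z."""
    while True:
        mz = np.sort(rng.uniform(*mz_range, size=n_features))
        if n_features < 2 or (np.diff(mz) / mz[:-1] * 1e6 > min_gap_ppm).all():
            break
    rt = rng.uniform(*rt_range, size=n_features)
    inten = rng.lognormal(np.log(1e5), 1.0, size=(n_features, len(profile_ids)))
    return make_table(mz, rt, inten, profile_ids, label)
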