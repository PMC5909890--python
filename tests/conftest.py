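import numpy as np
import pandas as pd
import pytest

from mzpanel.io import FeatureRecord, FeatureTable, SampleRecord
from mzpanel.library import builtin_panel_library, builtin_reference_library

MARKER_LABELS = {
    "FA 2-OH C16:0_N", "FA C18:0_N", "TUDCA_N",
    "PE ae C36:4_N", "PE aa C38:6_N", "LysoPC a C20:4_P",
}


@pytest.fixture(scope="session")
def panel_library():
    return builtin_panel_library()


@pytest.fixture(scope="session")
def reference_library():
    return builtin_reference_library()


@pytest.fixture
def tiny_table():
    """3 samples x 4 features, handcrafted."""
    samples = [
        SampleRecord("s1", "case", "athlete", "1", "<=6h"),
        SampleRecord("s2", "case", "athlete", "1", "<=6h"),
        SampleRecord("s3", "control", "athlete", "1", "<=6h"),
    ]
    features = [
        FeatureRecord("271.2277@NEG", 271.2277, "NEG"),
        FeatureRecord("283.2647@NEG", 283.2647, "NEG"),
        FeatureRecord("544.3398@POS", 544.3398, "POS"),
        FeatureRecord("600.1000@POS", 600.1, "POS"),
    ]
    X = np.array(
        [
            [10.0, 200.0, 3000.0, 5.5],
            [12.0, 180.0, 2500.0, 6.5],
            [9.0, 260.0, 4000.0, 4.5],
        ]
    )
    return FeatureTable.from_records(samples, features, X)


def make_group_table(X: np.ndarray, y: np.ndarray, state: str = "autoscaled", labels=None) -> FeatureTable:
    """Build a FeatureTable directly from a matrix and binary outcome.

    Used by selection/evaluation tests that need full control over the
    numeric values; feature m/z are synthetic placeholders.
    """
    n, p = X.shape
    samples = [
        SampleRecord(f"s{i:04d}", "case" if y[i] else "control", "sim", "1", "")
        for i in range(n)
    ]
    if labels is None:
        labels = [f"F{j}_N" for j in range(p)]
    features = [FeatureRecord(labels[j], 100.0 + j * 0.5, "NEG", labels[j]) for j in range(p)]
    sdf = pd.DataFrame(
        {
            "group": [s.group for s in samples],
            "cohort": "sim",
            "batch": "1",
            "timepoint": "",
        },
        index=pd.Index([s.sample_id for s in samples], name="sample_id"),
    )
    fdf = pd.DataFrame(
        {
            "mz": [f.mz for f in features],
            "esi_mode": "NEG",
            "annotation": labels,
        },
        index=pd.Index(labels, name="feature_id"),
    )
    mat = pd.DataFrame(np.asarray(X, dtype=float), index=sdf.index, columns=fdf.index)
    return FeatureTable(samples=sdf, features=fdf, abundances=mat, transform_state=state)
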