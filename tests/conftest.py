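import numpy as np
import pandas as pd
import pytest

from ramscreen import (
    PeakSpec,
    RamanSpectrum,
    SpectrumSet,
    SyntheticConfig,
    generate_cohort,
    preprocess_pipeline,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A small separable cohort: 6 vs 6 specimens, 3 scans each."""
    cfg = SyntheticConfig(
        seed=42,
        n_per_class={"BCA-positive": 6, "BCA-negative": 6},
        scans_per_specimen=3,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def preprocessed_specimens(small_cohort):
    sset, _ = small_cohort
    return preprocess_pipeline(sset, average=True)


@pytest.fixture(scope="session")
def preprocessed_scans(small_cohort):
    sset, _ = small_cohort
    return preprocess_pipeline(sset, average=False)


@pytest.fixture()
def toy_metadata():
    return pd.DataFrame(
        {
            "specimen_id": ["a", "b"],
            "class_label": ["pos", "neg"],
            "dataset": ["synthetic", "synthetic"],
        }
    )


@pytest.fixture()
def toy_set(toy_metadata):
    """Two single-scan spectra on a shared 5-point grid."""
    grid = np.array([400.0, 401.0, 402.0, 403.0, 404.0])
    matrix = np.array([[1.0, 2.0, 3.0, 4.0, 5.0], [5.0, 4.0, 3.0, 2.0, 1.0]])
    return SpectrumSet(grid, matrix, ["a", "b"], [0, 0], toy_metadata)


def make_spectrum(w, y, sid="s", scan=0):
    return RamanSpectrum(np.asarray(w, float), np.asarray(y, float), sid, scan)
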