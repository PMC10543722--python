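import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from msihet import (
    PixelTable,
    SyntheticConfig,
    generate_cohort,
    kmeans_segment,
    presence_matrix,
    rms_normalize,
)
from msihet.dataio import feature_columns

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


def make_pixel_table(intensities, patient_ids=None, cohort="tumor", prefix="px"):
    """Construct a minimal valid PixelTable from an n × F intensity array."""
    X = np.asarray(intensities, dtype=float)
    n, F = X.shape
    if patient_ids is None:
        patient_ids = ["P1"] * n
    frame = pd.DataFrame(
        {
            "pixel_id": [f"{prefix}{i}" for i in range(n)],
            "patient_id": patient_ids,
            "core_id": [f"{p}-c1" for p in patient_ids],
            "cohort": cohort,
            "x": np.arange(n),
            "y": np.zeros(n, dtype=int),
        }
    )
    return PixelTable(pd.concat([frame, pd.DataFrame(X, columns=feature_columns(F))], axis=1))


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully structured synthetic cohort shared across tests."""
    cfg = SyntheticConfig(
        n_patients=24,
        cores_per_patient=2,
        pixels_per_core=60,
        n_features=30,
        n_clusters_true=4,
        patches_per_core=10,
        centroid_separation=6.0,
        seed=42,
    )
    pixels, clinical, catalog, truth = generate_cohort(cfg)
    return cfg, pixels, clinical, catalog, truth


@pytest.fixture(scope="session")
def small_segmentation(small_cohort):
    cfg, pixels, clinical, catalog, truth = small_cohort
    norm = rms_normalize(pixels)
    seg = kmeans_segment(norm, cfg.n_clusters_true, seed=0, n_init=4)
    pres = presence_matrix(seg, norm)
    return norm, seg, pres
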