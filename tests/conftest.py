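import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from magicquant.segmentation import CellLabelMap
from magicquant.synth import SceneSpec, generate_scene

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


NOISELESS = dict(poisson_scale=0.0, read_noise_sd=0.0)


@pytest.fixture(scope="session")
def mito_scene():
    """One standard-noise mitochondrial scene with designed 2x enrichment."""
    return generate_scene(SceneSpec(seed=3, reporter_mito_enrichment=2.0))


@pytest.fixture(scope="session")
def noiseless_mito_scene():
    return generate_scene(
        SceneSpec(seed=5, reporter_mito_enrichment=3.0, cell_brightness_cv=0.0, **NOISELESS)
    )


@pytest.fixture(scope="session")
def nc_scene():
    """Nuclear-marker scene with a designed N/C ratio of 2.5."""
    return generate_scene(
        SceneSpec(
            image_shape=(12, 320, 320),
            n_cells=15,
            marker="nucleus",
            nc_ratio_true=2.5,
            seed=7,
        )
    )


def single_cell_labels(cell_mask: np.ndarray) -> CellLabelMap:
    """Wrap one boolean mask as a one-cell label map (unit-test helper)."""
    labels = np.zeros(cell_mask.shape, dtype=np.int32)
    labels[cell_mask] = 1
    qc = pd.DataFrame(
        [
            {
                "cell_id": 1,
                "area_px": int(cell_mask.sum()),
                "touches_border": False,
                "included": True,
                "reason": "",
            }
        ]
    )
    return CellLabelMap(labels=labels, cell_ids=[1], qc=qc)
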