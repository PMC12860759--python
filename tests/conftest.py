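import numpy as np
import pandas as pd
import pytest

from texsurv.images import Mask, Modality, PlanarImage
from texsurv.synthetic import CohortSpec, gen_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_survival():
    """Eight subjects, mixed censoring, two groups of four."""
    return {
        "time": np.array([2.0, 3.0, 5.0, 7.0, 11.0, 13.0, 17.0, 19.0]),
        "event": np.array([1, 0, 1, 1, 0, 1, 1, 1]),
        "group": np.array([1, 1, 0, 1, 0, 0, 1, 0], dtype=bool),
    }


@pytest.fixture
def small_cohort():
    """Default-shaped cohort (66 subjects) with one planted, three null markers."""
    return gen_cohort(CohortSpec(seed=42), n_null_markers=3)


@pytest.fixture
def strong_cohort():
    """Larger, higher-power cohort for pipeline-level checks."""
    return gen_cohort(
        CohortSpec(seed=11, n_subjects=120, n_events_target=40, planted_hr=4.0),
        n_linked_markers=2,
        n_null_markers=4,
    )


@pytest.fixture
def random_ct_image(rng):
    values = rng.normal(40.0, 30.0, size=(32, 32))
    return PlanarImage(values, (1.0, 1.0), modality=Modality.CT)


@pytest.fixture
def disc_mask():
    ii, jj = np.meshgrid(np.arange(32), np.arange(32), indexing="ij")
    return Mask((ii - 15.5) ** 2 + (jj - 15.5) ** 2 <= 100.0)
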