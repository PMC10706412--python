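from dataclasses import replace

import matplotlib
import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cnose

matplotlib.use("Agg")

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_spec():
    """Down-scaled array geometry for fast rendering in unit tests."""
    return replace(
        cnose.SyntheticSpec(),
        image_size=(240, 320),
        spacing=80.0,
        spot_radius=20.0,
    )


@pytest.fixture(scope="session")
def quiet_small_spec(small_spec):
    """Small geometry, no noise, no shading: exact expectations apply."""
    return replace(small_spec, noise_sd=0.0, illumination_gradient=0.0)


@pytest.fixture(scope="session")
def tiny_spec():
    """Smallest legal geometry (spot area just above the opening threshold)."""
    return replace(
        cnose.SyntheticSpec(),
        image_size=(120, 160),
        spacing=60.0,
        spot_radius=19.0,
        noise_sd=1.0,
        illumination_gradient=0.0,
    )


@pytest.fixture(scope="session")
def dataset104():
    """The study-sized dataset: 13 classes x 8 samples at the default
    noise level, rendered and analysed through the full pipeline."""
    df, truths = cnose.make_dataset(cnose.SyntheticSpec(), n_per_class=8, sample_seed=0)
    return df, truths


@pytest.fixture(scope="session")
def results104(dataset104):
    """Tuned and validated classifier on the study-sized dataset."""
    df, _ = dataset104
    model = cnose.AdulterationModel.from_dataframe(df)
    return model.fit(n_iter=50, seed=0)
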