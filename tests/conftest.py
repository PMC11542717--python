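import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("reproducible", derandomize=True)
settings.load_profile("reproducible")

from iamtox.dataset_io import load_endpoint_table, load_table3, load_uv_filter_panel
from iamtox.qsar_models import default_registry


@pytest.fixture(scope="session")
def panel():
    """The 13 published UV filters with descriptors, CHI_IAM and endpoints."""
    return load_uv_filter_panel()


@pytest.fixture(scope="session")
def registry():
    """Models recovered from the published prediction tables."""
    return default_registry()


@pytest.fixture(scope="session")
def chi_by_name():
    df = load_table3()
    return dict(zip(df["name"], df["chi_iam"].astype(float)))


@pytest.fixture(scope="session")
def fish_table():
    return load_endpoint_table("fish_pLC50")


@pytest.fixture(scope="session")
def daphnia_table():
    return load_endpoint_table("daphnia_pEC50")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240911)
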