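import numpy as np
import pytest

from hamdose import ApplicatorSpec, build_flat_plan_template, default_library, ir192_spectrum
from hamdose.engine import TransportSettings
from hamdose.source import SourceGeometry
from hamdose.tg43 import characterize_tg43


@pytest.fixture(scope="session")
def library():
    return default_library()


@pytest.fixture(scope="session")
def spectrum():
    return ir192_spectrum()


@pytest.fixture(scope="session")
def app_spec():
    return ApplicatorSpec()


@pytest.fixture(scope="session")
def template(app_spec):
    return build_flat_plan_template(app_spec)


@pytest.fixture(scope="session")
def source_geom():
    return SourceGeometry()


@pytest.fixture(scope="session")
def dataset_small(source_geom):
    """TG-43 dataset characterized at a small shared budget (seeded)."""
    settings = TransportSettings(n_histories=2_500_000, seed=9001, n_batches=20)
    return characterize_tg43(source_geom, settings, se_tolerance=None)
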