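import textwrap

import pytest

from acidisland import synthetic_data as sd
from acidisland.proximity import assign_distances
from acidisland.site_records import read_cities, read_sites


@pytest.fixture(scope="session")
def fixture_paths():
    return sd.packaged_fixture()


@pytest.fixture(scope="session")
def fixture_sites(fixture_paths):
    return read_sites(fixture_paths["sites"])


@pytest.fixture(scope="session")
def fixture_cities(fixture_paths):
    return read_cities(fixture_paths["cities"])


@pytest.fixture(scope="session")
def fixture_assignments(fixture_sites, fixture_cities):
    return assign_distances(fixture_sites, fixture_cities)


@pytest.fixture(scope="session")
def noise_free_dataset():
    """Noise-free synthetic study with constant precipitation: every fit
    must recover its ground-truth curve exactly."""
    cfg = sd.SyntheticConfig(seed=7, sigma_log=0.0, sigma_ph=0.0, precip_range=(1500.0, 1500.0))
    return cfg, sd.generate(cfg)


@pytest.fixture
def write_csv(tmp_path):
    def _write(name: str, text: str):
        path = tmp_path / name
        path.write_text(textwrap.dedent(text).lstrip())
        return path

    return _write
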