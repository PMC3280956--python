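import json

import pytest

from synthgrow.blockprep import build_catalog
from synthgrow.fixtures import FixtureSpec, generate_catalog
from synthgrow.reactions import load_reaction_library


@pytest.fixture(scope="session")
def coupling_library():
    return load_reaction_library(bundled="coupling")


@pytest.fixture(scope="session")
def fga_fgi_library():
    return load_reaction_library(bundled="fga_fgi")


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixture")
    generate_catalog(FixtureSpec(seed=7), out)
    return out


@pytest.fixture(scope="session")
def fixture_manifest(fixture_dir):
    return json.loads((fixture_dir / "manifest.json").read_text())


@pytest.fixture(scope="session")
def prepared_catalog(fixture_dir, coupling_library, fga_fgi_library):
    return build_catalog(fixture_dir / "catalog.smi", coupling_library, fga_fgi_library)
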