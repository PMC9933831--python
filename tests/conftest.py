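import json
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

from pepscout.fixtures import FixtureSpec, generate_world
from pepscout.proteome_io import ProteinRecord, ProteomeLibrary

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def toy_library() -> ProteomeLibrary:
    """Two tiny proteins sharing one tryptic peptide (GGGR)."""
    return ProteomeLibrary(
        records=[
            ProteinRecord(accession="P1", sequence="AAAKGGGR"),
            ProteinRecord(accession="P2", sequence="GGGRCCCK"),
        ],
        source_label="toy",
    )


@pytest.fixture(scope="session")
def demo_world(tmp_path_factory):
    """One generated world reused across tests: paths plus parsed answer key."""
    out = tmp_path_factory.mktemp("world")
    paths = generate_world(FixtureSpec(seed=7, failure_script="auto"), out)
    key = json.loads(Path(paths.answer_key).read_text())
    return paths, key
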