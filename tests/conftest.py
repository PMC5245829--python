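import pytest

from dinomir.cli_report import run_all
from dinomir.read_cleaning import CascadeConfig
from dinomir.synthetic_data import SimulationConfig, generate_library


@pytest.fixture(scope="session")
def default_bundle():
    """The default synthetic study conditions: 20 duplex loci at 50:1
    guide/star asymmetry, 5000 tiled mRNA fragments, 20% contaminants."""
    return generate_library(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def default_pipeline(default_bundle):
    b = default_bundle
    cascade = CascadeConfig(
        rrna=b.references["rrna"],
        trna=b.references["trna"],
        organelle=b.references["organelle"],
    )
    return run_all(b.reads, cascade, transcripts=b.references["transcripts"].records)


@pytest.fixture(scope="session")
def small_bundle():
    """A reduced library for fast unit-level checks."""
    cfg = SimulationConfig(
        seed=11,
        n_mirna_loci=5,
        n_fragments_per_transcript=120,
        fragment_tile_step=6,
    )
    return generate_library(cfg)
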