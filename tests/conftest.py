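import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `helpers` importable

import bhlhfam as bf


@pytest.fixture(scope="session")
def model():
    return bf.default_model()


@pytest.fixture(scope="session")
def small_family():
    """A 20-genes-per-genome trio shared by structural tests."""
    return bf.generate_family(bf.FamilyConfig(n_genes_per_genome=20, seed=11))


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """A complete pipeline run on the default study conditions."""
    outdir = tmp_path_factory.mktemp("pipeline")
    config = bf.FamilyConfig(seed=2024)
    summary = bf.run_pipeline(config, outdir)
    return config, summary, outdir
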