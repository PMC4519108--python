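import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from ssrforge.pipeline import run_pipeline
from ssrforge.synthetic_data import SimConfig, generate_pair


@pytest.fixture
def fasta_file(tmp_path):
    """Write records given as (id, seq) pairs to a FASTA file."""

    def _write(records, name="test.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rid, seq in records:
                fh.write(f">{rid}\n{seq}\n")
        return path

    return _write


@pytest.fixture(scope="session")
def sim_pair():
    """Noise-free paired fixture under the default study conditions."""
    return generate_pair(SimConfig(seed=7))


@pytest.fixture(scope="session")
def pipeline_result(sim_pair):
    return run_pipeline(sim_pair.p1, sim_pair.p2, annotations=sim_pair.annotations)


@pytest.fixture(scope="session")
def noisy_pair():
    """Same conditions with 0.5% flank substitution noise."""
    return generate_pair(SimConfig(seed=7, flank_snp_rate=0.005))


@pytest.fixture(scope="session")
def noisy_result(noisy_pair):
    return run_pipeline(noisy_pair.p1, noisy_pair.p2, annotations=noisy_pair.annotations)
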