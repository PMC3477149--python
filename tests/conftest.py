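import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from gametolog import SimConfig, simulate_gametologs, write_fixture


@pytest.fixture
def rng():
    return np.random.default_rng(20120)


@pytest.fixture
def write_fasta(tmp_path):
    def _write(records, name="aln.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rec_id, seq in records:
                fh.write(f">{rec_id}\n{seq}\n")
        return path
    return _write


@pytest.fixture(scope="session")
def sim_fixture_dir(tmp_path_factory):
    """A written simulation fixture (FASTA + tags + truth) without conversion."""
    outdir = tmp_path_factory.mktemp("simfix")
    aln, truth = simulate_gametologs(SimConfig(n_codons=1500, seed=11))
    paths = write_fixture(aln, truth, outdir)
    return paths
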