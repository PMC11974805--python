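import numpy as np
import pytest

from motifdms.presets import rad54_motif_spec, toy_motif_spec


@pytest.fixture(scope="session")
def rad54_spec():
    return rad54_motif_spec()


@pytest.fixture(scope="session")
def toy_spec():
    """Single-window motif (TKR) — the screen's elementary unit."""
    return toy_motif_spec()


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def write_fastq(tmp_path):
    """Write a list of read sequences as a FASTQ file and return its path."""

    def _write(reads, name="reads.fastq", qual_char="I"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for i, seq in enumerate(reads):
                fh.write(f"@read{i}\n{seq}\n+\n{qual_char * len(seq)}\n")
        return path

    return _write
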