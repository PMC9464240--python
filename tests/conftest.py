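from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gage.genome_io import GenomeSet, SequenceRecord

settings.register_profile(
    "ci",
    max_examples=50,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def random_sequence(rng: np.random.Generator, n: int, freqs=None) -> str:
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    p = freqs if freqs is not None else (0.25,) * 4
    return bases[rng.choice(4, size=n, p=p)].tobytes().decode()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def write_fasta_file(tmp_path):
    def _write(text: str, name: str = "genome.fa"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write


def make_genome(*seqs: str, ids=None) -> GenomeSet:
    ids = ids or [f"s{i + 1}" for i in range(len(seqs))]
    return GenomeSet([SequenceRecord(i, s) for i, s in zip(ids, seqs)])
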