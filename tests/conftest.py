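import random

import pytest

from alnkit.core import DataType, FormatSpec, validate_alignment
from alnkit import fixtures, io


@pytest.fixture
def rng():
    return random.Random(42)


@pytest.fixture
def toy_aln():
    """The worked 3-taxon example: 2/12 missing, one variable site."""
    return validate_alignment(
        [("t1", "ACGT"), ("t2", "AC-T"), ("t3", "?CGA")], source_name="toy"
    )


@pytest.fixture
def fasta_dir(tmp_path, rng):
    """Three small FASTA files on disk."""
    paths = []
    for i in range(3):
        aln = fixtures.random_alignment(rng, n_taxa=4, length=30, name=f"loc{i}")
        paths.append(io.write_file(aln, FormatSpec.FASTA, tmp_path / f"loc{i}.fas"))
    return paths


def random_shape_alignment(rng, name="aln", min_length=0):
    """A random alignment of random shape, datatype and missing rate."""
    datatype = rng.choice([DataType.DNA, DataType.AA])
    return (
        fixtures.random_alignment(
            rng,
            n_taxa=rng.randint(1, 30),
            length=rng.randint(min_length, 200),
            datatype=datatype,
            missing_rate=rng.uniform(0, 0.3),
            name=name,
        ),
        datatype,
    )
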