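import numpy as np
import pytest

from rippnet.io import PeptideRecord, PeptideSet
from rippnet.synthetic import SyntheticSpec, generate


@pytest.fixture
def toy_set():
    return PeptideSet(
        records=[
            PeptideRecord(id="a", sequence="MKTAYIAKQR" * 3, label=1),
            PeptideRecord(id="b", sequence="ACDEFGHIKLMNPQRSTVWY", label=0),
            PeptideRecord(id="c", sequence="MKVLLACDEFGHIKLMNPQR", label=0),
        ],
        name="toy",
    )


@pytest.fixture(scope="session")
def small_balanced():
    """Noise-free, perfectly separable synthetic set (60 + 60)."""
    spec = SyntheticSpec(n_positive=60, n_negative=60, substitution_prob=0.0, seed=11)
    return spec, generate(spec)


def write_fasta(path, records):
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")
    return path
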