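import numpy as np
import pytest

from promin.pwmscan import PWM
from promin.seqio import write_fasta, GenomicSequence


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_pwm():
    """A 3-position matrix with one strong, one moderate and one weak column."""
    freq = np.array(
        [
            [0.85, 0.05, 0.05, 0.05],
            [0.40, 0.40, 0.10, 0.10],
            [0.25, 0.25, 0.25, 0.25],
        ]
    )
    return PWM(id="TOY", name="toy", freq=freq)


@pytest.fixture
def fasta_file(tmp_path):
    """Factory writing sequences to a temp FASTA and returning the path."""

    def _write(seqs, name="test.fa"):
        path = tmp_path / name
        write_fasta(
            [s if isinstance(s, GenomicSequence) else GenomicSequence(*s) for s in seqs],
            path,
        )
        return path

    return _write


def random_dna(rng, n, probs=(0.25, 0.25, 0.25, 0.25)):
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=list(probs))])
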