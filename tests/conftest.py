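import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from kmersig.sequence_io import SequenceRecord  # noqa: E402


@pytest.fixture
def write_fasta(tmp_path):
    """Write FASTA text to a temp file and return its path."""

    def _write(text: str, name: str = "test.fa"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write


@pytest.fixture
def random_records():
    """Random ACGT-only records of given lengths (seeded)."""

    def _make(lengths, seed=0):
        rng = np.random.default_rng(seed)
        out = []
        for i, length in enumerate(lengths):
            seq = "".join(rng.choice(list("ACGT"), size=length))
            out.append(SequenceRecord(id=f"r{i}", seq=seq))
        return out

    return _make


def brute_force_count(records, kmer: str) -> int:
    """Independent oracle: count overlapping occurrences of one k-mer."""
    k = len(kmer)
    total = 0
    for rec in records:
        for i in range(len(rec.seq) - k + 1):
            if rec.seq[i : i + k] == kmer:
                total += 1
    return total


def brute_force_windows(records, k: int) -> int:
    """Independent oracle: count ACGT-only windows by direct enumeration."""
    total = 0
    for rec in records:
        for i in range(len(rec.seq) - k + 1):
            if all(ch in "ACGT" for ch in rec.seq[i : i + k]):
                total += 1
    return total
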