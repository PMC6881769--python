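"""FASTA input and background base composition.

Sequences are uppercased on read. All non-ACGT symbols (N and IUPAC
ambiguity codes) are excluded from the composition and break k-mer windows:
only the 4^k unambiguous k-mers are ever scored, so a window containing an
ambiguous base has no home in the motifome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from Bio.SeqIO.FastaIO import SimpleFastaParser

__all__ = [
    "SequenceRecord",
    "CompositionProfile",
    "FastaError",
    "read_fasta",
    "compute_composition",
    "count_valid_windows",
    "encode_bases",
]

BASES = "ACGT"

# A,C,G,T -> 0,1,2,3; everything else (N, IUPAC codes) -> -1
_CODE_TABLE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _CODE_TABLE[ord(_b)] = _i
    _CODE_TABLE[ord(_b.lower())] = _i


class FastaError(ValueError):
    """Malformed FASTA input."""


@dataclass(frozen=True)
class SequenceRecord:
    """A single named DNA sequence (uppercase, may contain ambiguity codes)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record needs a non-empty id")
        if not self.seq:
            raise ValueError(f"sequence record {self.id!r} has an empty sequence")


@dataclass(frozen=True)
class CompositionProfile:
    """Background base distribution of a sequence set.

    ``fractions`` are relative to unambiguous (ACGT) bases only.  ``counts``
    and the two totals are ``None`` for profiles reconstructed from a
    signature file header, which stores only the fractions.
    """

    p_a: float
    p_c: float
    p_g: float
    p_t: float
    counts: Optional[tuple[int, int, int, int]] = None
    total_unambiguous: Optional[int] = None
    total_raw: Optional[int] = None

    def __post_init__(self) -> None:
        fr = self.fractions
        if any(f < 0 or f > 1 for f in fr):
            raise ValueError(f"base fractions must lie in [0,1]: {fr}")
        if abs(sum(fr) - 1.0) > 1e-12:
            raise ValueError(f"base fractions must sum to 1: {fr}")

    @property
    def fractions(self) -> tuple[float, float, float, float]:
        """(p_A, p_C, p_G, p_T)."""
        return (self.p_a, self.p_c, self.p_g, self.p_t)

    @classmethod
    def from_counts(
        cls, counts: Sequence[int], total_raw: int
    ) -> "CompositionProfile":
        a, c, g, t = (int(x) for x in counts)
        total = a + c + g + t
        if total <= 0:
            raise ValueError("no unambiguous bases: composition undefined")
        return cls(
            p_a=a / total,
            p_c=c / total,
            p_g=g / total,
            p_t=t / total,
            counts=(a, c, g, t),
            total_unambiguous=total,
            total_raw=int(total_raw),
        )


def read_fasta(path) -> list[SequenceRecord]:
    """Read a (possibly multi-record, line-wrapped) FASTA file.

    Sequences are uppercased and whitespace is stripped.  Raises
    :class:`FastaError` for text before the first header, empty sequences,
    or duplicate ids.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with open(path) as handle:
        try:
            parsed = list(SimpleFastaParser(handle))
        except ValueError as exc:  # text before the first '>' header
            raise FastaError(f"{path}: {exc}") from exc
    for title, seq in parsed:
        rec_id = title.split()[0] if title.split() else title
        if not rec_id:
            raise FastaError(f"{path}: record with empty header")
        seq = "".join(seq.split()).upper()
        if not seq:
            raise FastaError(f"{path}: record {rec_id!r} has an empty sequence")
        if rec_id in seen:
            raise FastaError(f"{path}: duplicate record id {rec_id!r}")
        seen.add(rec_id)
        records.append(SequenceRecord(id=rec_id, seq=seq))
    if not records:
        raise FastaError(f"{path}: no FASTA records found")
    return records


def encode_bases(seq: str) -> np.ndarray:
    """Encode a sequence as int8 codes (A,C,G,T -> 0..3; others -> -1)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE_TABLE[raw]


def compute_composition(records: Sequence[SequenceRecord]) -> CompositionProfile:
    """Count A/C/G/T over all records; ambiguous bases are excluded."""
    if not records:
        raise ValueError("compute_composition requires at least one record")
    counts = np.zeros(4, dtype=np.int64)
    total_raw = 0
    for rec in records:
        codes = encode_bases(rec.seq)
        total_raw += codes.size
        counts += np.bincount(codes[codes >= 0], minlength=4)
    if counts.sum() == 0:
        raise ValueError("no unambiguous (ACGT) bases: composition undefined")
    return CompositionProfile.from_counts(counts, total_raw)


def count_valid_windows(records: Sequence[SequenceRecord], k: int) -> int:
    """Number of length-k windows made of only A/C/G/T, summed over records.

    Windows never span record boundaries; records shorter than k contribute
    nothing.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    total = 0
    for rec in records:
        codes = encode_bases(rec.seq)
        n = codes.size
        if n < k:
            continue
        invalid = (codes < 0).astype(np.int64)
        csum = np.concatenate(([0], np.cumsum(invalid)))
        # window starting at i is valid iff no invalid base in [i, i+k)
        total += int(np.count_nonzero(csum[k:] - csum[:-k] == 0))
    return total
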