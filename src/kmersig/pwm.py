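"""JASPAR position frequency matrices and k-mer matching.

Candidate k-mers are matched against transcription-factor binding-site
PFMs by sliding the shorter of (k-mer, matrix) along the longer and scoring
each full-overlap alignment.  The default similarity is the per-column
ratio-to-max: at each aligned position the k-mer's base contributes
freq(base)/max(column), averaged over the overlap.  On a one-hot matrix
this reduces to percent identity against the consensus.  A hit is called
at similarity >= 0.8 by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from kmersig.selection import reverse_complement

__all__ = [
    "PositionWeightMatrix",
    "PwmHit",
    "PwmFormatError",
    "read_jaspar",
    "similarity",
    "scan",
    "write_hits",
]

_BASE_ROW = {"A": 0, "C": 1, "G": 2, "T": 3}


class PwmFormatError(ValueError):
    """Malformed JASPAR PFM file."""


@dataclass(frozen=True)
class PositionWeightMatrix:
    """Per-position base frequencies of a binding site (columns sum to 1)."""

    id: str
    name: str
    columns: np.ndarray  # shape (width, 4), rows sum to 1

    @property
    def width(self) -> int:
        return int(self.columns.shape[0])

    def __post_init__(self) -> None:
        if self.columns.ndim != 2 or self.columns.shape[1] != 4:
            raise ValueError(f"{self.id}: columns must be (width, 4)")
        if self.width < 1:
            raise ValueError(f"{self.id}: width must be >= 1")
        if (self.columns < 0).any():
            raise ValueError(f"{self.id}: negative frequencies")
        sums = self.columns.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError(f"{self.id}: columns must sum to 1")


@dataclass(frozen=True)
class PwmHit:
    """Best-scoring alignment of a k-mer against one PFM."""

    kmer: str
    pwm_id: str
    pwm_name: str
    offset: int  # 0-based position of the k-mer's first base within the PWM
    similarity: float
    strand: str = "+"


def _finish_matrix(
    matrix_id: str, name: str, rows: dict[str, list[float]]
) -> PositionWeightMatrix:
    missing = [b for b in "ACGT" if b not in rows]
    if missing:
        raise PwmFormatError(f"matrix {matrix_id}: missing base row(s) {missing}")
    widths = {len(v) for v in rows.values()}
    if len(widths) != 1:
        raise PwmFormatError(f"matrix {matrix_id}: ragged rows (widths {sorted(widths)})")
    counts = np.array([rows[b] for b in "ACGT"], dtype=float).T  # (width, 4)
    if counts.shape[0] == 0:
        raise PwmFormatError(f"matrix {matrix_id}: empty matrix")
    if (counts < 0).any():
        raise PwmFormatError(f"matrix {matrix_id}: negative counts")
    sums = counts.sum(axis=1)
    if (sums == 0).any():
        bad = int(np.flatnonzero(sums == 0)[0])
        raise PwmFormatError(f"matrix {matrix_id}: zero-sum column {bad}")
    return PositionWeightMatrix(id=matrix_id, name=name, columns=counts / sums[:, None])


def read_jaspar(path) -> list[PositionWeightMatrix]:
    """Parse a JASPAR-style PFM file (``>ID NAME`` then A/C/G/T count rows).

    Counts are normalized to column frequencies.  Errors name the offending
    matrix.
    """
    matrices: list[PositionWeightMatrix] = []
    matrix_id: Optional[str] = None
    name = ""
    rows: dict[str, list[float]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if matrix_id is not None:
                    matrices.append(_finish_matrix(matrix_id, name, rows))
                fields = line[1:].split(None, 1)
                if not fields:
                    raise PwmFormatError(f"line {lineno}: header with no matrix id")
                matrix_id = fields[0]
                name = fields[1].strip() if len(fields) > 1 else ""
                rows = {}
            else:
                if matrix_id is None:
                    raise PwmFormatError(f"line {lineno}: counts before any '>' header")
                base = line[0].upper()
                if base not in _BASE_ROW:
                    raise PwmFormatError(
                        f"matrix {matrix_id}: unexpected row starting with {line[0]!r}"
                    )
                body = line[1:].strip().strip("[]").replace("[", " ").replace("]", " ")
                try:
                    values = [float(tok) for tok in body.split()]
                except ValueError as exc:
                    raise PwmFormatError(f"matrix {matrix_id}: bad count row: {line}") from exc
                if base in rows:
                    raise PwmFormatError(f"matrix {matrix_id}: duplicate {base} row")
                rows[base] = values
    if matrix_id is None:
        raise PwmFormatError(f"{path}: no matrices found")
    matrices.append(_finish_matrix(matrix_id, name, rows))
    return matrices


def similarity(
    kmer: str,
    pwm: PositionWeightMatrix,
    offset: int,
    metric: str = "ratio",
) -> float:
    """Similarity of a k-mer aligned at ``offset`` within a PFM.

    Position i of the k-mer aligns to column offset+i; positions where the
    k-mer overhangs the matrix are excluded.  ``metric='ratio'`` averages
    freq(base)/max(column) over the overlap; ``metric='consensus'`` scores
    the fraction of positions where the base attains the column maximum
    (ties count as a match).
    """
    if metric not in ("ratio", "consensus"):
        raise ValueError(f"unknown metric {metric!r}")
    cols = []
    bases = []
    for i, ch in enumerate(kmer):
        j = offset + i
        if 0 <= j < pwm.width:
            if ch not in _BASE_ROW:
                raise ValueError(f"non-ACGT character {ch!r} in k-mer {kmer!r}")
            cols.append(j)
            bases.append(_BASE_ROW[ch])
    if not cols:
        raise ValueError(
            f"k-mer {kmer!r} at offset {offset} does not overlap PWM {pwm.id}"
        )
    sub = pwm.columns[cols]  # (overlap, 4)
    maxima = sub.max(axis=1)
    got = sub[np.arange(len(cols)), bases]
    if metric == "ratio":
        return float(np.mean(got / maxima))
    return float(np.mean(got >= maxima))


def _full_overlap_offsets(k_len: int, width: int) -> range:
    """Offsets where the shorter of (k-mer, PWM) lies fully inside the longer."""
    if k_len <= width:
        return range(0, width - k_len + 1)
    return range(width - k_len, 1)  # negative offsets: PWM inside the k-mer


def scan(
    kmers: Sequence[str],
    pwms: Sequence[PositionWeightMatrix],
    cutoff: float = 0.8,
    metric: str = "ratio",
    both_strands: bool = False,
    min_overlap: Optional[int] = None,
) -> list[PwmHit]:
    """Slide each k-mer against each PFM and report best alignments >= cutoff.

    By default only full-overlap offsets are tried (the shorter sequence
    slides inside the longer); ``min_overlap`` relaxes this to allow
    overhanging alignments with at least that many aligned positions.
    ``both_strands`` also scans each k-mer's reverse complement.  Offset
    ties are broken toward the smallest offset.
    """
    if not pwms:
        raise ValueError("need at least one PWM")
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError(f"cutoff must lie in [0,1], got {cutoff}")
    hits: list[PwmHit] = []
    for kmer in kmers:
        variants = [(kmer, "+")]
        if both_strands:
            variants.append((reverse_complement(kmer), "-"))
        for pwm in pwms:
            best: Optional[tuple[float, int, str]] = None
            for seq, strand in variants:
                if min_overlap is None:
                    offsets = _full_overlap_offsets(len(seq), pwm.width)
                else:
                    lo = min_overlap - len(seq)
                    hi = pwm.width - min_overlap
                    offsets = range(lo, hi + 1)
                for off in offsets:
                    sim = similarity(seq, pwm, off, metric=metric)
                    if best is None or sim > best[0]:
                        best = (sim, off, strand)
            if best is not None and best[0] >= cutoff:
                hits.append(
                    PwmHit(
                        kmer=kmer,
                        pwm_id=pwm.id,
                        pwm_name=pwm.name,
                        offset=best[1],
                        similarity=best[0],
                        strand=best[2],
                    )
                )
    return hits


def write_hits(hits: Sequence[PwmHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("kmer\tpwm_id\tpwm_name\toffset\tsimilarity\tstrand\n")
        for h in hits:
            fh.write(
                f"{h.kmer}\t{h.pwm_id}\t{h.pwm_name}\t{h.offset}\t"
                f"{h.similarity:.6f}\t{h.strand}\n"
            )
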