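"""Selection of biologically relevant k-mers.

A k-mer is called significant for a species when its score exceeds the
species' own mean score plus two standard deviations (upper tail of the
signature's score distribution).  Further filters used in genus-level
comparisons: removal of repetitive k-mers (truncated tilings of 1-3 bp
units), k-mers common to at least half a genus at score >= 0.5, and
abundant high-scoring reverse-complement k-mers (score >= 0.8, occurrence
>= 10,000) that flag repeat-rich genomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from kmersig.scoring import KmerSignature

__all__ = [
    "SignificantKmerSet",
    "significant_kmers",
    "is_repetitive",
    "common_kmers",
    "abundant_high_scoring",
    "reverse_complement",
    "SCORE_2X",
]

# S for a k-mer observed twice as often as expected: (2E-E)/(2E+E) = 1/3.
# Used as a relevance cutoff when comparing against tandem-repeat k-mers.
SCORE_2X = 1.0 / 3.0

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class SignificantKmerSet:
    """K-mers above a species' mean + n*SD score cutoff, sorted by S desc."""

    species_id: str
    cutoff: float
    kmers: tuple[tuple[str, int, float, float], ...]  # (kmer, O, E, S)

    def __len__(self) -> int:
        return len(self.kmers)

    @property
    def min_score(self) -> float:
        """Smallest score among the selected k-mers (nan when empty)."""
        return self.kmers[-1][3] if self.kmers else math.nan


def significant_kmers(
    sig: KmerSignature, sd_mult: float = 2.0, two_sided: bool = False
) -> SignificantKmerSet:
    """K-mers scoring strictly above mean + sd_mult * SD of the signature.

    The mean and (sample) SD are taken over the full signature.  With
    ``two_sided`` the lower tail (S < mean - sd_mult*SD) is included too.
    """
    if len(sig) < 2:
        raise ValueError("signature needs >= 2 entries for an SD-based cutoff")
    scores = sig.scores
    mean = float(scores.mean())
    sd = float(scores.std(ddof=1))
    cutoff = mean + sd_mult * sd
    mask = scores > cutoff
    if two_sided:
        mask |= scores < mean - sd_mult * sd
    idx = np.flatnonzero(mask)
    idx = idx[np.argsort(-scores[idx], kind="stable")]
    if sig.has_occurrences:
        rows = tuple(
            (str(sig.kmers[i]), int(sig.observed[i]), float(sig.expected[i]), float(scores[i]))
            for i in idx
        )
    else:
        rows = tuple((str(sig.kmers[i]), 0, 0.0, float(scores[i])) for i in idx)
    return SignificantKmerSet(species_id=sig.species_id, cutoff=cutoff, kmers=rows)


def is_repetitive(kmer: str) -> bool:
    """True iff the k-mer is a truncated tiling of a 1, 2 or 3 bp unit.

    I.e. kmer[i] == kmer[i mod p] for some period p in {1, 2, 3} — a
    homopolymer, dimer repeat or trimer repeat in the filtering sense.
    """
    for p in (1, 2, 3):
        if all(kmer[i] == kmer[i % p] for i in range(len(kmer))):
            return True
    return False


def common_kmers(
    signatures: Sequence[KmerSignature],
    min_score: float = 0.5,
    min_fraction: float = 0.5,
    exclude_repeats: bool = True,
) -> set[str]:
    """K-mers at S >= min_score in at least ceil(min_fraction * n) signatures.

    The defaults select k-mers occurring at least three times more often
    than expected (S >= 0.5) in at least half of a genus's species, with
    dimer/trimer repeats removed.
    """
    if not signatures:
        raise ValueError("need at least one signature")
    ks = {s.k for s in signatures}
    if len(ks) != 1:
        raise ValueError(f"signatures mix k values: {sorted(ks)}")
    need = math.ceil(min_fraction * len(signatures))
    counts: dict[str, int] = {}
    for sig in signatures:
        for km in sig.kmers[sig.scores >= min_score]:
            counts[str(km)] = counts.get(str(km), 0) + 1
    result = {km for km, c in counts.items() if c >= need}
    if exclude_repeats:
        result = {km for km in result if not is_repetitive(km)}
    return result


def reverse_complement(kmer: str) -> str:
    """Watson-Crick reverse complement of an ACGT string."""
    if any(ch not in "ACGT" for ch in kmer):
        raise ValueError(f"non-ACGT character in k-mer {kmer!r}")
    return kmer.translate(_COMPLEMENT)[::-1]


def abundant_high_scoring(
    sig: KmerSignature,
    min_score: float = 0.8,
    min_occurrence: int = 10000,
    require_revcomp_pair: bool = False,
) -> set[str]:
    """K-mers with S >= min_score and O >= min_occurrence.

    These abundant high-scoring k-mers (and their reverse complements) mark
    repeat-rich genomes whose CC values with other species are skewed.  With
    ``require_revcomp_pair`` a k-mer is kept only if its reverse complement
    also passes both thresholds (a palindrome is its own partner).
    """
    if not sig.has_occurrences:
        raise ValueError(
            "signature lacks observed counts (legacy two-column file?)"
        )
    mask = (sig.scores >= min_score) & (sig.observed >= min_occurrence)
    passing = {str(km) for km in sig.kmers[mask]}
    if require_revcomp_pair:
        passing = {km for km in passing if reverse_complement(km) in passing}
    return passing
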