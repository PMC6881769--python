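"""K-mer enumeration and the normalized over/under-representation score.

For a sequence set with background base fractions p_A..p_T, the expected
probability of a k-mer is the product of its per-position base fractions
(zero-order Markov model), the expected occurrence is E = l * P, and each
k-mer is scored

    S = (O - E) / (O + E)

which maps extreme over-representation to +1, absence despite expectation
to -1 and random occurrence to ~0.  The full set of scores over the 4^k
motifome is the species' k-mer signature (the WGKS for whole genomes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from kmersig.sequence_io import (
    BASES,
    CompositionProfile,
    SequenceRecord,
    compute_composition,
    count_valid_windows,
    encode_bases,
)

__all__ = [
    "KmerSignature",
    "SignatureFormatError",
    "expected_probability",
    "expected_occurrence",
    "score_kmer",
    "build_signature",
    "write_signature",
    "read_signature",
    "codes_to_kmers",
    "kmer_to_code",
    "revcomp_codes",
]

_LETTERS = np.array(list(BASES), dtype="U1")


class SignatureFormatError(ValueError):
    """Malformed signature file."""


def kmer_to_code(kmer: str) -> int:
    """Lexicographic rank of an ACGT k-mer (A<C<G<T)."""
    code = 0
    for ch in kmer:
        idx = BASES.find(ch)
        if idx < 0:
            raise ValueError(f"non-ACGT character {ch!r} in k-mer {kmer!r}")
        code = code * 4 + idx
    return code


def codes_to_kmers(codes: np.ndarray, k: int) -> np.ndarray:
    """Decode integer k-mer ranks back to strings (vectorized)."""
    codes = np.asarray(codes, dtype=np.int64)
    chars = np.empty((codes.size, k), dtype="U1")
    for j in range(k):
        chars[:, j] = _LETTERS[(codes >> (2 * (k - 1 - j))) & 3]
    return np.ascontiguousarray(chars).view(f"U{k}").ravel()


def revcomp_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Integer ranks of the reverse complements of encoded k-mers."""
    codes = np.asarray(codes, dtype=np.int64)
    rc = np.zeros_like(codes)
    for j in range(k):
        digit = (codes >> (2 * (k - 1 - j))) & 3
        rc += (3 - digit) << (2 * j)
    return rc


@dataclass
class KmerSignature:
    """Per-species map from k-mers to (observed, expected, score).

    Entries are sorted lexicographically (A<C<G<T).  ``observed`` and
    ``expected`` are ``None`` for signatures read from legacy two-column
    (kmer, score) files, which remain usable for correlation only.
    """

    species_id: str
    k: int
    region_label: str
    l_used: int
    composition: CompositionProfile
    kmers: np.ndarray  # dtype U{k}, sorted
    scores: np.ndarray  # float64, in [-1, 1]
    observed: Optional[np.ndarray] = None  # int64
    expected: Optional[np.ndarray] = None  # float64

    def __post_init__(self) -> None:
        if self.kmers.size != self.scores.size:
            raise ValueError("kmers and scores must have equal length")
        if self.kmers.size and (
            self.scores.min() < -1.0 - 1e-12 or self.scores.max() > 1.0 + 1e-12
        ):
            raise ValueError("scores must lie in [-1, 1]")

    def __len__(self) -> int:
        return int(self.kmers.size)

    @property
    def has_occurrences(self) -> bool:
        return self.observed is not None and self.expected is not None

    @property
    def entries(self) -> dict[str, tuple[Optional[int], Optional[float], float]]:
        """kmer -> (O, E, S) mapping; O and E are None for legacy signatures."""
        if self.has_occurrences:
            return {
                km: (int(o), float(e), float(s))
                for km, o, e, s in zip(
                    self.kmers, self.observed, self.expected, self.scores
                )
            }
        return {km: (None, None, float(s)) for km, s in zip(self.kmers, self.scores)}


def expected_probability(composition: CompositionProfile, kmer: str) -> float:
    """Probability of a k-mer under the zero-order Markov background.

    Product of per-position base fractions.  Computed as an exp of summed
    logs for very long k-mers (k > 12) to dodge underflow; a plain product
    is exact for the k <= 9 range used in practice.
    """
    fractions = composition.fractions
    idxs = []
    for ch in kmer:
        idx = BASES.find(ch)
        if idx < 0:
            raise ValueError(f"non-ACGT character {ch!r} in k-mer {kmer!r}")
        idxs.append(idx)
    if len(kmer) > 12:
        if any(fractions[i] == 0.0 for i in idxs):
            return 0.0
        return math.exp(sum(math.log(fractions[i]) for i in idxs))
    p = 1.0
    for i in idxs:
        p *= fractions[i]
    return p


def expected_occurrence(p: float, l_used: int) -> float:
    """Expected occurrence E = l * P of a k-mer in l usable windows."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability must lie in [0,1], got {p}")
    if l_used < 0:
        raise ValueError(f"l_used must be non-negative, got {l_used}")
    return l_used * p


def score_kmer(O: float, E: float) -> float:
    """Normalized over/under-representation score S = (O-E)/(O+E).

    S -> 1 for strong over-representation, S -> -1 for absence despite
    expectation, S ~ 0 when observed matches expected.  Undefined (error)
    when O = E = 0; such k-mers are dropped from signatures.
    """
    if O < 0 or E < 0:
        raise ValueError("occurrences must be non-negative")
    denom = O + E
    if denom == 0:
        raise ValueError("score undefined for O = E = 0")
    return (O - E) / denom


def _count_kmers(records: Sequence[SequenceRecord], k: int) -> np.ndarray:
    """Observed occurrence of every k-mer (overlapping, forward strand)."""
    counts = np.zeros(4**k, dtype=np.int64)
    for rec in records:
        codes = encode_bases(rec.seq).astype(np.int64)
        n = codes.size
        if n < k:
            continue
        m = n - k + 1
        vals = np.zeros(m, dtype=np.int64)
        valid = np.ones(m, dtype=bool)
        for j in range(k):
            window = codes[j : j + m]
            valid &= window >= 0
            vals += window << (2 * (k - 1 - j))
        counts += np.bincount(vals[valid], minlength=4**k)
    return counts


def _expected_vector(composition: CompositionProfile, k: int) -> np.ndarray:
    """P_expected for every k-mer in lexicographic order."""
    fractions = np.asarray(composition.fractions)
    idx = np.arange(4**k, dtype=np.int64)
    p = np.ones(4**k, dtype=np.float64)
    for j in range(k):
        p *= fractions[(idx >> (2 * (k - 1 - j))) & 3]
    return p


def build_signature(
    records: Sequence[SequenceRecord],
    k: int,
    species_id: str,
    region_label: str = "whole_genome",
    length_mode: str = "valid_windows",
    canonical: bool = False,
) -> KmerSignature:
    """Count, model and score every k-mer of a sequence set.

    O is counted in a single overlapping pass over the forward strand of
    each record (windows containing ambiguous bases are skipped and never
    span record boundaries).  E comes from the records' own composition.
    ``length_mode='valid_windows'`` (default) uses the number of unambiguous
    windows as l, which makes sum(E) equal sum(O); ``'raw'`` uses the raw
    sequence length instead.  ``canonical=True`` collapses each k-mer with
    its reverse complement (summing both O and E onto the lexicographically
    smaller of the pair).

    K-mers with O = 0 and E = 0 (possible when a base fraction is zero) are
    dropped; that absent-key state is what the correlation step treats as a
    missing k-mer.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if not records:
        raise ValueError("build_signature requires at least one record")
    if length_mode not in ("valid_windows", "raw"):
        raise ValueError(f"unknown length_mode {length_mode!r}")

    composition = compute_composition(records)
    n_windows = count_valid_windows(records, k)
    if n_windows == 0:
        raise ValueError("no valid k-mer windows in input (sequences too short or ambiguous)")
    l_used = n_windows if length_mode == "valid_windows" else composition.total_raw

    observed = _count_kmers(records, k)
    expected = l_used * _expected_vector(composition, k)

    if canonical:
        codes = np.arange(4**k, dtype=np.int64)
        rc = revcomp_codes(codes, k)
        keep = codes <= rc
        # sum the pair onto the canonical representative; palindromes map to
        # themselves and must not be doubled
        obs_c = observed[keep] + np.where(rc[keep] != codes[keep], observed[rc[keep]], 0)
        exp_c = expected[keep] + np.where(rc[keep] != codes[keep], expected[rc[keep]], 0.0)
        codes, observed, expected = codes[keep], obs_c, exp_c
    else:
        codes = np.arange(4**k, dtype=np.int64)

    present = (observed > 0) | (expected > 0)
    codes, observed, expected = codes[present], observed[present], expected[present]
    scores = (observed - expected) / (observed + expected)

    return KmerSignature(
        species_id=species_id,
        k=k,
        region_label=region_label,
        l_used=int(l_used),
        composition=composition,
        kmers=codes_to_kmers(codes, k),
        scores=scores,
        observed=observed,
        expected=expected,
    )


def write_signature(sig: KmerSignature, path) -> None:
    """Write a signature as TSV with a commented header.

    Header lines carry species, k, region, l_used and the composition; rows
    are ``kmer  observed  expected  score`` sorted lexicographically.
    """
    fr = sig.composition.fractions
    with open(path, "w") as fh:
        fh.write(f"#species={sig.species_id}\n")
        fh.write(f"#k={sig.k}\n")
        fh.write(f"#region={sig.region_label}\n")
        fh.write(f"#l_used={sig.l_used}\n")
        fh.write(
            f"#pA={fr[0]:.12e} pC={fr[1]:.12e} pG={fr[2]:.12e} pT={fr[3]:.12e}\n"
        )
        fh.write("kmer\tobserved\texpected\tscore\n")
        if sig.has_occurrences:
            for km, o, e, s in zip(sig.kmers, sig.observed, sig.expected, sig.scores):
                fh.write(f"{km}\t{int(o)}\t{e:.12e}\t{s:.12e}\n")
        else:
            for km, s in zip(sig.kmers, sig.scores):
                fh.write(f"{km}\t\t\t{s:.12e}\n")


def _parse_header(lines: list[str], path) -> dict:
    meta: dict = {}
    for line in lines:
        body = line[1:].strip()
        if body.startswith("pA="):
            parts = dict(item.split("=", 1) for item in body.split())
            meta["fractions"] = tuple(float(parts[key]) for key in ("pA", "pC", "pG", "pT"))
        elif "=" in body:
            key, val = body.split("=", 1)
            meta[key.strip()] = val.strip()
    return meta


def read_signature(path) -> KmerSignature:
    """Read a signature TSV (full four-column or legacy two-column format).

    Legacy ``kmer<TAB>score`` files load with O and E absent and remain
    usable for correlation only.
    """
    header_lines: list[str] = []
    rows: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                header_lines.append(line)
            else:
                rows.append(line.split("\t"))
    if not rows:
        raise SignatureFormatError(f"{path}: no data rows")

    # skip a column-header row if present
    if rows and rows[0][0] == "kmer":
        rows = rows[1:]
    if not rows:
        raise SignatureFormatError(f"{path}: no k-mer rows")

    meta = _parse_header(header_lines, path)
    legacy = len(rows[0]) == 2 or (len(rows[0]) == 4 and rows[0][1] == "")

    kmers: list[str] = []
    observed: list[int] = []
    expected: list[float] = []
    scores: list[float] = []
    k = len(rows[0][0])
    seen: set[str] = set()
    for row in rows:
        km = row[0]
        if len(km) != k or any(ch not in BASES for ch in km):
            raise SignatureFormatError(f"{path}: bad k-mer {km!r} (expected length {k})")
        if km in seen:
            raise SignatureFormatError(f"{path}: duplicate k-mer {km!r}")
        seen.add(km)
        kmers.append(km)
        if legacy:
            scores.append(float(row[-1]))
        else:
            if len(row) != 4:
                raise SignatureFormatError(f"{path}: expected 4 columns, got {len(row)}")
            observed.append(int(row[1]))
            expected.append(float(row[2]))
            scores.append(float(row[3]))

    if "fractions" in meta:
        pa, pc, pg, pt = meta["fractions"]
        # renormalize: fractions were printed at finite precision
        tot = pa + pc + pg + pt
        composition = CompositionProfile(pa / tot, pc / tot, pg / tot, pt / tot)
    else:
        composition = CompositionProfile(0.25, 0.25, 0.25, 0.25)

    order = np.argsort(np.asarray(kmers))
    kmers_arr = np.asarray(kmers, dtype=f"U{k}")[order]
    scores_arr = np.asarray(scores, dtype=np.float64)[order]
    sig = KmerSignature(
        species_id=meta.get("species", "unknown"),
        k=int(meta.get("k", k)),
        region_label=meta.get("region", "whole_genome"),
        l_used=int(meta.get("l_used", 0)),
        composition=composition,
        kmers=kmers_arr,
        scores=scores_arr,
        observed=None if legacy else np.asarray(observed, dtype=np.int64)[order],
        expected=None if legacy else np.asarray(expected, dtype=np.float64)[order],
    )
    if sig.k != k:
        raise SignatureFormatError(
            f"{path}: header k={sig.k} does not match k-mer length {k}"
        )
    return sig
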