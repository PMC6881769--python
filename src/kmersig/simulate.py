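"""Synthetic genomes with controlled composition, planted k-mers and clades.

The generator emulates the study conditions the pipeline is meant for:
i.i.d. background sequence at a target base composition, specific k-mers
planted at a chosen multiple of their expected occurrence (replacing
background bases so total length stays fixed), tandem-repeat blocks, and a
clade structure produced by point substitutions from shared ancestors
(within-clade divergence < between-clade divergence).  All randomness flows
from a single seed through numpy SeedSequence spawn keys, so each genome is
reproducible independently of the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from kmersig.sequence_io import BASES, SequenceRecord

__all__ = [
    "FixtureSpec",
    "CladeSpec",
    "generate_genome",
    "evolve_clades",
    "clade_groups",
    "add_repeat_plants",
]

_LETTERS = np.array(list(BASES), dtype="U1")
_UNIFORM = (0.25, 0.25, 0.25, 0.25)


@dataclass(frozen=True)
class CladeSpec:
    """One clade: its label, size and divergence rates (subs per site)."""

    label: str
    n_species: int
    within_divergence: float
    between_divergence: float

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError(f"clade {self.label}: n_species must be >= 1")
        for rate in (self.within_divergence, self.between_divergence):
            if not 0.0 <= rate <= 0.75:
                raise ValueError(
                    f"clade {self.label}: divergence rates must lie in [0, 0.75]"
                )


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic genome or clade set."""

    seed: int
    length: int
    composition: tuple[float, float, float, float] = _UNIFORM
    plants: tuple[tuple[str, float], ...] = ()
    repeat_plants: tuple[tuple[str, int], ...] = ()
    clades: Optional[tuple[CladeSpec, ...]] = None

    def __post_init__(self) -> None:
        if abs(sum(self.composition) - 1.0) > 1e-9:
            raise ValueError("composition fractions must sum to 1")
        for kmer, mult in self.plants:
            if mult <= 0:
                raise ValueError(f"plant {kmer!r}: multiplier must be > 0")
            if any(ch not in BASES for ch in kmer):
                raise ValueError(f"plant {kmer!r}: non-ACGT characters")
            if self.length < 100 * len(kmer):
                raise ValueError(
                    f"length {self.length} too short for planted {len(kmer)}-mers "
                    f"(need >= {100 * len(kmer)})"
                )
        for unit, copies in self.repeat_plants:
            if copies < 1:
                raise ValueError(f"repeat {unit!r}: copies must be >= 1")
            if any(ch not in BASES for ch in unit):
                raise ValueError(f"repeat {unit!r}: non-ACGT characters")

    @classmethod
    def from_dict(cls, data: dict) -> "FixtureSpec":
        clades = data.get("clades")
        return cls(
            seed=int(data["seed"]),
            length=int(data["length"]),
            composition=tuple(data.get("composition", _UNIFORM)),
            plants=tuple(
                (str(p["kmer"]), float(p["multiplier"])) for p in data.get("plants", [])
            ),
            repeat_plants=tuple(
                (str(r["unit"]), int(r["copies"]))
                for r in data.get("repeat_plants", [])
            ),
            clades=tuple(
                CladeSpec(
                    label=str(c["label"]),
                    n_species=int(c["n_species"]),
                    within_divergence=float(c["within_divergence"]),
                    between_divergence=float(c["between_divergence"]),
                )
                for c in clades
            )
            if clades
            else None,
        )


def _rng(seed: int, *spawn_key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=spawn_key))


def _encode_str(s: str) -> np.ndarray:
    return np.array([BASES.index(ch) for ch in s], dtype=np.int8)


def _codes_to_record(codes: np.ndarray, rec_id: str) -> SequenceRecord:
    chars = _LETTERS[codes]
    seq = np.ascontiguousarray(chars).view(f"U{codes.size}")[0]
    return SequenceRecord(id=rec_id, seq=str(seq))


def _place_block(
    codes: np.ndarray,
    occupied: np.ndarray,
    block: np.ndarray,
    rng: np.random.Generator,
) -> None:
    """Overwrite background bases with one block at a random free position."""
    length = codes.size
    width = block.size
    if width > length:
        raise ValueError("planted block longer than the genome")
    for _ in range(10000):
        start = int(rng.integers(0, length - width + 1))
        if not occupied[start : start + width].any():
            codes[start : start + width] = block
            occupied[start : start + width] = True
            return
    raise ValueError("could not place a planted block: genome capacity exceeded")


def _plant_all(
    codes: np.ndarray,
    spec: FixtureSpec,
    rng: np.random.Generator,
) -> None:
    fractions = np.asarray(spec.composition)
    total_bp = sum(
        len(kmer) * int(round(mult * spec.length * np.prod(fractions[_encode_str(kmer)])))
        for kmer, mult in spec.plants
    ) + sum(len(unit) * copies for unit, copies in spec.repeat_plants)
    if total_bp > spec.length:
        raise ValueError(
            f"plants need {total_bp} bp but the genome is only {spec.length} bp"
        )
    occupied = np.zeros(spec.length, dtype=bool)
    for kmer, mult in spec.plants:
        block = _encode_str(kmer)
        p_kmer = float(np.prod(fractions[block]))
        n_copies = int(round(mult * spec.length * p_kmer))
        for _ in range(n_copies):
            _place_block(codes, occupied, block, rng)
    for unit, copies in spec.repeat_plants:
        block = np.tile(_encode_str(unit), copies)
        _place_block(codes, occupied, block, rng)


def generate_genome(spec: FixtureSpec) -> list[SequenceRecord]:
    """One synthetic genome: i.i.d. background plus planted k-mers/repeats.

    Each planted k-mer is written at non-overlapping random positions until
    its copy number reaches ``multiplier`` times its expected occurrence
    under the background model (insertion replaces background bases, so the
    total length is unchanged).  Deterministic given the spec's seed.
    """
    rng = _rng(spec.seed, 0)
    codes = rng.choice(4, size=spec.length, p=spec.composition).astype(np.int8)
    _plant_all(codes, spec, _rng(spec.seed, 1))
    return [_codes_to_record(codes, "seq1")]


def add_repeat_plants(
    records: Sequence[SequenceRecord],
    repeat_plants: Sequence[tuple[str, int]],
    seed: int,
) -> list[SequenceRecord]:
    """Overwrite random stretches of existing records with tandem repeats.

    Used to emulate a repeat-rich genome inside an otherwise ordinary clade
    (the scenario where abundant high-scoring k-mers skew CC values).
    """
    rng = _rng(seed, 99)
    out: list[SequenceRecord] = []
    for rec in records:
        codes = _encode_str(rec.seq)
        occupied = np.zeros(codes.size, dtype=bool)
        for unit, copies in repeat_plants:
            block = np.tile(_encode_str(unit), copies)
            _place_block(codes, occupied, block, rng)
        out.append(_codes_to_record(codes, rec.id))
    return out


def _mutate(
    codes: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Point substitutions at the given per-site rate (substituted sites
    always change base, drawn uniformly from the other three)."""
    if rate == 0.0:
        return codes.copy()
    n_sub = rng.binomial(codes.size, rate)
    if n_sub == 0:
        return codes.copy()
    out = codes.copy()
    pos = rng.choice(codes.size, size=n_sub, replace=False)
    out[pos] = (out[pos] + rng.integers(1, 4, size=n_sub)) % 4
    return out


def evolve_clades(spec: FixtureSpec) -> dict[str, list[SequenceRecord]]:
    """Clade-structured species set by point substitutions from a root.

    Each clade ancestor diverges from a common root genome at that clade's
    between-clade rate; each species diverges from its clade ancestor at the
    within-clade rate.  Requires within < between for every clade (the
    all-zero degenerate case — identical genomes everywhere — is allowed),
    otherwise the clade structure would be uninterpretable.
    """
    if not spec.clades:
        raise ValueError("spec has no clades")
    for clade in spec.clades:
        if clade.between_divergence > 0 and (
            clade.within_divergence >= clade.between_divergence
        ):
            raise ValueError(
                f"clade {clade.label}: within-divergence must be < between-divergence"
            )
    root_rng = _rng(spec.seed, 0)
    root = root_rng.choice(4, size=spec.length, p=spec.composition).astype(np.int8)

    genomes: dict[str, list[SequenceRecord]] = {}
    for ci, clade in enumerate(spec.clades):
        ancestor = _mutate(root, clade.between_divergence, _rng(spec.seed, 10 + ci))
        for si in range(clade.n_species):
            species_id = f"{clade.label}_{si + 1:02d}"
            codes = _mutate(
                ancestor, clade.within_divergence, _rng(spec.seed, 10 + ci, si)
            )
            genomes[species_id] = [_codes_to_record(codes, "seq1")]
    return genomes


def clade_groups(spec: FixtureSpec) -> dict[str, str]:
    """species_id -> clade label map matching :func:`evolve_clades`."""
    if not spec.clades:
        raise ValueError("spec has no clades")
    return {
        f"{clade.label}_{si + 1:02d}": clade.label
        for clade in spec.clades
        for si in range(clade.n_species)
    }
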