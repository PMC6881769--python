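"""Pairwise Pearson correlation of k-mer signatures and group statistics.

Two species are compared by the Pearson correlation coefficient (CC) of
their k-mer scores over the k-mers present in both signatures; k-mers
missing from either are omitted.  The symmetric all-versus-all CC matrix is
the basis for clustering, and group-level contrasts (within genus vs.
between genera) are tested with Welch's t-test and sized with Cohen's d.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from kmersig.scoring import KmerSignature

__all__ = [
    "CorrelationMatrix",
    "GroupSummary",
    "GroupTestResult",
    "Comparison",
    "pairwise_cc",
    "cc_matrix",
    "pair_count",
    "group_summaries",
    "welch_cohen",
    "write_cc_matrix",
    "read_cc_matrix",
]


@dataclass
class CorrelationMatrix:
    """Symmetric species x species Pearson CC matrix."""

    species: list[str]
    values: np.ndarray
    k: int
    region_label: str = "whole_genome"

    def __post_init__(self) -> None:
        n = len(self.species)
        if self.values.shape != (n, n):
            raise ValueError("values shape must match the species list")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 1.0):
            raise ValueError("correlation matrix diagonal must be 1")
        if self.values.min() < -1 - 1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("correlation values must lie in [-1, 1]")

    def cc(self, a: str, b: str) -> float:
        i, j = self.species.index(a), self.species.index(b)
        return float(self.values[i, j])


@dataclass(frozen=True)
class GroupSummary:
    """Distribution summary of a set of pairwise CC values."""

    label: str
    min: float
    median: float
    mean: float
    max: float
    sd: float
    n_comparisons: int


@dataclass(frozen=True)
class GroupTestResult:
    """Welch's t-test plus Cohen's d (with 95% CI) for two CC sets."""

    t_statistic: float
    p_value: float
    cohens_d: float
    d_ci_low: float
    d_ci_high: float
    n1: int
    n2: int


@dataclass(frozen=True)
class Comparison:
    """Which pairwise CC values to summarize.

    kind 'within': the n(n-1)/2 unordered pairs inside ``group``.
    kind 'between': all |G1| x |G2| cross pairs of ``group`` and ``other``.
    kind 'complement': all unordered pairs among species NOT in ``group``
    (a Table-2 style 'non-X' row).
    """

    kind: str
    group: str
    other: Optional[str] = None
    label: str = field(default="")

    def __post_init__(self) -> None:
        if self.kind not in ("within", "between", "complement"):
            raise ValueError(f"unknown comparison kind {self.kind!r}")
        if self.kind == "between" and self.other is None:
            raise ValueError("'between' comparison needs a second group")
        if not self.label:
            default = {
                "within": self.group,
                "between": f"{self.group} vs. {self.other}",
                "complement": f"non-{self.group}",
            }[self.kind]
            object.__setattr__(self, "label", default)


def pairwise_cc(
    sig_a: KmerSignature,
    sig_b: KmerSignature,
    omit_zero_observed: bool = False,
) -> float:
    """Pearson CC of two score vectors over their shared k-mers.

    K-mers missing from either signature are omitted.  With
    ``omit_zero_observed`` k-mers with O = 0 in either signature are also
    dropped from the intersection (stricter reading of 'missing'); by
    default they stay, since their S = -1 is informative.
    """
    if sig_a.k != sig_b.k:
        raise ValueError(f"k mismatch: {sig_a.k} vs {sig_b.k}")
    # kmers arrays are sorted and unique
    shared, ia, ib = np.intersect1d(
        sig_a.kmers, sig_b.kmers, assume_unique=True, return_indices=True
    )
    xs, ys = sig_a.scores[ia], sig_b.scores[ib]
    if omit_zero_observed:
        if not (sig_a.has_occurrences and sig_b.has_occurrences):
            raise ValueError("omit_zero_observed needs signatures with O values")
        keep = (sig_a.observed[ia] > 0) & (sig_b.observed[ib] > 0)
        xs, ys = xs[keep], ys[keep]
    if xs.size < 3:
        raise ValueError(
            f"undefined correlation: only {xs.size} shared k-mers (need >= 3)"
        )
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise ValueError("undefined correlation: zero variance in a score vector")
    r, _ = stats.pearsonr(xs, ys)
    return float(r)


def cc_matrix(
    signatures: Sequence[KmerSignature],
    omit_zero_observed: bool = False,
) -> CorrelationMatrix:
    """All-versus-all CC matrix over >= 2 same-k signatures."""
    if len(signatures) < 2:
        raise ValueError("need at least 2 signatures")
    ids = [s.species_id for s in signatures]
    if len(set(ids)) != len(ids):
        dupes = sorted({x for x in ids if ids.count(x) > 1})
        raise ValueError(f"duplicate species ids: {dupes}")
    ks = {s.k for s in signatures}
    if len(ks) != 1:
        raise ValueError(f"signatures mix k values: {sorted(ks)}")
    n = len(signatures)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            r = pairwise_cc(signatures[i], signatures[j], omit_zero_observed)
            values[i, j] = values[j, i] = r
    return CorrelationMatrix(
        species=list(ids),
        values=values,
        k=signatures[0].k,
        region_label=signatures[0].region_label,
    )


def pair_count(n: int) -> int:
    """Number of distinct unordered pairs among n species: n(n-1)/2."""
    if n < 2:
        raise ValueError(f"need n >= 2 species, got {n}")
    return n * (n - 1) // 2


def _summary(label: str, vals: np.ndarray) -> GroupSummary:
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return GroupSummary(
        label=label,
        min=float(vals.min()),
        median=float(np.median(vals)),
        mean=float(vals.mean()),
        max=float(vals.max()),
        sd=sd,
        n_comparisons=int(vals.size),
    )


def comparison_values(
    matrix: CorrelationMatrix,
    groups: Mapping[str, str],
    spec: Comparison,
) -> np.ndarray:
    """The pairwise CC values selected by one comparison spec."""
    for sp in matrix.species:
        if sp not in groups:
            raise ValueError(f"species {sp!r} has no group assignment")
    idx_of = {sp: i for i, sp in enumerate(matrix.species)}
    if spec.kind == "within":
        members = [idx_of[s] for s in matrix.species if groups[s] == spec.group]
        pairs = [(a, b) for ii, a in enumerate(members) for b in members[ii + 1 :]]
    elif spec.kind == "between":
        g1 = [idx_of[s] for s in matrix.species if groups[s] == spec.group]
        g2 = [idx_of[s] for s in matrix.species if groups[s] == spec.other]
        pairs = [(a, b) for a in g1 for b in g2]
    else:  # complement: all unordered pairs among species not in the group
        rest = [idx_of[s] for s in matrix.species if groups[s] != spec.group]
        pairs = [(a, b) for ii, a in enumerate(rest) for b in rest[ii + 1 :]]
    if not pairs:
        raise ValueError(f"comparison {spec.label!r} selects no species pairs")
    return np.array([matrix.values[a, b] for a, b in pairs])


def group_summaries(
    matrix: CorrelationMatrix,
    groups: Mapping[str, str],
    comparisons: Sequence[Comparison],
) -> list[GroupSummary]:
    """Min/median/mean/max/SD/n for each requested comparison."""
    return [
        _summary(spec.label, comparison_values(matrix, groups, spec))
        for spec in comparisons
    ]


def welch_cohen(
    group1_ccs: Sequence[float], group2_ccs: Sequence[float]
) -> GroupTestResult:
    """Welch's t-test (unequal variance) plus Cohen's d for two CC sets.

    d uses the pooled (n-1-weighted) SD; its 95% CI uses the standard
    normal-approximation variance Var(d) = (n1+n2)/(n1*n2) + d^2/(2(n1+n2)).
    """
    x = np.asarray(group1_ccs, dtype=float)
    y = np.asarray(group2_ccs, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("CC values must be finite")
    t, p = stats.ttest_ind(x, y, equal_var=False)
    n1, n2 = x.size, y.size
    s1, s2 = x.var(ddof=1), y.var(ddof=1)
    pooled = np.sqrt(((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2))
    d = 0.0 if pooled == 0 else float((x.mean() - y.mean()) / pooled)
    var_d = (n1 + n2) / (n1 * n2) + d * d / (2 * (n1 + n2))
    half = 1.959963984540054 * np.sqrt(var_d)
    return GroupTestResult(
        t_statistic=float(t),
        p_value=float(p),
        cohens_d=d,
        d_ci_low=d - half,
        d_ci_high=d + half,
        n1=int(n1),
        n2=int(n2),
    )


def write_cc_matrix(matrix: CorrelationMatrix, path) -> None:
    """Square TSV with species ids as header row and column, 6 decimals."""
    df = pd.DataFrame(matrix.values, index=matrix.species, columns=matrix.species)
    with open(path, "w") as fh:
        fh.write(f"#k={matrix.k}\n#region={matrix.region_label}\n")
        df.to_csv(fh, sep="\t", float_format="%.6f")


def read_cc_matrix(path) -> CorrelationMatrix:
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for line in lines:
        if not line.startswith("#"):
            break
        key, _, val = line[1:].strip().partition("=")
        meta[key] = val
        body_start += 1
    df = pd.read_csv(io.StringIO("".join(lines[body_start:])), sep="\t", index_col=0)
    values = df.to_numpy(dtype=float)
    values = (values + values.T) / 2.0  # heal 6-decimal rounding asymmetry
    np.fill_diagonal(values, 1.0)
    return CorrelationMatrix(
        species=[str(s) for s in df.index],
        values=values,
        k=int(meta.get("k", 0)),
        region_label=meta.get("region", "whole_genome"),
    )
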