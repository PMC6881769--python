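# Methods

## Model

`kmersig` compares genomes (or subgenomic sequence sets such as 5′UTR, 3′UTR
or intron collections) by their **k-mer signatures**: for every one of the
4^k lexicographically possible k-mers, the observed occurrence *O* is counted
in a single overlapping pass over the forward strand, the expected occurrence
is computed from a zero-order Markov background,

    P_expected = ∏ᵢ p_i          (product of per-position base fractions)
    E = l · P_expected,

and each k-mer receives the normalized score

    S = (O − E) / (O + E) ∈ [−1, 1].

S → 1 marks strong over-representation, S → −1 absence despite expectation,
S ≈ 0 random occurrence. Useful reference points on this scale: a k-mer
observed at exactly twice its expectation scores 1/3 (≈0.333), and at three
times its expectation exactly 0.5. Two species are compared by the Pearson
correlation coefficient (CC) of their score vectors over the k-mers present
in both signatures; 1 − CC is the distance used for UPGMA/WPGMA/NJ trees and
heatmap ordering.

## Assumptions and conventions

- **Background model** is zero-order (single-base composition). Higher-order
  Markov backgrounds would absorb dinucleotide biases into E; they are out of
  scope by design — the signature is meant to *capture* such biases.
- **Ambiguous bases** (N and IUPAC codes) are excluded from the composition
  and break k-mer windows; windows never span record (contig) boundaries.
  Soft-masked lowercase bases are uppercased and counted, since discarding
  them would silently change every count; `--length-mode`/`--canonical`
  flags expose the main alternatives rather than guessing.
- **Genome length l.** The "length of the genome" multiplying P_expected is
  taken as the number of valid (all-ACGT) k-mer windows, not the raw base
  count. This makes ΣE = ΣO hold exactly — a conservation law the raw length
  only approximates — and both quantities are asserted on every build.
  `length_mode="raw"` reproduces the literal raw-length reading.
- **Strand.** Counting is forward-strand only by default. Reverse-complement
  structure is analyzed downstream (`abundant_high_scoring`,
  `require_revcomp_pair`); `canonical=True` optionally collapses each k-mer
  with its reverse complement at build time.
- **Missing k-mers.** A k-mer with O = 0 and E = 0 (possible when a base
  fraction is zero) is dropped from the signature; the correlation step
  omits k-mers absent from either signature. K-mers with O = 0 but E > 0
  stay (S = −1 is informative); `omit_zero_observed=True` implements the
  stricter reading that drops them from the intersection.

## Parameters

| parameter | default | meaning |
|---|---|---|
| k | 8 | k-mer length; 7–9 brackets the typical core TFBS length (±1 wobble) |
| sd_mult | 2.0 | significance cutoff mean + 2·SD over a species' scores (upper tail; ~2.5% of a normal distribution) |
| min_score | 0.5 | common-k-mer score threshold = 3× over-representation |
| min_fraction | 0.5 | fraction of a genus required to share a common k-mer (ceiling rule: ≥ ⌈n/2⌉ species) |
| min_occurrence | 10,000 | occurrence floor for "abundant high-scoring" k-mers on whole genomes |
| pwm_cutoff | 0.8 | PWM match similarity threshold (80% sequence similarity) |

The mean+2SD cutoff is one-sided (upper tail): the selection targets
over-represented k-mers and their minimum selected scores are positive;
`two_sided=True` returns the depleted tail as well. The SD is the sample
(n−1) standard deviation throughout.

## PWM matching

JASPAR-style position frequency matrices are normalized to column
frequencies. A candidate k-mer is slid against each matrix through all
full-overlap offsets (the shorter of the two inside the longer). Similarity
at an offset is the mean over aligned positions of
freq(base)/max(column) — on a one-hot matrix this is percent identity to the
consensus, which is the most defensible reading of "sequence similarity"
against a PFM. The alternative `metric="consensus"` scores strict identity
to the column-max base (ties count as matches). Reverse-strand scanning and
overhanging alignments are off by default and available as options, since no
single convention is canonical.

## Group statistics

Within-genus, between-genus and "non-X" CC sets are summarized by
min/median/mean/max/SD and pair counts (within: n(n−1)/2; between: |G1|·|G2|;
non-X: all unordered pairs outside X). Contrasts use Welch's t-test (unequal
variance, Welch–Satterthwaite df) and Cohen's d with the pooled (n−1) SD;
the 95% CI of d uses the Hedges–Olkin normal approximation
Var(d) ≈ (n1+n2)/(n1·n2) + d²/(2(n1+n2)). Note that with the sample SD,
exact duplication of both groups rescales d by √((2n−1)/(2n−2)); d is
duplication-invariant only asymptotically (or under population SD). No
multiple-testing correction is applied across group tests.

## Trees

UPGMA and WPGMA are implemented directly: at each step the pair of clusters
at minimal distance is merged at height d/2, with cluster–cluster distances
updated by size-weighted (UPGMA) or simple (WPGMA) averaging. When two pairs
tie at the minimal distance, the pair whose sorted leaf-label tuple is
lexicographically smallest merges first, so trees are bit-reproducible
across runs and platforms. Outputs are rooted and ultrametric (asserted to
1e−9 in tests). NJ uses the standard Q-criterion (via scikit-bio) with
negative branch lengths clamped to zero, and reproduces additive distances
to 1e−9. Heatmap row/column order is the UPGMA leaf order.

## Synthetic data generator

`kmersig.simulate` builds the study conditions the pipeline expects, without
any downloads:

- **Background**: i.i.d. bases at a target composition. At 1 Mbp the
  realized fractions concentrate within ±0.5% of the target.
- **Planted k-mers**: each plant overwrites background bases at
  non-overlapping random positions until its copy number reaches
  `multiplier ×` its expected occurrence (length × ∏pᵢ). Overwriting (rather
  than inserting) keeps the total length, and hence l, stable across specs.
- **Tandem repeats**: a unit tiled `copies` times at a random position, for
  repeat-skew scenarios (a repeat-loaded clade member loses CC with its
  clade-mates).
- **Clades**: a shared root genome; each clade ancestor diverges by i.i.d.
  point substitutions at the between-clade rate, each species from its
  ancestor at the within-clade rate (within < between enforced; substituted
  sites always change base — a Jukes–Cantor-like model with no indels, which
  suffices because the signature depends on k-mer content, not alignment).
- **Determinism**: all randomness flows from one seed through numpy
  `SeedSequence` spawn keys, so any genome is reproducible independently.

What the generator does **not** emulate: real genome sizes (fixtures are
0.02–1 Mbp vs. hundreds of Mbp), compositional heterogeneity along the
genome (isochores, GC-rich islands), indels and rearrangements, gene
structure, and realistic repeat families. Passing tests therefore
demonstrate correctness of the computations and the qualitative behaviors
(clade recovery, repeat skew, planted-motif recovery) — not that real genera
will separate at any particular CC level.

## Problem sizes and numerical choices

Tests use 0.02–1 Mbp genomes and k ∈ {2,…,8}: parameter recovery runs 20
seeds at 1 Mbp/k=8, clade recovery 3 clades × 4 species at 0.5 Mbp/k=8 —
sizes at which the planted effects are comfortably detectable while the
whole suite stays fast. E is computed in double precision (a direct product
for k ≤ 12, summed logs beyond). Pearson correlation requires ≥ 3 shared
k-mers and nonzero variance in both vectors, otherwise an explicit
undefined-correlation error is raised. Signature TSVs store E and S at 13
significant digits so read(write(sig)) round-trips to ≥ 12 digits; the CC
matrix TSV uses 6 decimals and is re-symmetrized on read. p-values are
reported in full double precision (extreme contrasts can underflow to 0.0).

## Known limitations

- The zero-order background makes E independent of position; locally biased
  regions inflate |S| genuinely but indistinguishably from functional
  enrichment — hence the separate repeat filters.
- The mean+2SD rule references the normal distribution, but score
  distributions are skewed at small l or extreme composition; the cutoff is
  a pragmatic quantile, not a calibrated test.
- The PWM similarity is not a p-value-calibrated motif score; it is the
  simple symmetric measure the 80% convention implies.
- UPGMA assumes clock-like divergence; for strongly rate-heterogeneous
  taxa the NJ tree is the safer output.
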