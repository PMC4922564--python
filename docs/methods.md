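# Methods

This note documents the models, conventions and numerical choices behind
`isofam`, in the order the pipeline runs them.

## Family definition filters

The length filter keeps a protein iff |len − mean| ≤ SD, where the mean and
the *sample* (n−1) standard deviation are computed over the domain
subsequence lengths of the filter's input. The choice of the sample SD is a
convention (the population SD is nearly identical for realistic family
sizes); filtering uses the domain subsequence, not the full protein,
because family membership is defined by the domain. The filter is
re-entrant but not idempotent by construction — statistics are recomputed
on each call's input — so re-filtering can only shrink the set.

The reference-identity filter keeps a protein iff its percent identity to
at least one reference structure is ≥ 30 (configurable), the minimum at
which homology modeling is considered usable. A protein with no identity
entries is an error by default (`on_missing="drop"` switches to silent
removal).

## Evidence matrices

Every evidence source is a named symmetric N×N matrix with an orientation
(similarity-like or distance-like) and a missing mask. The canonical
vocabulary covers 25 sources: sequence alignment scores (`seqAliG`,
`seqAliL`), structural alignment statistics (`strAliSize`, `strAliId`,
`strAliScr`), structural-signature distances (`csmDist`), genomic context
(`neighborhood`, `fusion`, `cooccurrence`, `coexpression`), property
differences (`difMolWeight`, `difIsoPoint`, class molar-percent
differences, `difInstab`, `difGRAVY`), composition distance (`aaCompDist`),
shared annotations (`interpro`, `go`), and active-site comparisons (`ASid`,
`ASscr`). Sources requiring external tools or databases (structural
alignment, structural signatures, genomic context, isoelectric point,
instability index) are inputs, never recomputed.

**Alignment scoring.** Global (Needleman–Wunsch) and local
(Smith–Waterman) scores use BLOSUM62 with affine gaps under the convention
that a gap of length L costs `open + L·extend`, defaults open 10 / extend 4
(the defaults of the R alignment stack this emulates; both configurable).
Scores are produced by Biopython's `PairwiseAligner` with
`open_gap_score = −(open+extend)`; tests verify exact agreement with an
independent quadratic-space Gotoh dynamic program on random sequences.
Unknown residue letters raise by default; an opt-in mode maps them to `X`
scoring 0 against everything.

**Active-site comparisons.** Identity and summed BLOSUM62 score are
computed over *comparable* columns only — columns where neither protein has
a gap — excluded from both numerator and denominator. Gaps in the
active-site alignment encode modeling failure, not biology, so counting
them as mismatches would conflate the two. A pair with no comparable
columns scores 0 with a warning.

**Property matrices.** Scalar properties give |v_i − v_j| distance
matrices. The composition array is the per-residue molar percentage
divided by the Dayhoff reference composition (packaged constant, percent
units); pairs are compared by squared Euclidean distance. Amino-acid class
sets follow the EMBOSS pepstats convention (aliphatic AILV, aromatic FHWY,
non-polar ACFGILMPVWY, polar DEHKNQRST, charged DEHKR, basic HKR, acidic
DE). Molecular weight is the average-mass residue sum plus one water;
GRAVY is the mean Kyte–Doolittle hydropathy.

**Normalization.** Present off-diagonal values are min–max mapped to
[0, 1], or to [−1, 1] when negatives exist; distance-like matrices are then
interval-reversed (x→1−x on [0,1], x→−x on [−1,1]) so larger always means
more similar. The diagonal is excluded from min/max and set to maximum
similarity afterward. Missing pairs (genomic-context data typically covers
only a subset) are imputed as the interval's *minimum* similarity: absence
of evidence contributes no similarity. A constant matrix normalizes to all
zeros with a warning. Normalization is idempotent (a normalized matrix is
returned unchanged).

## Putative active-site selection

A pocket qualifies when ≥ 3 of its positions are conserved in ≥ 50% of the
family ("at least" on both bounds, so exactly 3 positions at exactly 50%
qualifies); among qualifying pockets the one with the largest pocket score
wins, with score ties broken lexicographically by pocket id for
reproducibility. Conservation of a position is the frequency of its modal
non-gap residue *over all rows* (gapped rows count in the denominator: a
residue must be present and identical in half the family); a flag switches
to the non-gap denominator. When no pocket qualifies the selection errors,
listing per-pocket conserved counts, rather than guessing.

## Spectral clustering

The combined similarity matrix is shifted to be non-negative (affine shift
by −min if needed), its diagonal zeroed, and all-zero rows floored at
1e−12 so the graph is connected. We form the random-walk normalized
Laplacian `L_rw = I − D⁻¹W` and solve the equivalent symmetric generalized
problem `(D − W)v = λDv` (numerically stable; identical eigenpairs). The
eigenvectors of the K smallest eigenvalues form the N×K embedding — with
no row normalization, which belongs to a different spectral variant — and
seeded K-means (10 restarts, greedy center seeding) labels the rows. If
K-means ever returns an empty cluster the run is retried with a shifted
seed up to 5 times, then errors; K-means implementations practically never
produce empty clusters, so the retry bound is a safety contract.

## Mutual-information quality and SDP ranking

At position p, the probability space is the set of non-gap rows at p
("gaps are not considered"): joint p(c, r) and marginals p(c), p(r) are
relative frequencies over that subset, for cluster marginals too. The
partial score is

    MI_p(c, r) = f_in(r)·PMI_p(c, r) + f_out(r)·PMI_p(c̄, r)

where f_in/f_out are residue r's frequencies within cluster c and within
its complement. Under this reading the two PMI terms provably have
opposite signs whenever both are finite, which is the property that makes
the complement term act as a penalty for non-exclusive residues. The score
is 0 whenever PMI_p(c, r) ≤ 0, 0·ln 0 ≡ 0 throughout, and the final value
is floored at 0 (with unequal cluster sizes the complement penalty can
otherwise exceed the positive term).

Position-level scores weight each residue by its within-cluster frequency
f_k — so a residue appears twice, once in the weight and once inside
MI_p(c, r); this double weighting is implemented as specified, with a
documented flag to disable the outer f_k for sensitivity analysis. The
overall quality averages over positions and clusters:

    MI = (1/P)(1/C) Σ_p Σ_c MI_p(c)

For C equal-size clusters each having an exclusive, fully covering residue
at every position this equals ln C exactly (each cluster term is
1·ln(1/p(c)) = ln C), giving a closed-form oracle used in tests. The
report also carries the unnormalized sum Σ_p Σ_c MI_p(c): published
family-level values of this statistic elsewhere exceed the ln C envelope
of the averaged form, suggesting the averaging factor is sometimes
omitted in print, so both variants are reported and neither is asserted
as canonical.

SDP ranking lists, per cluster, the residues with positive partial MI in
decreasing order, ties broken by (position, residue); labels render as
residue + 1-based position, plus the reference-structure residue number
when position labels exist (e.g. `K11_523`).

## Genetic-programming integration

The genome is an addition-only binary tree over matrix-name leaves, so
integer coefficients arise as leaf multiplicities — this reproduces
printed equation forms like `2ASid + ASscr + seqAliG` without an
ephemeral-constant mechanism, and rendering sorts terms lexicographically
as such tables do. Defaults: population 50, generations 30, crossover
0.8 / mutation 0.1 / reproduction 0.1 (mutually exclusive), tournament
size 3, max tree depth 6, 1 elite. These are this package's choices —
the original experiment configuration is not published — and all are
configurable and echoed in provenance output.

Crossover swaps random subtrees (offspring exceeding max depth revert to
their parents); mutation replaces a random subtree with a fresh random
tree of depth ≤ 3. Fitness is the overall MI of the spectral clustering
of the individual's combined matrix. One K-means seed is drawn per run
and shared by all evaluations, so selection compares individuals rather
than clustering draws; as a consequence fitness depends only on the
coefficient vector, and evaluations are memoized on it. Elitism makes the
per-generation best-fitness history non-decreasing. The whole run is
reproducible from (inputs, config).

## Synthetic benchmark generator

The generator plants known structure in every input modality. Defaults:
N = 60 proteins in 3 equal subfamilies; a 10-position active site with 3
SDP positions (one dominant residue per subfamily, distinct across
subfamilies — mirroring the two-residue swaps that switch real enzyme
specificities — flipped to a random residue at rate 0.05), 4
family-conserved positions and 3 uniform positions; 2% gaps; one
informative evidence matrix (within-block mean 0.9, between 0.1, additive
symmetric Gaussian noise SD 0.1) plus two pure-noise matrices; optional
redundant (ρ-correlated) and partially missing matrices; 80-residue domain
sequences built from per-subfamily consensus with 10% substitutions;
scalar properties drawn per subfamily with overlap. The within/between
means and noise level are chosen so the planted partition is recoverable
but not trivial (the signal-to-noise of the block structure, not the
Gaussian noise family, is the contract).

What the generator does *not* emulate: phylogenetic correlation between
sequences (no evolutionary model), realistic score distributions of
specific external tools, or subfamily size imbalance of the kind that
dominates real superfamilies. Passing tests on this benchmark therefore
demonstrate correctness of the machinery and recoverability under planted
block structure, not performance on imbalanced real families.

## External validation

All measures are computed from the class-by-cluster contingency table:
pairwise precision, recall, F1, Rand and Jaccard from TP/FP/FN/TN pair
counts (TP = Σ C(n_kk', 2) etc.); variation of information
`VI = H(S) + H(S′) − 2I(S, S′)` with natural logarithms (the nats
convention is confirmed by reproducing the published crotonase value of
0.80 from its table); and edit distance `2·(nonzero cells) − K − K′`.
The two packaged SFLD superfamily tables (crotonase, 12 families × 12
clusters, N = 2,694; enolase, 12 families × 12 clusters, N = 4,791) were
cross-checked cell-by-cell against their published family totals before
packaging.

## Problem sizes and tolerances

Oracle-equivalence tests use exact agreement to 1e−9: 50 random pairs of
length ≤ 30 for alignment DP, 100 random small alignments for partial MI,
50 random partition pairs (N ≤ 40) for pair counting. Spectral recovery is
exercised noiselessly up to N = 200 / K = 5 and stochastically at N = 60,
K = 3, σ = 0.1 over 20 seeds (≥ 18 perfect recoveries expected).
GP-vs-exhaustive uses N = 40, K = 2, three matrices with coefficients
enumerated over {0,1,2,3}³, 5 seeds; these sizes make the exhaustive
oracle (63 evaluations) exact while keeping each evaluation's eigensolve
well-conditioned. Closed-form MI identities are tested for C ∈ {2,3,5},
P ∈ {1,10}.

## Known limitations

- The ideal number of clusters K is a required input; the MI measure
  decreases as K grows and cannot compare clusterings across different K.
- The MI fitness is tied to the active-site alignment; a poorly chosen
  pocket propagates to every downstream stage.
- Hard partitioning cannot express promiscuous proteins that belong to
  several functional groups.
- Evidence redundancy (highly correlated matrices) makes the evolved
  equations non-unique; `matrix_correlation` quantifies but does not
  remove it.
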