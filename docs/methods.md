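# Methods

## The problem

Phylogenetic tree inference assumes that a multiple sequence alignment (MSA)
carries homogeneous historical signal. In practice, individual taxa or taxon
subsets can be so divergent — through substitution saturation, alignment
ambiguity or missing data — that their similarity to the rest of the
alignment is statistically indistinguishable from chance. Such sequences are
the classic substrate of long-branch attraction: trees built from them can
show high bootstrap support for branches that reflect noise, not history.
Column-wise alignment trimmers (Gblocks, trimAl, BMGE) remove whole alignment
blocks and cannot see *taxon-specific* randomness. `alidrift` tests every
sequence pair separately and summarizes the result per pair and per branch.

## The pairwise randomness test

For a pair of aligned sequences X and Y, a window of `w` consecutive sites
(default `w = 6`) slides along the alignment with step 1.

1. **Observed score.** The window's observed score is the sum of per-site
   pair scores: match/mismatch (+1/−1 by default) for nucleotides, a
   substitution-matrix entry (BLOSUM62, PAM250 or PAM500) for amino acids.
   Ambiguity codes (IUPAC nucleotide codes; amino-acid X/B/Z/J) are *neutral*
   and contribute 0. Gaps are either a fifth, identity-matchable state
   (default) or neutral (`-N`); under matrix scoring gap/residue costs a
   configurable `gap_penalty` (default: the mismatch score) and gap/gap the
   match score, mirroring the fifth-state contract.

2. **Permutation null.** The null distribution conditions on *local
   composition*: independently for X and Y, `w` residues are drawn uniformly
   with replacement from that sequence's residues inside the window extended
   by `flank` columns on each side (default `flank = w`, clipped at the
   alignment ends), and the synthetic window pair is scored the same way.
   This is repeated `n_permutations` times (default 100). Per-sequence pools
   (rather than a joint pool or an in-place shuffle) preserve each sequence's
   local composition, which is exactly the property the test conditions on.
   Neutral residues stay in the pools and contribute 0 wherever drawn, so
   observed and null scores stay on one scale.

3. **Verdict.** The window is judged non-random (+1) iff the observed score
   is *strictly* greater than at least a fraction `1 − alpha` of the
   permutation scores (default `alpha = 0.05`). Ties count against
   significance, so a compositionally constant window — where every
   permutation reproduces the observed score — is always judged random (−1).
   This is deliberately conservative.

4. **Profile.** Each site accumulates the verdict of every window covering
   it; the sum is divided by the window size `w`. Interior sites are covered
   by `w` windows, so values lie in [−1, +1]; sites within `w − 1` columns of
   an alignment edge are covered by fewer windows and are attenuated toward 0
   (|value| ≤ coverage/w). An `edge_normalize_coverage` toggle divides by the
   actual coverage instead.

Because each window receives its own random stream — spawned from
`SeedSequence(master_seed, spawn_key=(i, j, window_start))` with the pair
index (i, j) in canonical (sorted) order — profiles are exactly symmetric in
X and Y, reproducible, and independent of execution order, so serial and
parallel runs are byte-identical.

Under these defaults the behaviour at the two extremes is forced: an
identical, compositionally diverse pair gets +1 at every interior site, while
two unrelated random sequences trigger false positives at rate ≈ alpha, giving
an expected site value near `alpha − (1 − alpha) = −0.9` (empirically ≈ −0.97,
because the tie rule pushes the rejection rate slightly below alpha).

## The similarity matrix

The pair score S_XY is the arithmetic mean of the profile over all sites that
are not *globally invariant*. A column is globally invariant iff every taxon
carries the identical canonical state (an all-gap column counts under
fifth-state coding; any neutral residue makes a column variable). Invariant
columns are uninformative about pair-specific randomness and would dilute the
score, especially in conserved genes. All N(N−1)/2 pairs are computed
(optionally in parallel over pairs), the matrix is filled symmetrically, and
the diagonal is fixed at +1 purely as a display convention — it enters no
statistic. A pair with no variable site is recorded as NaN ("missing"), never
silently 0, and is excluded from downstream means.

## Branch tagging

Given a guide tree whose leaves appear in the matrix:

- **Terminal branch** of taxon A: `R_A = mean_{Y != A} S_AY`.
- **Internal branch**: each edge of the *unrooted* topology inducing a
  non-trivial bipartition A|B is scored with the mean of S_XY over all
  |A|·|B| cross-split pairs; within-side pairs are excluded. The two edges
  incident to a degree-2 root induce the same split and are scored once. A
  fully bifurcating N-taxon tree therefore yields exactly N − 3 internal
  reports. Side order is canonicalized before summation so A|B and B|A give
  bit-identical results.

A branch is flagged *suspicious* iff R < 0 (exactly; R = 0 is not flagged).
Negative R means the similarity carried across that split is on balance
indistinguishable from random — support for the branch may be inflated.
NaN matrix entries are excluded from both sum and count. Pairwise scores are
treated as independent replicates in these means; no covariance correction is
attempted, and the flag should be read as a screen, not a test with a
calibrated error rate.

Matrix taxa absent from the tree are ignored with a warning (their rows are
simply unused); tree leaves absent from the matrix are a hard error, since
their scores would be undefined.

## The simulator

`alidrift.simulate` generates test alignments by evolving sequences along a
tree under a symmetric equal-exchange model: Jukes–Cantor for nucleotides and
its 20-state analogue for amino acids, i.e. `P(stay) = 1/k + (k−1)/k ·
exp(−k/(k−1)·d)` for k states at rate-scaled distance d. Among-site rate
variation uses a mixed model: a site is invariant with probability
`prop_invariant` (default 0.3), otherwise its rate is a continuous
Gamma(shape α, mean 1) draw (default α = 1.0). These defaults are the
benchmark conditions used throughout the test suite. The expected proportion
of differing sites has the closed form
`(1 − ρ)·(k−1)/k·(1 − (1 + c·d/α)^(−α))` with `c = k/(k−1)`, which the tests
use as an independent oracle.

Optional indels place Poisson-distributed insertion and deletion events per
branch (expected count = rate × branch length × current length) with lengths
uniform on {1..max_length}; insertions create fresh alignment columns gapped
in all other lineages, so column homology is exact by construction. The
length law is deliberately simple — the properties being exercised depend on
the presence of misalignable gaps, not on the tail of the length
distribution. Likewise the amino-acid simulator uses uniform exchange rather
than an empirical exchange matrix: the saturation behaviour the tests need
does not depend on the exchangeabilities.

Two presets reproduce classic long-branch designs. `setup_a` is a 4-taxon
Felsenstein-zone quartet `((L1:BL2,S1:BL3):BL1,L2:BL2,S2:RB)` — two long
branches (BL2) on opposite sides of a short internal branch (BL1 = 0.01,
BL3 = 0.1, RB = 0.1). `setup_b` is a 6-taxon tree with two long *internal*
branches separated by a short one, leaves L1/L2 behind the long branches and
RB1–RB4 elsewhere. `setup_grid` sweeps BL2 over a grid (canonically
0.1–1.5 in steps of 0.2) with per-cell seeds spawned from the master seed.

What the simulator does *not* emulate: empirical base composition bias,
site-specific selection, realistic indel length laws, alignment error from a
real aligner, or model misspecification. Passing tests therefore demonstrate
that the statistic behaves as designed under its own model assumptions — that
elongating branches drives pair scores monotonically from +1 territory toward
−1, that identical sequences score +1 and unrelated ones ≈ −0.97 — not that
any particular empirical dataset will be classified correctly.

## Numerical and design choices

- **Match/mismatch = +1/−1**: symmetric values make constant-signal and
  constant-noise windows mirror images; both are configurable.
- **Defaults w = 6, flank = w, n_permutations = 100, alpha = 0.05**: 100
  permutations make the 95% criterion resolvable (the smallest admissible
  sample is `ceil(1/alpha) = 20`, which is enforced); the 3w-column
  neighborhood keeps the null local.
- **Edge sites normalized by w**, matching the profile definition; the
  coverage-normalized variant is an explicit toggle.
- **Exact null oracle**: because window positions are filled i.i.d., the
  exact permutation-score distribution is the w-fold convolution of the
  single-position score distribution over all equiprobable pool draws;
  `exact_null_distribution`/`exact_verdict` implement this and agree with the
  Monte Carlo verdict at `n_permutations = 2000` on ≥ 99% of windows of
  random alignments (measured ≈ 99.9%).
- **Degenerate inputs**: windows larger than the alignment, empty null
  samples, self-comparisons, all-gap alignments and fully-invariant pairs all
  raise typed errors; degenerate pairs propagate as NaN.
- **Benchmark problem sizes**: the packaged grids use alignments of 5,000
  sites and 10 replicates per branch-length point, which resolves the
  monotonic decay cleanly (Spearman ρ = −1 in the shipped runs); larger
  designs are one argument away via `setup_grid`.

## Known limitations

- The per-sequence-pool resampling scheme is one defensible reading of
  "permutation within the window and a neighborhood"; alternatives (joint
  pools, in-place shuffles) would condition on slightly different properties.
  The package's invariants are therefore validated against forced cases and
  the exact-enumeration oracle, not against any external binary.
- Branch scores average correlated pairwise comparisons; R < 0 is a flag,
  not a p-value.
- The similarity score is not an evolutionary distance; do not cluster or
  build trees from it.
- Profiles cost O((M − w)·n_permutations·w) per pair and the matrix scales
  quadratically in N; memory stays O(N² + M) because profiles are streamed
  per pair.
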