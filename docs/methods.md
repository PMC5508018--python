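# Methods

This note records the models, conventions and numerical choices behind
`mlsakit`, and what the synthetic-data generator does and does not
emulate.

## Diversity statistics

All statistics treat gaps (`-`) and IUPAC ambiguity codes as missing
data, never as a fifth character state. This is the conservative,
standard convention and it makes every statistic invariant to how
missingness is encoded.

* **Alleles.** Strains share an allele iff their aligned sequences are
  character-identical (case-insensitive). Allele numbers start at 1 in
  order of first appearance; sequence types (STs) are assigned the same
  way over the tuple of per-locus alleles.
* **Parsimony-informative sites.** A column is informative iff at least
  two distinct unambiguous states each occur in at least two sequences.
  The percentage denominator is the minimum per-sequence ungapped length
  across the alignment (the trimmed length of the shortest sequence):
  diversity tables in this field report percentages against trimmed
  lengths, and this choice reproduces them exactly (e.g. 48/1430 →
  3.36%, 869/4515 → 19.2%).
* **Reporting precision.** Percentages are rounded half-up: two decimals
  below 10, one decimal from 10 up — the mixed precision such tables
  print. `diversity.round_report` is the single implementation.
* **Pairwise identity.** identity% = 100 · matches / compared columns.
  Under pairwise deletion (the default) a column is skipped for a pair
  when either member has a gap/ambiguity; under complete deletion such
  columns are removed for all pairs first. On gapless data MLSA identity
  of a concatenation is exactly the length-weighted mean of per-locus
  identities (asserted by test).
* **Nei–Gojobori Ka/Ks.** Per codon, synonymous site counts are the
  fraction of the three single-base changes at each position that
  preserve the amino acid; mutations to stop codons count as
  nonsynonymous. Observed differences between codons are averaged with
  equal weight over all minimal-length mutation pathways, excluding
  pathways that pass through a stop codon (if every pathway is blocked,
  all are used). Proportions pS = Sd/S and pN = Nd/N are Jukes–Cantor
  corrected, d = −¾·ln(1 − 4p/3). Pairs with pS or pN ≥ 0.75 are
  saturated and dropped with a warning. The per-locus value aggregates
  as the ratio of the mean dN to the mean dS over all usable pairs
  (ratio of means, not mean of ratios — stabler when individual pairs
  have tiny dS); dS = 0 leaves the ratio undefined (`None`), never zero.
  A terminal stop codon is ignored; an internal one is an error.

## Concatenation and trees

Loci concatenate in the scheme's fixed order (gyrB, rpoD, dnaK, trpB,
recA by default); order affects the recorded 0-based half-open locus
boundaries but not similarity (asserted by test). Strains missing from
any locus fail the run unless explicitly downgraded to
exclusion-with-warning, because the scheme assumes every strain has
every locus.

Trees are built by neighbor joining on distances d = 1 − sim/100
(optionally Jukes–Cantor corrected; similarity ≤ 25% saturates the
correction and is rejected). Two behaviors are pinned for
reproducibility: ties in the Q criterion break toward the lowest index
pair, and a negative estimated branch length is clamped to zero with the
deficit moved to its sibling edge so the joined pair's distance is
preserved. NJ here replaces maximum-likelihood tree search deliberately:
the package's claims concern clade membership and thresholds, which NJ
reproduces exactly on additive, desk-scale data (verified against
exhaustive least-squares topology enumeration for up to six taxa and
against scikit-bio's NJ), and it avoids wrapping external binaries.
Outgroup rooting is intentionally not applied by default.

Bootstrap supports resample columns of the concatenation with
replacement; each replicate goes through identity → distance → NJ, and
an original internal edge's support is the percentage of replicates
containing its bipartition. Internal edges of numerically zero length
(≤ 1e-12) carry no support, so a signal-free alignment cannot be
reported as resolved. Everything is deterministic given the seed.

Clades at a similarity threshold are single-linkage components (chains
of pairs at or above the threshold), which makes the clustering monotone
in the threshold.

## Calibration and the soft threshold

The map from dDDH to MLSA similarity is modeled as
y(x) = a·e^(b·x) + c·e^(d·x). Fitting is nonlinear least squares
(Levenberg–Marquardt with analytic Jacobian) from a deterministic
multi-start grid: a₀ ∈ {0.9, 1.0, 1.1}·max(y), b₀ ∈ {10⁻⁴, 10⁻³, 10⁻²},
and (c₀, d₀) from a log-linear fit to the residual of the first term,
with small seeded jitter (nine starts). Objective tolerance 10⁻¹⁰; at
most 300 function evaluations per start — converged runs use a few
dozen, so the cap only truncates divergent starts. Among starts tied on
the objective the model with the smallest |c| wins, so single-exponential
data comes back with a vanishing second term. Requirements: at least
five points spanning at least 10 dDDH percentage points.

The species threshold is the curve evaluated at the 70% dDDH anchor
(direct evaluation, not root finding, since y is the MLSA axis), rounded
half-up to one decimal. The model must be monotone increasing over its
fitted domain, checked on a 1000-point grid of the analytic derivative;
anchoring outside the fitted domain warns (extrapolation). The ambiguous
zone's lower bound is data-derived: the largest observed MLSA similarity
strictly below the threshold among pairs with dDDH below the anchor.
When the observed pairs leave a wide empty region below the threshold
(as clade-structured data often do), the detected zone is
correspondingly wide — the zone describes the data, not a constant.

The shipped `THIOCLAVA_CALIBRATION` (a = 90.87, b = 9.749·10⁻⁴,
c = −982.7, d = −0.2097, R² = 0.9906, domain 20–100% dDDH) maps 70% dDDH
to 97.3% MLSA; on the data it was fitted to, the ambiguous zone extends
down to 96.6%. Outside its domain the curve is meaningless (y(0) =
a + c = −891.83).

## Demarcation rules

Per pair: MLSA similarity ≥ upper bound → same species; below the lower
bound → different; in between → ambiguous, resolved by dDDH (≥ 70%
same, else different) or, lacking dDDH, by ANI (≥ 96% same, < 95%
different, 95–96% remains ambiguous — the published ANI boundary is a
band, encoded as such). Clusters are the single-linkage closure over
resolved same pairs. A pair whose firm MLSA verdict contradicts dDDH or
ANI is conflict-flagged; for dDDH the genome evidence also wins the
final label (the gold standard outranks the marker scheme). A
non-transitive same relation is surfaced as a conflict on the violating
pair while closure still yields a partition. Clusters containing no
user-designated reference type strain are putative novel species;
reference ids are configuration, not constants. The 16S screen simply
lists pairs at or above 98.65% (configurable) 16S identity — the pairs
single-gene taxonomy cannot split.

## Synthetic data

The generator produces the statistical regime the workflow assumes,
with full ground truth.

* **Strain tree.** Species subtrees are stars: strain tips attach to
  their species ancestor with lengths jittered around within/2, so
  within-species path lengths spread around `within_species_divergence`.
  Species join at heights spread over [0.75, 1.25]·between/2, giving
  between-species path lengths spread around
  `between_species_divergence`. Units are expected substitutions per
  site throughout. A single-species configuration is handled as one
  star (no species-level joins).
* **Sequence evolution.** Coding loci evolve under a 61-state codon
  model with uniform codon frequencies: rate κ for transitions, ×ω for
  nonsynonymous changes, zero into stops, normalized to one expected
  substitution per nucleotide site per unit branch length. Uniform
  frequencies make the generator matrix symmetric, so one
  eigendecomposition serves all branches. Non-coding loci (16S) use a
  K2P nucleotide model. Defaults: five coding loci at 933/885/918/927/
  852 bp with ω ∈ {0.07, 0.04, 0.04, 0.04, 0.02} (the spread housekeeping
  genes show under strong purifying selection), κ = 2; a 1430-bp
  non-coding locus at rate multiplier 0.25 (16S evolves several-fold
  slower than housekeeping genes, which reproduces a 96–100% 16S
  similarity range alongside 85–95% between-species MLSA similarity).
* **Divergences.** Defaults within = 0.010 and between = 0.105
  substitutions/site place within-species MLSA similarity near 99%
  (> 97.3) and between-species similarity in the high-80s to low-90s
  (< 96.6), with per-locus parsimony-informative fractions of 17–21% —
  the regime a well-chosen MLSA scheme operates in.
* **dDDH/ANI surrogate.** Pairwise dDDH is produced by numerically
  inverting the reference calibration curve at the pair's realized MLSA
  similarity and adding Gaussian noise (default sd 1%); ANI is the
  affine map of dDDH anchored at (70, 95.5) and (100, 100). This is a
  declared surrogate: it supplies exactly the dependence structure the
  calibration and demarcation stages need, not a genome model.
* **What is not emulated.** No indels (gap handling is exercised by
  hand-built alignments in tests, not by the simulator); no
  recombination or HGT; no base-composition bias (uniform equilibrium
  frequencies put simulated G+C near 50 mol%, whereas real housekeeping
  genes in GC-rich genera run 60–65 mol% — the G+C statistic is
  therefore checked by direct arithmetic, not by simulation); no rate
  heterogeneity across sites; 16S multi-copy heterogeneity absent.
  Passing tests on this generator demonstrate the estimators and
  decision rules, not robustness to alignment error or recombination.

## Determinism and problem sizes

Every stochastic component takes an explicit seed (numpy Generator /
SeedSequence); identical seeds give byte-identical fixture bundles. The
statistical checks in the test suite use desk-scale sizes chosen to make
the assertions sharp: 100 random 30-codon pairs against the Ka/Ks
enumeration oracle; all unrooted topologies for 4–6 taxa (15/105 trees)
in the least-squares tree oracle; 100 seeded refits of 50 noisy curve
points for threshold recovery; 20 seeded 23-strain/9-species fixtures
for exact partition recovery; 20 replicates of a 1500-bp neutral locus
for the ω = 1 limit of the Ka/Ks estimator.

## Known limitations

* NJ topologies can differ from maximum-likelihood trees in deep
  branches when distances are strongly non-additive; the demarcation
  stages consume similarity matrices directly and are unaffected.
* The calibration fit is only constrained where (dDDH, MLSA) pairs
  exist; with strongly clade-structured data the region near the 70%
  anchor may be an interpolation across an empty interval, and the
  derived threshold inherits that uncertainty.
* The Ka/Ks estimator is the classic counting method; it is unbiased at
  κ = 1 and mildly biased for κ > 1 (no codon-model maximum likelihood
  is provided, by design).
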