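# Methods

## The estimation problem

Noncoding DNA does not evolve one site at a time in isolation: the
substitution process at a focal site depends on its flanking bases.  `ctxsub`
estimates that dependence from alignments of two closely related *ingroup*
sequences plus an *outgroup*, under the classic parsimony-style convention
that at any site whose flanking context is identical in all three sequences,
the outgroup base is the ancestral state and each ingroup base is an
independently derived state.  Every eligible alignment column therefore
contributes two records — (ancestral, derived₁) and (ancestral, derived₂) —
including conserved columns, which populate the diagonals of the count
matrices.  No multiple-hit correction is applied: at the divergences the
method targets (~0.066 substitutions/site between ingroups) the raw
per-site proportions are read directly as rates, in units of
substitutions/site per average ingroup branch.

## Site eligibility

A column enters the counts only if

1. of the 10 surrounding columns (5 per side), at least 8 are non-gap bases
   in both ingroups;
2. at least 7 of those 10 columns are identical non-gap matches between the
   ingroups (≥70% similarity; any gap counts as a mismatch);
3. the *r* nearest columns on each side are gap-free and identical in all
   three sequences (conserved context, with alignment neighbors equal to
   physical neighbors);
4. the focal column is a plain A/C/G/T in all three sequences and lies at
   least max(5, *r*) columns from either alignment end.

The "10 surrounding sites" are read as 5 alignment columns on each side —
a symmetric window is the natural reading — and ambiguity codes are treated
as gaps.  Regions of ≤70 alignment columns are skipped entirely.  When the
outgroup differs from both ingroups the column counts as two substitutions;
no consensus rule is imposed.  Exclusions are tallied per filter
(first-failing-filter attribution) so that
`columns_scanned = eligible + Σ exclusions` holds exactly.

## Contexts, complement combining, canonicalization

A radius-*r* context is the ordered pair of flanking *r*-mers; radius 3
(the hexanucleotide context) is the default and there are 4^(2r)
strand-explicit contexts.  Reading the opposite strand maps context *c* to
its reverse complement rc(*c*) and every base through complementation, so
the two strands' counts are pooled: each context receives its partner's
complement-transformed matrix, `CM'[c][i,j] = CM[c][i,j] +
CM[rc(c)][comp(i), comp(j)]`.  Self-complementary contexts (right =
revcomp(left); 4^r of them) keep their raw counts unchanged — pooling a
self-complementary matrix with its own transform would count each event
twice.  Complementary pairs are then redundant and the canonical
representative (lexicographically smaller concatenated string) is used,
giving (4^(2r) − 4^r)/2 + 4^r classes — 2,080 at radius 3 — over which the
total count is conserved exactly.

## Rates, intervals, fold variation

Row-normalizing a count matrix gives the Markov matrix Π with
Π[i,j] = CM[i,j]/ΣCM[i]; empty rows are flagged, never NaN-filled.  Each
off-diagonal probability carries a Wald 95% interval
p ± 1.96·√(p(1−p)/n) clipped to [0, 1], with n the row sum.  After
combining, the A and G rows mirror the T and C rows, so transition (T↔C,
A↔G partner) and transversion rates are summarized for the pyrimidine rows
only.  Ts:Tv with a zero transversion count is reported as undefined and
excluded from fold tables.  Fold-variation tables report max/min ratios
across contexts passing either of two row-count thresholds: at least 50
transitions and 50 transversions, or at least 100 substitutions in the row;
the "from T and C" line takes extremes over the union of both rows.

## Equilibrium composition

For each canonical context the stationary vector φ solves φ = φΠ: the left
eigenvector for eigenvalue 1 (scipy eigen-decomposition, power-iteration
fallback), normalized to sum 1, entries in (−10⁻¹², 0) clipped to zero, and
the residual ‖φΠ − φ‖∞ required to be ≤ 10⁻¹⁰.  Degenerate outputs — an
empty row, a non-unique eigenvalue-1 eigenspace, or a zero equilibrium
frequency, all typical of sparse counts — are flagged and reported rather
than dropped.  Observed composition per context is the frequency of the
derived (ingroup) focal bases, i.e. the column sums of the same combined
matrix, so both sides of the predicted-vs-observed comparison fold the two
strands identically.  Composition statistics are A+T% and the signed skews
100·(G−C)/(G+C) and 100·(A−T)/(A+T); a skew with a zero denominator is
flagged undefined.  Whether the original comparisons used ancestral or
ingroup bases for "observed" is not determinable from the source; derived
bases are the package's choice because they describe the extant sequences
the equilibria are meant to explain.

## Context indices

ATI (flanking A+T), RI (flanking purines on the analyzed strand, applied to
pyrimidine rows) and RATI (per-base scores A=2, C=0, G=1, T=1) weight the
N_i flanking pair by proximity.  As printed, the ATI/RI weights 2^(3−i) cap
the indices at 14, which is inconsistent with the documented index values
of 28 and cutoffs like "RI ≥ 26"; the package therefore uses weights
2^(4−i) (8/4/2) for ATI and RI — which reproduces every documented range —
and the printed 2^(3−i) (4/2/1) for RATI, whose maximum is already 28.  The
weights are explicit keyword arguments for anyone who wants the literal
printed forms.

## CpG analysis

The CpG contrast is computed from the *uncombined*, strand-explicit counts,
once per strand reading: focal G preceded by C versus any other 5' neighbor
(columns G→A versus all other outcomes, conserved G→G included), and focal
C followed by G versus any other 3' neighbor (C→T versus the rest).  The
second column must include the diagonal: the published row totals are the
full G-row/C-row site counts, and only with conserved sites included do the
printed counts reproduce odds ratios of 1.36 and 1.37.  The odds ratio is
the plain cross-product ratio without continuity correction; heterogeneity
is a Pearson χ² with df = 1, uncorrected.

## Duplex stability

Heptanucleotide stability is the sum of the six internal dinucleotide-step
ΔG°₃₇ values from the unified nearest-neighbor parameter set
(SantaLucia 1998, *PNAS* 95:1460–1465), without initiation or terminal
terms: every use in the package is a relative comparison across heptamers,
which is invariant to those additive constants.  The constants are shipped
verbatim in `ctxsub.features.NN_DG37`; the test suite checks their internal
duplex symmetry and additivity, not their provenance.

## Strand-symmetry procedure

Genomes are oriented by a reference gene set — rps12 and psbA on one
strand, psbK, psbD and psbC on the other — and kept only when all five are
annotated in that arrangement; the rps12/psbA strand is relabeled "A".
Genes annotated in ≥90% of the oriented genomes and lying on strand A in
≥80% or ≤20% of them form the symmetry gene list.  Matrices built from
strand-A sequences are strand-explicit, and for each complementary context
pair with at least 50 substitutions on each side, the stationary statistics
of rc(*c*) are complement-mapped and correlated against those of *c*;
squared correlations near 1 indicate the substitution process does not
distinguish strands.  Gene names are matched exactly after
case-normalization (no synonym resolution), and the module takes whatever
oriented genomes exist rather than requiring a particular corpus size.

## The synthetic-data generator

Because the original alignment corpus is an external download, every
downstream stage is validated against a simulator with known ground truth.
Sequences evolve by an exact Gillespie algorithm: per-site rates are looked
up from the current flanking context, one event fires at a time, and the
neighbors' contexts (hence rates) are refreshed after each event — a
per-site matrix-exponential shortcut would be wrong here precisely because
neighbor dependence couples the sites.  Sites within one radius of a
sequence end have undefined context and never mutate (and are never
counted).  Branch lengths are expected substitutions/site under the uniform
reference rate (total per-site leave rate 1).  Datasets are simulated on a
star-like 3-taxon tree — one ancestor, two independent ingroup branches,
one outgroup branch — with per-region random streams spawned
deterministically from a single master seed, so identical parameters give
byte-identical datasets.

Defaults emulate the target corpus: 280 regions of 300 nt, ingroup
branches of 0.033 each (≈0.066 substitutions/site between ingroups),
outgroup branch 0.05, A+T-rich composition (GC 0.35), and occasional short
indels (0.002 events/site, geometric lengths of mean 2, ingroups only).
Indels are recorded as events and the emitted alignment is constructed from
that known history — there is no realignment step, so the alignment is true
by construction.  The generator does *not* emulate recombination,
selection, among-region rate variation, real chloroplast genome
architecture, or alignment error; passing tests therefore demonstrate
estimator correctness under the stated generative model, not robustness to
misalignment.

Presets: `uniform` (all 12 changes equal); `cpg` (transitions ×k at CG
dinucleotides, both strand readings, default k = 1.4); `ati_tv`
(transversions scaled 1 + slope·ATI, radius 3); `at_bias` (C→T and G→A
scaled 1 + s·(flanking A+T fraction), a minimal strand-symmetric generator
of context-dependent equilibria); `f81` (context-independent with arbitrary
stationary composition, for which an i.i.d. draw from that composition is
an exact stationary start).  A `burn_in` branch can be applied to the root
sequence before the triplet to bring it near the model's own stationary
state.

## Calibration studies and their sizes

`ctxsub.calibration` bundles four studies, each simulating with outgroup
branch 0 so ancestral inference is exact:

* **CpG recovery** — 100 regions × 5 kb under `cpg` (k = 1.4, ingroup
  branches 0.05); the estimated CG/non-CG C→T rate ratio should sit within
  3 delta-method standard errors of 1.4.
* **Uniform rates** — 100 regions × 5 kb, branches 0.10, radius 1; pooled
  Ts:Tv should be within 3 SE of 0.5 (one transition vs two transversions,
  an identity that holds at any divergence for this symmetric model), and
  the across-context fold variation is compared with the envelope of 20
  replicate simulations at identical parameters.  The envelope is extended
  to [0.8·min, 1.25·max] because the primary run is a 21st exchangeable
  draw: with a bare min/max envelope it would fall outside with probability
  ≈2/21 by construction, regardless of correctness.  Radius 1 is used
  because reaching the 50-transition/50-transversion row threshold at
  radius 3 would require tens of millions of sites.
* **Stationary composition** — 30 regions × 2 kb under `f81` from a
  stationary start; observed per-context focal-base frequencies are
  compared with the analytic equilibrium as z-scores using the site count
  (records/2) as the effective sample size, since the two ingroup records
  per site are correlated.  With 64 (context, base) cells, a per-cell 3 SE
  rule would fail ~16% of seeds by multiplicity alone, so the familywise
  rule is: at most 2 of the 64 cells beyond 3 SE and none beyond 5 SE.
* **Equilibrium agreement** — 30 regions × 2 kb under `at_bias` (s = 3)
  with a burn-in of 6 substitutions/site; squared correlation between
  predicted (stationary) and observed A+T% across contexts should exceed
  0.9.  A context-*independent* model cannot power this comparison — all
  contexts share one equilibrium and the correlation would be noise against
  noise — so the stationary-start accuracy check and the r² check
  deliberately use different generating models.

These sizes keep the full battery to a few minutes on one CPU while leaving
the binomial error bands at a few percent.

## Numerical conventions

Bases are ordered A, C, G, T everywhere (serialization contract);
complementation is index reversal.  Canonical representatives are the
lexicographically smaller concatenated context string.  Count tables are
dense int64 arrays of shape (4^(2r), 4, 4); TSV serialization writes one
row per nonzero cell and round-trips exactly.  All randomness flows through
`numpy.random.Generator` seeded from explicit integers; per-region streams
are `SeedSequence` children of the master seed.

## Known limitations

* Rates are uncorrected proportions; at divergences well beyond ~0.1
  substitutions/site the conservation filters and multiple hits bias them
  downward.
* The eligibility filters condition on conserved flanking context; under
  strongly context-dependent models this mildly under-samples fast-flank
  contexts (second-order at the target divergences).
* Stationary vectors of sparse matrices are frequently degenerate; they
  are flagged, and analyses that need non-degenerate equilibria should
  raise `min_subs` rather than trust zero-frequency vectors.
* The 70-column region filter applies to alignment columns, standing in
  for a pre-alignment length filter that cannot be reproduced without the
  original region extraction.
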