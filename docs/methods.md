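# Methods

## Clonotype identity and the support filter

A clonotype is keyed by its CDR3 amino-acid sequence. The default key
deliberately excludes the V gene: sharing across samples is defined on
CDR3 amino-acid identity, with observed V calls carried along as
annotations and reported per shared clonotype (`v_plus_cdr3_aa` key mode
is available when stricter identity is wanted). CDR3 strings are treated
as opaque tokens — no anchor trimming or normalization beyond
upper-casing — so clonal identity is exactly string identity as emitted by
the upstream clonotype caller.

Read support is summed over all records mapping to one key *before* the
support threshold is applied (`min_reads = 6`, i.e. strictly more than
five reads): nucleotide-level variants of one amino-acid clonotype pool
their evidence. A `filter_before_collapse` flag applies the threshold
per-record instead, for sensitivity analysis. Whether non-productive
records are removed first is left to the caller; the reader preserves the
`productive` flag so either policy can be applied.

Ties are broken everywhere by descending count, then lexicographic key.
All writers emit fixed-column TSV sorted this way, so identical inputs
produce identical bytes.

## The sharing statistic

For samples i and j with unique-clonotype counts X_i and X_j and shared
count Y_ij, the normalized sharing count is

    NormY_ij  = Y_ij / ((X_i + X_j)/2)^2
    NormψY_ij = (Y_ij + ψ) / ((X_i + X_j)/2)^2,   ψ = 0.01 by default.

The quadratic denominator reflects the empirical power law Y = aX² for
the number of clonotypes two repertoires of size X share; NormY is then
an estimator of a, and is invariant in expectation under uniform
clonotype subsampling (thinning keys at rate q scales E[Y] by q² and X by
q). The pseudocount is added to *every* pair, not only zero-sharing ones:
a conditional shift would bias comparisons between groups that differ in
their zero fraction. Normalization of an empty repertoire (X = 0) is an
error, never NaN — silent NaNs would propagate into group tests.

Public clonotypes are keys carried by ≥ 2 distinct individuals
(configurable); keys recurring in ≥ 2 samples of exactly one individual
form the complementary within-individual shared set. Detection can be
restricted to one timepoint, supporting both pooled-per-donor and
per-timepoint analyses.

Group comparisons (e.g. NormψY between treatment groups) are thin,
explicitly labeled wrappers over scipy.stats: Kruskal–Wallis, unpaired t,
or Mann–Whitney U (exact permutation null when both groups have ≤ 8
observations). All-identical inputs are reported as the exact null
(statistic 0, p = 1) rather than NaN.

## SHM profiling

IgHG analysis first removes non-productive, incomplete-V and non-IGHG
clonotypes (each removal tallied, never silent). Mutation counts are
consumed as integers from upstream germline alignment over FR1–FR3 — CDR3
is excluded because junctional diversity is indistinguishable from
hypermutation there — and this package never computes alignments itself.

Histograms use five closed integer bins, 0–5 / 6–10 / 11–15 / 16–20 /
>20. Five bins are the analysis convention; the specific edges are a
package choice aligning the second boundary with the ≤ 10-mutation
headline cutoff, and are configurable and recorded in output metadata.
Histograms and the low-mutation percentage are clonotype-weighted (each
clonotype counts once regardless of read support). The paired day-0 vs
post-vaccination comparison uses a two-sided paired t test on the
per-individual changes in pct_low; zero-variance deltas (all identical)
are reported as the degenerate null with an explicit flag. Responder
labels are high iff the day-84 − day-0 titer rise strictly exceeds
500 AU.

## The synthetic cohort generator

The generator emulates the data structure the analyses assume, at desk
scale, with every planted feature recorded in a truth object:

* **Cohort shape** — 8 individuals, timepoints 0/63/84 days, ~200 cells
  per sample, mirroring a three-dose vaccination schedule with sorted
  populations of 150–1,000 cells.
* **Clone sizes** — cells per clone follow a discrete power law truncated
  at the sample size. The default exponent 3.3 gives a mean clone size of
  ~1.25 cells, i.e. ~160 unique clonotypes per 200 cells with a handful
  of clones crossing the 2% expansion line; steeper than the 2.5 often
  quoted for bulk repertoires because a small sorted-cell sample is
  dominated by singletons.
* **Reads per cell** — shifted Poisson, 1 + Poisson(19): deep enough that
  the more-than-five-reads filter retains nearly all true clones, while
  still exercising the threshold.
* **Key universe** — private keys are random 12-mers with a 2-letter
  prefix unique to each individual; planted public keys use a reserved
  prefix. Cross-individual collisions are therefore structurally
  impossible, so planted publicity is cleanly separated from generator
  artifacts. Public keys are planted with 2 cells per carrier (read
  support far above the filter), never persist outside their configured
  timepoints, and default to 6 keys in 5 of 8 individuals at day 63.
* **Persistence** — within an individual, each new clone reuses a
  previously seen key with probability 0.2, producing the
  within-individual sharing across timepoints that the public/within
  classification must distinguish.
* **SHM mixture** — mutation counts are a two-component Poisson mixture
  (means 6 and 20, for memory-derived low-SHM vs germinal-center-derived
  higher-SHM clonotypes). The low-component weight is 0.3 at day 0 and
  rises to 0.6 post-vaccination in planted high responders only. The
  closed-form mixture probability of ≤ 10 mutations is stored in the
  truth record, so estimates can be checked against an analytic value.
* **Titers** — log-normal baseline with a uniform boost of 800–2,500 AU
  for the 7 planted high responders and 0–300 AU for the 4 low
  responders, so the > 500 AU labeling recovers the planted split
  exactly.

What the generator does *not* emulate: V(D)J recombination biology
(convergent recombination, CDR3 length/gene-usage distributions),
sequencing error, cross-reactive near-identical CDR3s, or
individual-level covariates. Passing tests therefore demonstrate the
correctness and calibration of the *analysis* under the stated
statistical structure, not that real repertoires follow that structure.

## Numerical choices and problem sizes

* The 2% expansion boundary is evaluated on integer read counts
  (count ≥ threshold × total − 1e-9) so a clone at exactly 2.000% is
  always included regardless of float rounding.
* Frequency vectors (including the top-N "other" residual) must sum to 1
  within 1e-9; histogram bin fractions likewise.
* Power-law recovery uses 10,000 Poisson pairs over X ∈ {50, 100, 200,
  500}; subsampling invariance uses 250 pairs at X = 400 thinned at 50%.
  Null calibration runs 100 seeded unplanted cohorts. These sizes hold
  Monte-Carlo error well below the tolerances being checked while keeping
  a full run in tens of seconds.
* All randomness flows through `numpy.random.default_rng` seeded from the
  caller; identical configs (including seed) produce byte-identical
  outputs, which the suite asserts.

## Known limitations

* Sharing is exact-match only; no clustering of similar CDR3s, no TCR
  specificity prediction.
* The reader supports AIRR Rearrangement TSV and vdjtools tables, not raw
  FASTQ/BAM or IMGT archives; UMI consensus building and mutation calling
  are upstream concerns.
* `sharing_per_donor` counts keys shared with any other individual at the
  same timepoint; donors sampled at different timepoint sets are compared
  only where timepoints coincide.
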