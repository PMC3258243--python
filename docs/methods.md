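# Methods notes

This note records the models implemented in `barcodelim`, the assumptions
behind them, the defaults and why they were chosen, and the places where a
genuine design choice had to be made.

## Distances

Uncorrected p-distances are used throughout: the fraction of mismatching
positions among positions where both sequences carry an unambiguous base.
Gaps, `N`, `?` and all IUPAC ambiguity codes are treated as missing and
deleted pairwise (they are stored verbatim in the alignment).  A pair with
no comparable position has an *undefined* distance (NaN) — never zero — and
is excluded from summaries with a logged count; clustering refuses matrices
containing undefined pairs rather than guessing.

Model-corrected distances (K2P and relatives) are deliberately not offered:
for threshold-based barcode grouping the raw proportion is the quantity of
interest, and corrections only inflate deep distances without affecting the
intra/inter separation the method relies on.

Global intra-/interspecific means are means over specimen pairs, not
species-pair averages of averages; per-species figures average that
species' internal pairs.  Singletons have no intraspecific distance and are
reported as `n/a`.  The cryptic-species screen flags species whose *mean*
intraspecific distance strictly exceeds the cutoff (default 3%, the
conventional barcode screening value); the maximum is available via
`statistic="max"` since "divergence above X%" is ambiguous between the two
readings.

## Objective clustering

Clusters are connected components of the `d ≤ t` graph — single linkage by
transitive closure, so any sequence within the threshold of any cluster
member joins that cluster.  The comparison is closed (`≤`); for pairs lying
exactly on a printed threshold an open comparison could differ, which is
why the operator is documented here.  Labels are deterministic (each
cluster is named after its lexicographically smallest member), making
output diffable and order-independent; clustering is invariant under input
permutation, and partitions at increasing thresholds are nested
coarsenings (both properties are tested).

Haplotype collapse removes exact full-string duplicates only (first
occurrence kept).  Near-duplicates differing in missing data are retained:
collapsing them would make the result depend on comparison order.

## Congruence scoring

A candidate group is *perfect* / *lumped* / *split* as defined in the
README; *lumped* takes precedence for groups that contain several species
one of which is incomplete, which is the only convention under which the
three counts partition the groups.  Specimens without a reference label
(e.g. females that cannot be diagnosed morphologically) are dropped from
both partitions before scoring, with a logged count.  Because the split
count tallies candidate groups rather than affected species, the number of
split *species* is reported alongside.  Percentages are rounded to one
decimal in tabular reports and two decimals in machine output.

## GMYC

### Likelihood

The single-threshold mixed Yule/coalescent model treats inter-event waiting
times as exponential under the summed rate

    b_i = λ₁ n_div,i^p₁ + λ₂ Σ_j (n_j,i (n_j,i − 1))^p₂ ,

with `ln L = Σ_i (ln b_i − b_i x_i)` over all intervals, including the last
interval running to the present.  `n_div,i` counts *species* lineages: all
lineages during intervals above the threshold, and a constant count equal
to the number of lineages crossing the threshold below it — a species
persists while its gene copies coalesce.  One-lineage entities contribute
zero coalescent rate (0^p := 0, including p = 0).  The scaling exponents
are boxed to [0, 10], the standard setting of the original software.  An
independent tree-traversal implementation of this likelihood lives in the
test suite and must agree to 1e-9 relative.

### Fitting

Candidate thresholds sit at midpoints between consecutive distinct node
ages, plus one candidate above the root (the null configuration).  Exact
age ties are broken with a deterministic jitter of 1e-9 × root age, ordered
so parents stay older than children.  Whether the original software places
candidates at node ages or between them is not documented; midpoints avoid
the boundary ambiguity of the closed/open comparison at a node age.

Per candidate, (λ₁, p₁, λ₂, p₂) are optimized by bounded L-BFGS-B with an
analytic gradient, in (log λ, p) coordinates (log-rates bounded to
[−30, 15]), from three deterministic starts: exponents at 1 with
moment-matched rates (events/integrated rate for each component), and the
same construction at exponents 0.5 and 2 — the surface is low-dimensional
but can be multimodal in the exponents.  The null-configuration candidate
additionally starts from the fitted null parameters, which guarantees
`lnL_max ≥ lnL_null` up to round-off (the inequality is asserted).  The
null model `b_i = λ (n_i(n_i−1))^p` is fitted by profiling λ analytically
and optimizing p on [0, 10].

### Entities, confidence set, test

Entities are the lineages crossing the best threshold; tips whose parent
node is older than the threshold are singletons.  The entity-count
confidence set is the min–max entity count among candidates within 2
log-likelihood units of the maximum.  The LR statistic 2(lnL_max −
lnL_null) is referred to χ² with df = 3 (5 alternative parameters against
2), the df = 2 convention being reported alongside.  Because the threshold
is a non-regular parameter the χ² reference is approximate; a calibration
experiment on single-population coalescent trees (25 tips, 500 seeded
replicates — the package's null-calibration study, also run as a test)
measured a false-rejection rate of 7.4% at df = 3 versus 16.6% at df = 2 at
the nominal 5% level, confirming df = 3 as the primary reference.

## β-diversity and the regional/local comparison

Sørensen similarity is computed exactly as `QS = 2C/(A+B)`; a site with no
species makes its pairs undefined rather than zero.  Reports show shared
counts in the upper triangle and QS (2 decimals) in the lower, with full
precision in machine output.

The regional/local comparison recomputes, per threshold, each area's
clustering against that area's own morphospecies, and the pooled dataset
against the full reference; agreement and accuracy are *relative* values
(percent of each dataset's own morphospecies count), so areas of different
richness are comparable.  The 95% interval on the per-area values uses
Student-t with n−1 df — the small-sample default for seven areas; a
normal-quantile alternative is available by flag.  A zero-variance set of
area values degenerates to a point interval, and the pooled value is
flagged when strictly outside.  Note what the interval is: a confidence
interval for the *mean* of the area values.  Its nominal 5% error rate
applies to excluding that mean (verified by simulation in the tests); a
pooled value that estimates a genuinely different quantity can fall outside
far more often, which is precisely the signal the comparison looks for.
Areas with fewer than two labelled specimens are excluded with a warning.

## Synthetic data generator

The generator emulates the statistical structure the analyses assume, not
sequence evolution per se:

- **Divergences.**  Species ancestors radiate in a star from a genus root;
  per-species root divergence fractions are drawn from a Beta distribution
  on a band calibrated so that realized tip-to-tip interspecific distances
  hit the target mean (default 19.8%) inside the target band (12–24%),
  *net of* the intraspecific variation that specimen-level mutation adds.
  Specimens mutate from their species ancestor at per-species rates drawn
  from a clipped exponential with mean matching half the intraspecific
  target (default mean pairwise 1.28%); the exponential tail reproduces the
  observed pattern that roughly a tenth of morphospecies exceed the 3%
  screening cutoff.  Substitutions hit uniformly random sites — no rate
  heterogeneity, codon structure or indels.  Distances, not phylogenetic
  realism, drive every downstream analysis; this is a documented
  limitation, and passing tests say nothing about alignment quality or
  model-based tree inference on real data.
- **Geography.**  Seven areas by default; species occupy k areas with
  probabilities proportional to (259, 10, 2, 0, 1) for k = 1..5 — the
  observed shape of a hyperdiverse montane fauna, ~96% single-area.  A
  configurable fraction of multi-area species (default 0.1) receives
  per-area sub-ancestors 2–9% apart, emulating geographically structured
  haplotype pools.
- **Label errors.**  A fraction of species (default 0.033) is hidden
  behind another species' label (cryptic merge), a fraction (default
  0.015) is split across two labels, and ~1.3% of specimens lose their
  label entirely (unassignable specimens).  All injections are recorded,
  and the expected congruence of the true partition against the labels is
  computable in closed form (each merge ⇒ two split groups; each oversplit
  ⇒ one lumped group); the closed form must equal the pipeline output
  exactly, which is tested.
- **Chronograms.**  The tree generator implements the mixed generative
  process directly: a pure-birth species tree (birth rate = 1/depth scale)
  in which every species tip carries a stem of at least one depth-scale
  unit, and below each tip a neutral Kingman coalescent genealogy.  The
  generative threshold is explicit: genealogies are drawn conditioned
  (by rejection) on their root age staying below `threshold_depth`,
  default 4 × the coalescent scale.  Unconditioned coalescent root depths
  have an exponential tail, and a single species whose genealogy is
  several-fold deeper than the rest *is*, by the model's own likelihood, a
  two-entity configuration — such trees do not come from a process with a
  single threshold, which is what this generator is defined to produce.
  The factor 4 is the smallest round multiple that separates the regimes
  while leaving the coalescent essentially unconditioned (≳96% acceptance
  per species at the default scales).  The single-species case (used as
  the null process in calibration) is an unconditioned plain coalescent.
- **Determinism.**  Every stochastic call flows from one
  `numpy.random.default_rng(seed)`; identical configuration and seed give
  bit-identical output.

## Problem sizes used in the test suite

Simulation-backed guarantees run at sizes chosen to make the checks sharp
while keeping the suite quick: clustering versus the connectivity oracle on
200 random instances of 10–40 sequences; GMYC species-count recovery on 100
seeded trees of 20 species × 5 tips at a species/coalescent timescale ratio
of 50 (≥95 must recover exactly); null calibration on 500 single-population
trees of 25 tips; CI coverage on 2000 replicates of 7 area values; and one
end-to-end run at full study scale (270 species, 7 areas, ~950 sequences,
with GMYC on a 240-tip chronogram).

## Known limitations

- The sequence generator's star phylogeny has no between-species tree
  structure, so it cannot produce paraphyletic morphospecies or test
  tree-based diagnosis.
- GMYC here is single-threshold only; multiple-threshold and Bayesian
  variants, and chronogram estimation itself, are out of scope (ultrametric
  trees are inputs).
- The χ² reference for the LR test is approximate (non-regular threshold
  parameter); p-values near 0.05 should be read accordingly.
- Polytomies are rejected rather than silently resolved: how ties were
  handled upstream of the original analyses is undocumented, and arbitrary
  resolution would move likelihood mass invisibly.
- Two printed similarity values in one published six-locality table are
  inconsistent with QS = 2C/(A+B) applied to that table's own counts (they
  match C/(A+B)); the stated formula is implemented, so those two cells are
  not reproduced.
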