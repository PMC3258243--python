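# barcodelim

Molecular biodiversity assessment for hyperdiverse, mostly undescribed
communities from DNA barcodes.  `barcodelim` re-implements, as a tested and
reusable library, the workflow used to survey species-rich arthropod faunas
with cox1 barcode data: objective (distance-threshold) clustering, single
threshold GMYC species delimitation on a chronogram, congruence scoring of
molecular entities against morphospecies hypotheses, Sørensen β-diversity,
and the comparison of regional versus local clustering.  A synthetic-data
generator with full ground truth stands in for field collections, so every
stage is testable without sequence downloads.

It is aimed at people running barcode-based biodiversity surveys —
taxonomists cross-checking morphospecies sorts against molecular groups,
and community ecologists who need defensible species-level units for α/β
diversity work.

## Methods

**Distances.** For aligned sequences the uncorrected p-distance is
`d = m / n`, where `n` counts positions at which both sequences carry an
unambiguous base (A/C/G/T; gaps, N, `?` and IUPAC ambiguity codes are
deleted pairwise) and `m` counts mismatches among them.  Per-morphospecies
mean intraspecific distances above a 3% cutoff flag candidates for cryptic
species scrutiny.

**Objective clustering.** At a user-preset threshold *t*, clusters are the
connected components of the graph linking sequences with `d ≤ t`
(single-linkage transitive closure).  Sweeping *t* from 1–12% traces the
cluster count through the barcoding gap.

**Congruence.** Each molecular group is *perfect* (all and only the members
of one morphospecies), *lumped* (≥2 morphospecies) or *split* (part of one);
lumped takes precedence, so the three counts partition the groups.  With
`S` morphospecies, `G` groups and `P` perfect groups:

    agreement = 100 · G / S        taxonomic accuracy = 100 · P / S

Agreement above 100% signals overestimation of species diversity.

**GMYC.** On an ultrametric tree, branching events older than a threshold
age *T* are modelled as a Yule process on species lineages and younger
events as neutral coalescence within species.  Between successive events
the waiting time `x_i` is exponential with rate

    b_i = λ₁ · n_div,i^p₁  +  λ₂ · Σ_j ( n_j,i (n_j,i − 1) )^p₂ ,

where `n_div,i` counts species lineages and `n_j,i` the lineages of entity
*j*; `ln L = Σ_i [ln b_i − b_i x_i]`, with scaling exponents `p₁, p₂`
constrained to [0, 10].  The fit maximizes over candidate thresholds at
midpoints between node ages; lineages crossing the best *T* are the
delimited entities, candidates within 2 log-likelihood units give an entity
count confidence set, and a likelihood-ratio test (χ², df = 3; the df = 2
convention is also reported) compares the mixed model to a one-process
null.  Identical haplotypes should be collapsed first
(`collapse_haplotypes`) and can be re-attached to their entities afterwards
(`expand_entities`).

**β-diversity.** For two sites with `A` and `B` species of which `C` are
shared, the Sørensen similarity is `QS = 2C/(A+B)`.  The regional-vs-local
comparison clusters each area separately and the pooled dataset as a whole,
expresses agreement/accuracy relative to each dataset's own morphospecies
count, and flags thresholds where the pooled value falls outside the 95%
Student-t confidence interval of the per-area values.

## Worked example

```python
import barcodelim as bl

tree, truth = bl.simulate_gmyc_tree(
    k_species=25, tips_per_species=4,
    species_depth_scale=1.0, coalescent_scale=0.02, seed=7,
)
result = bl.gmyc_fit(tree)
```

Running `python examples/03_gmyc_delimitation.py` (the script around the
snippet above) prints:

```
tree: 100 tips, root age 3.37
entities: 25 (0 singletons), confidence set 25-25; true species count 25
threshold age: 0.5511
lnL 519.01 vs null 446.16; LR = 145.70, p = 2.23e-31 (chi2, df=3)
entity partition identical to simulated species: True
```

The fitted threshold age (0.55) falls between the within-species
coalescent timescale (~0.03) and the shallowest speciation (~1.0), the 25
lineages crossing it match the simulated species exactly, and the LR test
overwhelmingly rejects the one-process null — the tree really does contain
two branching regimes.  The other scripts in `examples/` walk through
threshold sweeps, congruence scoring, β-diversity, the regional-vs-local
comparison and cryptic-species screening, each printing the numbers it
computes and what they mean.

A thin CLI mirrors the library (`barcodelim distances | cluster | sweep |
congruence | gmyc | beta | simulate`); run `barcodelim --help`.

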