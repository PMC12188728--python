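# Methods

## The paired design

The unit of analysis is a genus-level pair: one host-associated genome
matched with one free-living genome of the same genus. Pairing removes
most of the phylogenetic signal that would otherwise dominate any
host-versus-free contrast, at the cost that every statistic must
respect the pairs. The data model enforces the invariant at read time
(each `pair_id` → exactly one host + one free genome, same genus), and
the MAG quality filter (keep MAGs with completeness ≥ 50% and
redundancy ≤ 10%, boundaries inclusive; WGS bypasses the filter) drops
a *whole pair* when it removes one member, because an orphaned genome
cannot contribute to any downstream statistic. Re-validation after
filtering therefore always passes.

## Module completeness

A module definition is an ordered list of steps, each a set of
alternative KOs; a step is satisfied when any alternative is present
(OR within a step, AND across steps) and completeness is the fraction
of satisfied steps. This simplified grammar (steps separated by `;`,
alternatives by `,`) deliberately approximates the full KEGG boolean
module grammar, which supports nested operators this package does not
attempt to parse; "75% of the KOs required" is implemented as 75% of
*steps*, the closest simple reading, and documented as such.
Completeness is monotone non-decreasing in the KO set, and presence at
a stricter threshold implies presence at a looser one — both are
property-tested. Zero-variance filtering operates on the completeness
*values* (not the presence calls), since the ordination consumes the
continuous profiles.

## Paired odds ratios

For KO *k*, only discordant pairs are informative: with *a* pairs
host-only and *b* pairs free-only, `OR = (a + 0.5)/(b + 0.5)`. The 0.5
offset keeps the ratio finite and maps a fully concordant KO to
exactly 1. When a genus contributes several genomes per lifestyle the
matching within that genus is arbitrary, so the pairing is redrawn as
a uniform-random within-genus bijection, 100 times by default, and the
median OR (midpoint convention for even counts) is retained. One
master seed spawns one RNG substream per replicate, so results are
independent of KO iteration order and bitwise reproducible. KOs never
observed in any genome are dropped (with a logged count) before any
percentile computation: the KO universe is the observed set.

Tail classification uses inclusive boundaries: host-enriched iff
`median OR >=` the upper percentile (computed with the "higher"
quantile convention), free-enriched iff `<=` the lower percentile
("lower" convention); on *n* distinct values at 5/95 this yields
exactly the top and bottom 5% by rank. Real KO collections carry a
large neutral mass at OR = 1; when a tail threshold lands exactly on
1, KOs with OR = 1 are excluded from that tail so the neutral mass can
never flood a tail. Class-restricted runs (e.g. one class at 1/99) are
the same operation on the subset table.

## Module enrichment

Per module, the two completeness values of each pair are compared;
ties are excluded (classical sign test — the per-module tie count is
reported) and the two-sided p-value is the doubled smaller tail of
Binomial(n untied, ½), capped at 1. BH correction is applied across
modules via `statsmodels`; undefined tests (all pairs tied) propagate
as NaN and do not participate in the correction. The test compares
completeness *fractions*, not presence calls, so modules that shift
without crossing the presence threshold still register.

## Ordination and PERMANOVA

Bray–Curtis `d(u,v) = Σ|u−v| / Σ(u+v)` on the variance-filtered
completeness profiles (an all-zero profile is an error — the distance
is undefined). PCoA is classical Torgerson double-centering +
symmetric eigendecomposition; axes with positive eigenvalues are
returned, negative eigenvalues are reported unchanged (no
Lingoes/Cailliez correction). PERMANOVA is the one-factor Anderson
pseudo-F on squared distances with seeded label permutations and the
add-one p-value convention, default 999 permutations. Both are
implemented in-package because seeded determinism is a hard
requirement of the pipeline contract; the test suite cross-checks
eigenvalues and the pseudo-F statistic against scikit-bio, and checks
the permutation p against exhaustive enumeration at n = 6 and the
type-I error rate against the nominal 5% level. Each factor
(lifestyle, class) is tested in a separate one-factor run; the paired
structure is *not* used as permutation strata, a known limitation of
this formulation.

## Metabolic scope and added value

Scope is qualitative network expansion: starting from the seed
(growth-medium) compounds, a reaction fires when all its substrates
are reachable and adds its products, to the least fixed point.
Reversible reactions are split into two directed reactions first;
stoichiometry is ignored throughout (the optional SBML reader
extracts species references and the `reversible` flag only). Scope is
monotone in seeds and reactions and idempotent; the implementation (a
worklist with per-compound notification) is verified against a naive
iterate-until-stable oracle on hundreds of random networks. Added
value = scope(host ∪ bacterium) − (scope(host) ∪ scope(bacterium));
it is disjoint from both individual scopes by construction, so seed
compounds can never appear in it and no currency-metabolite
special-casing is needed.

Group comparison: per compound, the counts of organisms per lifestyle
whose added value contains it are treated as discordant counts in a
two-sided exact binomial at p = ½, BH-corrected across compounds; per
organism, |added value| is analysed with a two-way ANOVA
(class × lifestyle with interaction, type-II sums of squares chosen
for the unbalanced class sizes) and Tukey HSD for class. An empty
design cell drops the interaction with a warning.

## Synthetic data

The generator reproduces the *shape* of the study rather than any
real genome content: 72 genera (= 72 pairs at the default one genome
per lifestyle per genus) assigned to four classes with 3/8/29/32
genera respectively; 5,000 background KOs present i.i.d. with a
per-class probability (base 0.3, jittered uniformly ±0.15 per class —
identical across lifestyles, which produces the class-level clustering
that ordination should detect and no spurious lifestyle signal); 50
planted KOs present with probability 0.9 in host-associated and 0.1 in
free-living genomes — the planted-recovery condition the OR pipeline
is required to meet; 60 modules of 2–6 steps with 1–3 alternatives, of
which 8 are built entirely from planted KOs so module enrichment has
ground truth. Synthetic FASTA uses i.i.d. bases at a programmed GC
(default 40%, a mid-range value for marine heterotrophs) and 200 kb
per genome — far below real bacterial genome sizes, a deliberate
choice since only length and GC are ever computed from sequence and
GC precision at 200 kb (±0.2%) is ample. Reaction networks: 8 seed
compounds, a 60-compound random pool, 40 random reactions per
organism, 28 bacteria per lifestyle with class sizes 4/12/10/30; each
host-associated bacterium receives 3 planted cross-feeding motifs
(host converts a seed into a dedicated intermediate; the bacterium
converts intermediate + seed into a dedicated product) whose products
are provably in the cooperation's added value because the dedicated
compounds occur nowhere else.

What the generator does **not** emulate: phylogenetic correlation
beyond class-level presence probabilities, gene-order or sequence
realism, copy numbers, KO co-occurrence structure within real
pathways, and stoichiometric constraints. Passing tests therefore
demonstrate the correctness and calibration of the statistics under
the declared design, not biological conclusions about real genomes.

## Numerical choices and degenerate inputs

- Median over an even number of re-pairings: midpoint of the central
  values.
- Percentile conventions as above; empty OR tables, zero modules after
  variance filtering, unbalanced genera, and groups of size < 2 raise
  typed errors rather than returning silently degenerate output.
- GC content over a sequence with no unambiguous base is NaN (not an
  error); ambiguous bases count toward length only.
- The sign test with zero untied pairs returns NaN with direction
  `none`.
- All stochastic stages take explicit integer seeds; the pipeline
  derives per-stage seeds from the single config seed, and reruns are
  byte-identical (manifests contain no timestamps).

## Problem sizes in the test suite

Tests run the full study-scale configuration where it is cheap (144
genomes × 5,050 KOs × 100 re-pairings completes in about a second,
vectorised) and scaled-down toys where exhaustive enumeration is the
oracle (4-pairing re-pairing toys, 6-point PERMANOVA with all 720
permutations, ≤ 30-reaction networks). Calibration checks use 200
simulated datasets for the PERMANOVA type-I rate and 200 null
replicates for FDR control.
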