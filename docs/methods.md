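# Methods

## The one-to-one map

Pairwise alignment chains describe candidate homologies as ordered
lists of gapless blocks with gaps (`dt` on the reference, `dq` on the
query) between them. Chains from a single alignment run overlap freely
on both genomes, so they do not define a function, let alone a
bijection. `build_bijective_map` resolves overlaps by greedy
score-descending claim-and-trim on **both genomes simultaneously**:
chains are visited from highest score to lowest (ties broken by larger
aligned-base count, then smaller chain id), and each gapless block
keeps exactly those base pairs whose reference base *and* query base
are still unclaimed. Because a base pair is dropped or kept as a unit,
the surviving relation is one-to-one by construction, and building the
map from the swapped chain set yields the identical set of base pairs
(verified as a property test). This plays the role of selecting and
re-chaining the first layer of an alignment net; the exact netting
heuristic of the original alignment tooling is deliberately not
reproduced — the contract is the bijective reciprocal map itself, and
the per-base greedy claim table serves as the independent oracle in the
tests.

Trimming may fragment a gapless block into several paired blocks;
single-base fragments are kept (no minimum length — a length filter at
this stage would silently change coverage). All in-memory coordinates
are 0-based half-open on the '+' strand; minus-strand query coordinates
of a chain are converted at block-pairing time (`pos' = size − pos`),
and inverted orientation is recorded on the paired block. Chromosome
names are compared as exact strings.

## Interval mapping and its filters

An interval maps to the `[min, max)` span of its partner bases on the
other genome; internal unaligned gaps are tolerated inside the span.
Two filters remove ambiguous cases before a target is reported:
elements overlapping paired blocks of two or more distinct chains
(`FILTERED_MULTI_CHAIN`) and elements whose partners fall on two or
more chromosomes (`FILTERED_MULTI_CHROM`). Since a chain pairs with a
single query chromosome, the second filter can only fire when chain
ids are not unique; it is kept for defensive completeness. Any element
with at least one partnered base maps (the success event used
throughout is an overlap of 1 bp); `--min-frac` can impose a stricter
mapped-base fraction.

`roundtrip` verifies the bijectivity guarantee: the partner segments of
an element are mapped back and must reproduce exactly the partnered
source bases. It is defined on partner-base sets rather than by
re-mapping the target span, because the span may legitimately straddle
a second chain's territory (its internal gaps can be claimed by other
chains after cleaning), which would trip the multi-chain filter on the
return journey even though the underlying relation is perfectly
invertible.

## Classification

A peak set is first reduced to elements overlapping a DHS (open
chromatin) interval by ≥ 1 bp — occupancy calls without accessibility
support are discarded. Each mappable element's target span is then
intersected with the comparison species' (DHS-filtered) peak
compendium, indexed by (cell type, TF) assay key. Presence of the
(analog cell, same TF) key makes the element `FUNCT_CONS` regardless of
other overlaps: conservation of the same factor dominates repurposing.
Otherwise any overlap means `FUNCT_ACTIVE`, none means `SEQ_CONS`, and
unmappable elements are `SPECIES_SPECIFIC`. The four categories are
mutually exclusive and exhaustive. Category fractions are reported over
mappable elements (summing to 1), with the species-specific fraction
reported separately over all elements.

## Statistics

* **Binomial conservation test.** `n` features positioned at random on
  a universe of length `L` hit a region of coverage `C` with
  probability `C/L` each; p-values are exact binomial tails and
  intervals are Clopper–Pearson. The "0.99% CI" phrasing found in this
  literature is read as a 99% confidence level; at that level a
  0.99% interval would be nearly degenerate. For the sequence-level
  test `L, C, n` are genome length, one-to-one mappable coverage and
  feature count; for the activity-level test they are mappable
  coverage, the compendium's mappable coverage, and the mapped feature
  count.
* **Paired signed-rank test** on per-TF FunctCons:SeqCons ratios.
  Zero differences are dropped. Up to n = 25 the exact sign-flip null
  distribution is computed by convolution over doubled midranks — this
  stays exact under tied magnitudes (e.g. a constant shift), where
  generic exact routines refuse; beyond that the normal approximation
  is used. The reported statistic is always W+, the positive-rank sum.
* **Signal comparison.** One-sided Mann–Whitney U (conserved >
  sequence-only), exact when group sizes permit and no ties are
  present; an assay is significant when p < α/m with m the number of
  assay-level tests (Bonferroni). The ratio of group means is reported
  alongside.
* **Exaptation test.** With FA the FunctActive count, nFC the
  non-FunctCons count, and M the coverage of (other genome's mapped
  SeqCons ∪ own FunctActive) on this genome, FA/nFC ≥ M/L is assessed
  by a one-sided exact binomial test with null probability M/L,
  reported with a one-sided lower confidence bound (interval of the
  form (low, 1.000)). M is computed literally as that union's coverage.
* **Target-gene conservation.** Scores are shared-orthologous targets
  over own targets, restricted to the ortholog table on both sides (so
  non-orthologous genes cannot affect any score); distributions are
  compared with a two-sided two-sample Kolmogorov–Smirnov test, and the
  D statistic and p-value are reported without further interpretation.

## Turnover

For each mapped TFBS, the distance to the closest same-TF TFBS of the
analogous cell in the other species is the **edge-to-edge gap** of the
homologous span: 0 when they share a base, the intervening base count
otherwise. This makes "positive distance" coincide with "no overlap",
with one boundary convention: exactly touching intervals (gap 0, no
shared base) are treated as conserved placement, not turnover.
Turnover requires 0 < d < window; the window default is 150 bp and the
boundary is exclusive. The summary fraction's default denominator is
the SeqCons sites (mapped sites with no same-assay occupancy, i.e.
d > 0 or no site on the chromosome); `denominator="mapped"` switches to
all mapped sites. Unmapped TFBS are excluded and counted separately.
Nearest-site lookup uses a sorted-starts array plus a prefix-argmax
over ends, so nested intervals are handled exactly.

## Saturation (assay recycling)

For subset sizes k, assays of the comparison species are sampled
without replacement (independent replicates, default 20, seeded), their
peaks are unioned, and coverage is the fraction of the reference
assay's MAPPED elements whose target span hits the union by ≥ 1 bp. At
k = #assays every replicate equals the classification-derived
(FunctCons + FunctActive)/mappable fraction — an endpoint identity the
tests assert across modules. The null curve repositions every
comparison peak uniformly on the mappable portion of its genome
(lengths preserved, starts drawn from mappable bases, ends clipped at
chromosome boundaries) before sampling.

## The simulator

`tfosmap.synthetic` models coordinates only (no nucleotide sequence).
A per-chromosome walk applies deletions, insertions and inversions
while advancing both descendant coordinate systems from a common
ancestral walk, so the planted homology is bijective by construction.
Event rates are per-base (converted to per-block event probabilities as
`1 − (1 − rate)^blocklen`); block and gap lengths are geometric with
configurable means (defaults: 800 bp blocks, 150 bp gaps, ~86% aligned
on a 100 kb, 2-chromosome genome). Colinear same-orientation runs are
emitted as multi-block chains; each inversion becomes its own
minus-strand chain, because a query interval ascending along the walk
descends on the '+' strand and cannot be chained with its neighbours.
Real chains score 1000 + 10 × aligned bases; decoy chains (score
≤ ~100) lie with their whole reference side inside a planted segment,
so the cleaning must reject every base they offer — making planted
truth and cleaned map identical, which the tests assert exactly.
`random_chains` generates unconstrained overlapping chains for
adversarial oracle tests.

Peak planting carves disjoint slots (40 bp peaks, 20 bp margins) from
the planted segments (mappable categories) and from the unaligned gaps
(species-specific peaks, with a margin so no base touches a segment).
Partner peaks in the comparison species occupy exactly the homologous
span: same-assay partners for `FUNCT_CONS`, other-assay for
`FUNCT_ACTIVE`, none for `SEQ_CONS`. The default mix — 15% FunctCons,
50% FunctActive, 35% SeqCons of 500 mappable elements, plus 100
species-specific — mirrors the observed regime in which repurposed
elements dominate. Signals are lognormal (σ = 0.4) with a 1.3×
multiplicative shift on conserved categories, the magnitude reported
for human assays. All planted peaks are covered by emitted DHS;
requested off-DHS decoys are placed away from any DHS so the filter
must remove exactly them.

TFBS planting displaces each comparison-species partner by an exact
offset from the homologous span (default offsets: half strictly inside
the 150 bp window, half at or beyond it, so the planted turnover
fraction is exactly 0.5). An exclusion hull (max offset + window +
site length) around each planted pair guarantees the nearest site is
always the planted partner; slots violating a hull are skipped and the
plan errors out if candidates are exhausted. Zero offsets are rejected
— overlap is conserved placement by definition. Link planting gives a
chosen number of elements per category an own-genome enhancer–gene
link, and a planted subset (default 43 of 100 FunctActive, 54 of 60
FunctCons) additionally gets the orthologous link at the homologous
site, making retained-target fractions exact by construction.

What the simulator does **not** emulate: nucleotide content and motif
structure, duplications and translocations (duplications would break
the one-to-one truth; ambiguity is instead exercised with decoy
chains), peak-calling noise, signal spatial structure, and correlated
assay occupancy. Passing tests therefore demonstrate the correctness
of the mapping, classification and statistical machinery under
controlled truth — not the biological accuracy of any genome-scale
estimate, which depends on real alignments and compendia.

## Numerical and design choices

* Overlap threshold is ≥ 1 bp everywhere (peaks vs DHS, targets vs
  compendium, TFos vs links, saturation hits), matching the binomial
  success event; it is configurable where it appears.
* Exact tests are used wherever the sample permits; enumeration
  oracles in the test suite confirm agreement to 1e-12 for n ≤ 20.
* Type-I calibration checks simulate each test's null at sizes where
  the exact test's attainable level is close to the nominal α = 0.01
  (large counts keep binomial discreteness negligible); rejection rates
  over 1000 seeded replicates fall within (0.001, 0.03).
* Problem sizes in the tests and the acceptance script — 100 kb
  two-chromosome genomes, 600 peaks, 28 TFBS, 3 comparison assays, 50
  random oracle fixtures of ~2 kb — keep exhaustive per-base oracles
  exact and the whole suite fast while exercising every code path
  (inversions, decoys, multi-chain junctions, unmappable margins).
* The CLI writes a JSON run manifest beside every output (inputs,
  parameters, seed, version) instead of consuming a config file; flags
  fully determine a run and the manifest is the reproducibility record.

## Known limitations

* The netting heuristic of the original alignment tooling is not
  reproduced bit-for-bit; only the bijective-map contract is.
* Multi-segment targets are reported as spans, so a downstream overlap
  against the span can include bases that are internal unaligned gaps.
* Exactly-touching intervals count as distance 0 in the turnover scan
  (see above).
* Enhancer–gene links are consumed as input; inferring them from
  synchronized accessibility is out of scope, as are peak calling,
  motif discovery, and reproducibility (IDR) analysis.
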