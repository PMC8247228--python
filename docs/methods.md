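# Methods

This note documents the models, rules and numerical choices behind
`gutevolve`, and what the synthetic-data generator does and does not
emulate.

## Study system and scope

The pipeline analyses the within-host evolution of a clonal probiotic
strain (one chromosome, four plasmids) ingested by several host subjects
(human, mouse, zebrafish), re-isolated and whole-genome sequenced on days
3, 7, 14, 21 and 28 after the end of administration, together with the
evolutionary response of the resident gut community observed through
shotgun metagenomics. Upstream read mapping, assembly and taxonomic
profiling are out of scope: the pipeline consumes per-isolate stranded
allele-count tables, per-isolate contig sets, relative-abundance tables
and per-species SNP-count tables, and defines thin converter contracts for
producing them from standard callers.

## Isolate SNP calling

A candidate site is evaluated in two layers.

Per isolate-site cell: the call passes when (i) the site quality score is
strictly below 60 — quality here follows the upstream caller's convention
that lower values are stronger variant evidence, and converters must
supply a compatible scale; (ii) at least 7 reads align to the forward
strand and at least 7 to the reverse strand; (iii) the major allele holds
at least 90% of all reads. A 50/50 tie yields no allele: the 90% rule can
never pass a tie, and explicitness avoids arbitrary tie-breaking. A
missing cell (no data for that isolate at that site) fails with reason
`missing` — missingness is deliberately distinguishable from observed
zero coverage so the failure-fraction rule below counts it.

Per site: the site is retained iff (i) at least one pair of passing
isolates is discordant on the called base; (ii) the median total read
count across *all* isolates (missing cells contribute 0) is at least 10;
(iii) the fraction of failing isolates is below 1/3. The boundary is
compared exactly as a rational (`3·n_fail ≥ n_isolates` discards), so no
floating-point rounding can move the printed "33% or more" bound. The
quality criterion is per isolate-site by default; a site-level variant
(median cell quality applied to all isolates) is exposed as
`site_level_quality` for callers that emit one score per site.

The alternate allele of a retained site is the most frequent non-ancestral
allele among passing calls (lexicographic tie-break); additional alleles
are recorded in the audit log, and isolates carrying them are called
ambiguous — sites are treated as bi-allelic downstream. The retained set
is invariant to the order in which sites and isolates are presented, which
is property-tested against a brute-force enumeration of all rules.

## Distances, trees, dMRCA, spectrum

Pairwise distance counts positions with unambiguous, differing calls in
both isolates; the number of comparable positions is carried with every
pair, and a pair with none is flagged undefined rather than zero.
Neighbor joining is delegated to scikit-bio, the tree is rooted on the
ancestral reference (included as an all-ancestral taxon) and negative NJ
branch lengths are clamped to zero with the total deficit recorded.

dMRCA for a set of isolates (one host and time point, typically)
restricts to SNP positions polymorphic *within that set*, counts derived
alleles per isolate there, and averages. Ambiguous calls are excluded
from both the polymorphism determination and the per-isolate counts,
mirroring the pairwise-distance rule. Consequences that are asserted as
invariants: a single-isolate set has dMRCA 0, and adding positions at
which every set member is ancestral changes nothing.

The mutation spectrum partitions the 12 ordered substitutions into 6
strand-symmetric classes. Two weightings are exposed and labelled:
`per_snp` (each SNP once; the default) and `per_isolate` (each SNP
weighted by its unambiguous carrier count). They answer different
questions and can rank classes differently — the bundled confirmed-SNP
table ranks A:T→G:C first under `per_snp` — so neither ranking is
asserted as a test.

## Parallel evolution

A gene's mutations count as parallel evolution when they are repeated and
independent: (i) ≥ 2 SNPs; (ii) maximum pairwise genomic span ≤ 2000 bp —
the span rule guards against long genes collecting scattered hits by
chance; (iii) when genotypes are available, not all SNP pairs perfectly
co-occur (identical derived-isolate sets describe one mutational event on
one haplotype, not independent hits). Without genotype data the
co-occurrence check is skipped and flagged. The SNP density per 2000 bp
over the mutated span is reported as a diagnostic; span and density
formulations agree whenever the mutated span is within the window, which
is property-tested. Both the pooled scope and a per-host scope (rule
evaluated within each host's own SNP set) are reported.

## Mobile elements

Contigs ≥ 500 bp that align to the reference at ≥ 90% identity are core
and removed; survivors are deduplicated (≥ 90% identity over ≥ 85% of the
longer sequence) into non-redundant accessory elements. The alignment
engine is injected behind a small contract (percent identity over the
query, both strands); the bundled engine uses edlib edit-distance
alignment, which is exact and fast at this scale, and BLAST/BLAT-style
engines can be plugged in for production use (the e-value threshold on
the interface is honoured by such engines; an edit-distance engine has no
e-value theory and treats it as advisory).

Presence calling follows the printed thresholds exactly: present iff
coverage > 80% AND depth > 60×; absent iff coverage < 20% OR depth < 60×.
The two rules leave a gap (e.g. coverage 50% at depth 70×) and an overlap
(coverage > 80% at depth exactly 60× satisfies neither); rather than
silently invent a binary call, an explicit `ambiguous` state covers the
gap and the absent rule wins the overlap. The call is monotone in both
coverage and depth (property-tested). Day-level presence frequencies use
present/(present+absent); a day with only ambiguous evidence is reported
missing, not zero.

## Lineage dynamics

SNP frequency at a day is derived isolates / unambiguously-called
isolates; SNPs derived in fewer than 4 isolates overall are dropped as
irreproducible. Frequencies are computed from isolate genotypes (what the
generator produces and what isolate sequencing supports); both pooled and
per-host/per-subject scopes are available.

Interpolation across unsampled days uses a monotone piecewise-cubic
Hermite interpolant (PCHIP) clamped to [0, 1]. Any piecewise cubic is
expressible in Bézier form; PCHIP was chosen because the testable
contracts — passes exactly through observations, stays in [0, 1], is
monotone wherever the observations are — hold by construction, with no
free handle-length parameter.

Sublineages are built from derived-isolate sets. SNPs whose carrier sets
are nearly identical (symmetric difference within a 10% tolerance,
majority vote for membership) define one lineage — they co-occur because
they arose on one sweeping haplotype. Lineages are then ordered by
set inclusion with the same tolerance; overlapping-but-not-nested pairs
are conflicts, and if conflicting isolates exceed 10% of the cohort the
build aborts demanding manual curation rather than guessing. Naming
follows the E1 / E1-A / E1-B-1 convention by descending lineage size.

Muller decomposition: exclusive(parent) = max(0, raw(parent) − Σ raw
children), the clamp encoding that a parent fully displaced by its
children keeps zero frequency. Per-day exclusive frequencies sum to at
most 1 (tolerance 1e-9), and the operation is idempotent on its own
output treated as leaves.

Cross-host comparison: each host is summarised as a Jaccard distance
matrix between its per-day sets of segregating SNPs (frequency above a
configurable threshold, default 0), and a Mantel test (Pearson on
condensed distances, row/column-permutation null, explicit seed) compares
hosts. The in-package Mantel exists because a seedable permutation test
was required; it is cross-checked against scikit-bio's implementation in
the test suite. With only five sampling days the permutation space is
5! = 120, so attainable p-values are bounded below by ~1/120 — exact
small-sample behaviour, not an artefact.

## Community co-evolution

Relative abundances are CLR-transformed after multiplicative zero
replacement (δ = 0.65 × the row's smallest nonzero value, non-zeros
rescaled to preserve the unit sum; a uniform-pseudocount strategy is also
available). The co-occurrence stage is a documented stand-in for sparse
inverse-covariance methods: Spearman correlations on CLR values,
per-pair permutation p-values (independent column shuffles), and
Benjamini–Hochberg FDR at q = 0.05. Species with a significant negative
edge to the probiotic are competitors; significant positive edges are
labelled positive associates. Because CLR is compositional, suppressing
competitors mechanically inflates the CLR values of everything else, so
uncoupled species can show positive association with the probiotic — the
stand-in therefore only labels, and external edge lists (e.g. from sparse
inverse covariance) can be substituted.

SNP accumulation per resident species is referenced to each subject's
day-0 baseline (day-0 count is 0 by construction). Reported statistics:
mean SNPs per species per group and day; per-subject Euclidean norm of
the species-count vector (displacement from baseline); per-day rates
(count / elapsed days — the denominator behind published per-day rates is
not uniquely defined, so the elapsed-day normalisation is stated rather
than matched to any particular figure); and a two-sided Wilcoxon rank-sum
test of competitor vs non-competitor final-day counts.

## The synthetic-data generator

The generator is the package's test bed and defines the study conditions
under which recovery is demonstrated.

Genome: a 120 kb chromosome plus four plasmids (9/8/7/6 kb), 80
non-overlapping 900 bp genes on alternating strands. This is a scaled-down
genome — large enough that background sites, gene placement and strand
handling are exercised, small enough that the full suite runs in seconds.

Evolution: lineage frequencies evolve per subject by discrete-generation
Wright–Fisher resampling (population 2000, 2 generations/day): expected
frequency ∝ current × (1 + s), renormalised, then multinomially resampled.
The default scenario plants a scripted birth schedule of five nested
branches (E1 day 1, E1-A and E1-B day 3, E1-B-1 day 7, E1-B-2 day 9) with
selection coefficients 0.30–0.50 per generation and birth frequency 0.08,
carrying 22 SNPs in total: five genes receive multiple SNPs **on different
branches** (so the hits are independent and survive the co-occurrence
exclusion), seven genes one SNP each, three SNPs intergenic. A scripted
birth may add several SNPs at once — co-occurring SNP groups are exactly
what defines a branch; in unscripted stochastic mode each birth adds one
SNP (infinite-sites within the horizon, no back-mutation), keeping truth
unambiguous.

Sampling and sequencing: 3 human and 2 mouse subjects; 20 isolates per
subject and day on days 3, 7, 14, 21, 28 (500 isolates); per candidate
site, depth is negative-binomial with mean 60× (shape 20), reads split
between strands at probability 0.5, bases err uniformly at 0.5%, 2% of
cells are missing, and 40 monomorphic background sites exercise site
rejection. Site quality is drawn in the passing range for covered cells —
the generator models a well-behaved caller; quality-driven failure modes
are covered by unit tests, not by the scenario. Mobile elements: one
1.6 kb element carried by every lineage and one 1.2 kb element gained by
the E1-B branch; carriers get coverage 0.90–1.0 at 65–90×, non-carriers
0–0.10 at 0–10×.

Community: 24 species (8 competitors), log-normal abundances with
competitor log-abundance negatively coupled (strength 0.8) to a probiotic
that decays over the 28 days; per-species SNP counts accumulate by
Poisson increments at 2.5/day for competitors, 0.07/day for
non-competitors and 0.065/day in the placebo group, giving day-28 means
near 70 vs 2 — roughly the one-to-two-orders-of-magnitude contrast the
competitor effect is meant to exhibit.

What the generator does **not** emulate — and what passing tests
therefore do not show about real data: read-level artefacts (mapping
bias, indels, strand-biased error), contamination and mixed colonies,
per-gene mutation-rate variation, horizontal transfer beyond whole-element
gain, real compositional covariance structure of gut communities, and
between-host differences in selection (both hosts share the scripted
history; cross-host concordance on simulated data is near 1 by design).

## Reproducibility and numerical choices

Every stochastic stage takes an explicit seed; omission is an error in
the CLI. Generator output is bitwise-reproducible from (config, seed);
deterministic pipeline stages reproduce identical output digests across
runs (recorded in the run manifest). Ties are broken deterministically
throughout (lexicographic alt alleles, size-then-name lineage ordering).
Problem sizes used in the shipped analyses — 500 isolates, 62 candidate
sites, 200 random matrices for the oracle comparison, 100 community
replicates for the contrast — were chosen so each stage demonstrates its
contract at study-like scale while the whole suite stays fast.

## Known limitations

- Indels, recombination and back-mutation are out of scope end to end.
- The co-occurrence stand-in labels association, not conditional
  dependence; compositional coupling can mislabel strongly suppressed
  systems (use external sparse-inverse-covariance edges where it matters).
- dMRCA is a within-time-point polymorphism statistic, not a coalescent
  estimate; it is comparable across time points only under similar
  sampling depth.
- The per-day SNP accumulation rate uses elapsed days as denominator;
  other normalisations (per observation interval, per species-day) give
  different numbers.
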