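# Methods

This note records the models, conventions and design choices behind
`adiporeg`, and what the synthetic benchmarks do and do not demonstrate.

## Expression model and cluster assignment

The expression matrix is assumed normalised and log2-scale (genes ×
samples). The design has nine condition cells — day 3 untreated, days 6
and 11 each under control, CD2314, BIO and CD2314+BIO — with three
replicates each; day-3 samples are carried in the matrix but excluded
from testing, since no treatment arms exist there.

Per gene, per time point t ∈ {d6, d11} and comparator c ∈ {control, BIO,
CD2314+BIO}, CD2314 is tested against c. Two statistics are offered:

* **moderated** (default): the pooled two-group variance s²_g (d_g =
  n₁+n₂−2 df) is shrunk toward a scaled inverse-χ² prior (d₀, s₀²)
  fitted across genes by the moment method on log s²_g (digamma/trigamma
  matching, with d₀ = ∞ when the observed spread of log-variances does
  not exceed its sampling noise); the test uses
  t̃ = Δ/√(s̃²(1/n₁+1/n₂)) with d₀+d_g df. The implementation agrees
  with Bioconductor limma's `lmFit`/`eBayes` on the same two-group
  design to ~1e-9 relative error (checked in the test suite via
  Rscript). With three replicates per arm, the plain Welch test leaves a
  large fraction of genuinely shifted genes right at the BH cutoff in at
  least one of the three required comparisons, and the joint 3-contrast
  sensitivity drops to ~0.55 under the default simulation settings;
  moderation is what makes the all-three-comparisons intersection rule
  usable at this replication level, and it matches how such array
  analyses are actually run.
* **welch** (`test="welch"`): plain unequal-variance t with
  Welch–Satterthwaite df. Degenerate zero-variance genes are not
  dropped: equal means give p = 1, unequal means are treated as
  maximally significant with the observed direction.

BH correction is applied **per (time point, comparator) family across
genes**, at q = 0.05 by default. The alternative — one joint family over
all six contrasts — is not implemented; per-family correction keeps each
contrast's error rate interpretable on its own.

Cluster labels: a gene is CD2314-specific at t iff all three comparisons
at t are significant with a single common direction. Day-6-only up/down →
clusters 1/2, day-11-only up/down → 3/4, both days → 5. Cluster 5 by
default requires the *same* direction at both days
(`cluster5_direction="same"`); a gene significant at both days with
opposite directions keeps its day-6 label (the earlier, commitment-phase
signal). `cluster5_direction="any"` treats any gene modulated at both
days as cluster 5.

qPCR support: relative expression by the ΔCt method,
2^−(Ct_target − mean(Ct_refs)), normalising to the geometric mean of the
reference-gene expression levels (the geometric mean of 2^−Ct values is
2^−mean(Ct)); three reference genes by default.

## Promoter universe

Windows are −2,000/+1,000 bp around the TSS. Coordinates are 0-based
half-open throughout (BED convention) and the TSS base counts as the
first downstream base: a plus-strand TSS at t gives [t−2000, t+1000), a
minus-strand TSS gives [t−999, t+2001) reverse-complemented. Windows are
clipped at chromosome edges; bases without a conservation record get 0
(never conserved — the conservative choice for masking).

Deduplication: promoters overlapping by strictly more than 1,500
genomic bp (strand-ignored — overlap is a physical-sequence property)
conflict. Conflicting pairs are visited in deterministic order and one
member of each is discarded by a seeded uniform draw until no conflict
remains; discards that no longer conflict with anything kept are then
re-admitted, so the retained set is a maximal conflict-free subset.
Deduplication is applied once to the whole universe before any
cluster/background partitioning.

## Motif scanning

PWM collections are parsed from JASPAR multi-record PFM and TRANSFAC
column-table text (negative counts and ragged rows rejected; TRANSFAC
frequency-style matrices, columns summing to ~1, are rescaled to a
nominal count of 100). Log-odds entry (b, j) =
log2(((count(b,j)+π) / (colsum(j)+4π)) / bg(b)) with pseudocount
π = 0.25 per cell by default and uniform background.

Both strands are scanned at every offset (binding sites are
orientation-agnostic); the per-offset score is the max of the two
strands. Under conservation mode θ a window is eligible only if *every*
base has conservation ≥ θ — the strictest reading of "conserved
regions"; the per-promoter score is the best eligible hit, with
`eligible=false` when no window passes. With no conservation
requirement, the score is the arithmetic mean of the three highest
candidate scores (overlapping windows allowed; fewer than three
candidates are averaged as-is). Reported hit positions break ties by
smallest offset, then plus strand; scores are unaffected.

Raw bit-scores are min–max normalised per PWM,
(raw − min_possible)/(max_possible − min_possible), so that optimised
thresholds are comparable across motifs; the enrichment statistic
depends only on ranks, so the absolute score scale (and the pseudocount
choice) does not affect which motifs are reported, only the numeric
threshold quoted.

## Enrichment statistic

For one motif, one conservation mode and one cluster (n promoters of the
N-promoter universe): every distinct observed score is a candidate
threshold; "scoring over" is inclusive (≥), which makes the sweep over
observed values exhaustive. At threshold s with k cluster and K universe
promoters at or above it,

* fold = (k/n) / ((K−k)/(N−n)) — cluster rate against the rate among
  *all other* promoters. K−k = 0 with k > 0 is reported as infinite
  fold and remains eligible if p passes.
* p = upper hypergeometric tail P(X ≥ k), X ~ Hypergeom(N, K, n)
  (scipy's implementation; verified against exhaustive enumeration for
  all N ≤ 12 in the tests).

The candidate maximising fold among those with Bonferroni-corrected
p < α = 0.01 is selected (ties → larger threshold); winners with
fold < 1.8 are discarded. The Bonferroni factor defaults to
(#PWMs) × (#modes, 5) and is a parameter, since reasonable alternatives
(motifs only; × clusters) exist. The threshold sweep itself is *not*
separately corrected — the optimisation is anti-conservative by
construction, and the Bonferroni factor plus the fold filter are what
keep null reports rare (checked empirically in the tests). Promoters
ineligible under a mode count as non-scoring at every threshold. Per
motif, the mode with the lowest raw p (ties → higher fold) is reported.
The background universe is the whole promoter universe minus the tested
cluster; members of other clusters are not excluded.

## PPI modules

Ortholog filtering is deliberately conservative: an edge (a, b) survives
iff |orth(a)| = |orth(b)| = 1, where absent table keys count as empty.
Mapped edges are undirected and deduplicated (two human edges collapsing
onto one mouse pair count once); self-loops survive. A cluster module
keeps exactly the edges with both endpoints in the cluster's gene list;
genes with no retained interaction are excluded from the node set by
default (`keep_isolated=True` retains them). Components come from
networkx and are cross-checked against a flood-fill oracle in the tests.

## Synthetic-data generators

All three simulators are driven by one `numpy.random.default_rng` seed
(recorded in output headers) and are byte-reproducible.

**Expression.** Per-gene baseline ~ N(8, 1.5²) log2 units; i.i.d.
Gaussian replicate noise with sd 0.25, chosen as a typical
within-condition replicate spread for normalised arrays (a calibration
choice, not an empirical claim). Planted genes (200 per cluster by default) shift the CD2314
condition only, by ±2.0 log2 units at their designated day(s) — a
clearly-responding-gene effect size. Optional "confounded" genes apply
the same shift to CD2314 *and* one rotating comparator arm, so they
differ from only two of the three comparators and exercise the
all-three-comparisons rule. The generator does not emulate probe-level
effects, mean–variance trends, or correlated replicates; passing
recovery tests therefore demonstrates the intersection-of-contrasts
logic and the moderated test under well-specified noise, not robustness
to array artefacts.

**Promoter universe.** One promoter region per gene (default 3,000 bp,
one third downstream of the TSS), strands alternating, packed onto
chromosomes with 500 bp spacers so that no two promoters overlap (the
overlap rule is exercised by dedicated tests instead). Unplanted
sequence is i.i.d. uniform over A/C/G/T. Planted motif instances are
*sampled from the PWM's column distributions* — not the consensus — so
score thresholds, not exact matching, are what recovers them; default
rates 40% of foreground vs 5% of background promoters. Conservation:
Beta(1, 3) background drawn per 10-bp block (mean 0.25, so unconserved
sequence fails the masked modes), plus Poisson(4) conserved elements of
30 bp with values uniform on [0.7, 1.0] in *every* promoter, foreground
and background alike, and conservation 0.95 at planted sites. The
conserved elements matter: if elevated conservation occurred only at
planted sites, merely *having* an eligible window would separate
foreground from background and any motif — including column-shuffled
decoys — would appear enriched under masking. With conserved islands
everywhere, eligibility is uninformative and only the planted motif's
sites separate the groups. Mode 1.0 is intentionally unreachable in the
simulation (no run of exactly-1.0 conservation), exercising the
ineligible-promoter path.

**PPI.** Distinct unordered human protein pairs (loops allowed once)
sampled uniformly; a configurable fraction of proteins is "ambiguous",
alternately mapping to two mouse ids or to none, the rest to exactly
one. The truth table marks which edges survive the one-to-one rule,
giving an exact expected mouse edge set. Erdős–Rényi-like topology only;
no degree heterogeneity or literature bias.

## Pipeline and reproducibility

One global seed is fanned out to per-stage sub-seeds via SHA-256 of
`"{seed}:{stage}"` (below 2³¹), so stages are individually reproducible
and decoupled. Every output TSV carries a header comment with package
version, seed and a hash of the resolved parameters (paths excluded);
`run_config.yaml` records the resolved configuration and
`manifest.json` lists every output file with its SHA-256 digest. Two
runs with identical config and seed produce byte-identical trees
(asserted in the tests at full demo size).

Demo problem sizes — 5,000 genes, 2,200 promoters of 3,000 bp, 20 PWMs
(1 planted + 19 column-shuffled decoys), 600 proteins / 1,000 edges —
are chosen so the full pipeline completes in about a minute on one CPU
while keeping the enrichment stage's Bonferroni factor (100) and
promoter universe realistic in structure; recovery benchmarks in the
test suite use 10–20 seeded replicates at these sizes.

## Known limitations

* The moderated test assumes exchangeable per-gene variances around one
  prior; strong mean–variance trends (limma-trend territory) are not
  modelled.
* Scoring is zeroth-order: no higher-order background models, no
  per-hit p-value calibration; absolute bit-scores are
  implementation-defined (pseudocount-dependent), though enrichment
  results are rank-invariant to this.
* The three hits averaged in unmasked mode may overlap one another;
  no spacing constraint is imposed.
* The ortholog rule discards all many-to-many biology by design; it
  trades recall for precision.
* The probe→gene summarisation of real array data (multiple probe sets
  per gene) is out of scope; inputs are assumed to be one row per gene.
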