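# Methods notes

This note documents the models, conventions, and numerical choices
behind `ticklink`, and what the synthetic benchmarks do and do not show.

## Annotation filtering and best-hit classification

Annotation tables carry one row per (feature, sample) alignment hit with
e-value, percent identity, and alignment length. Filtering keeps rows
with e-value ≤ 1e-5, alignment ≥ 15 bp, and identity ≥ 60% (taxonomic
profiling) or ≥ 80% (functional profiling); only Bacteria-domain rows
are retained downstream, but `profile_io.domain_percentages` reports the
per-sample domain split *before* removal so the Bacteria share can be
tabulated alongside QC summaries. All comparisons are inclusive on the
"keep" side — the cut-offs are stated without a direction of equality in
common annotation-server usage, and an inclusive convention makes the
boundary testable (14 bp removed, 15 bp kept).

Best-hit classification keeps one row per (feature, sample): smallest
e-value, ties broken by largest identity, then longest alignment, then
lexicographically smallest subject id. The final tie-break on an opaque
subject id makes the reduction fully deterministic, which matters for
byte-identical reruns.

Taxonomic and functional annotations of a read may coexist on one row;
the linkage join (below) requires them on the *same* row, i.e. the same
feature. Joining across rows of the same read would inflate linkage
counts and is deliberately not done.

## Read QC

"Dynamic trimming" is implemented as: keep each read's longest
contiguous window containing at most `max_below` (default 5) bases with
quality below `phred_floor` (default 15), leftmost window on ties; drop
reads whose window is shorter than `min_len` (default 50 bp). The
windowed formulation is transparent and is validated against a
brute-force all-windows oracle in the tests. Reads are trimmed first and
length-filtered second, and both tallies are reported separately.
Replicate removal keeps, among reads sharing an identical
`dup_prefix_len` (default 50 bp) prefix, only the longest
(first-encountered on ties). `min_len` and `dup_prefix_len` are not
prescribed by the upstream convention and are exposed as parameters.
Host-genome screening requires an external reference index and is a
logged pass-through hook.

GC% per read excludes ambiguous bases from numerator and denominator;
summary standard deviations are sample sd (n−1), reported as 0 for a
single read by convention.

## Count matrices and normalization

Aggregation at any rank/level pools rows lacking the label into an
`unclassified` row, so matrix totals always equal table totals. Size
factors follow the median-of-ratios estimator: reference = per-feature
geometric mean over samples, computed on features positive in every
sample; factor = per-sample median count/reference ratio, rescaled to
geometric mean 1 so factors are comparable across runs. Only the
normalization step of the negative-binomial count-model approach is
used — no dispersion estimation or variance-stabilizing transform.

**A deliberate split:** exact tests (Fisher) always consume raw integer
counts — exactness requires integers — while normalized counts and
relative abundances feed ordination/heatmap outputs only. Ordination
defaults to relative abundances.

## Community statistics

* Rarefaction uses the analytic hypergeometric expectation
  Σᵢ[1 − C(N−Nᵢ, d)/C(N, d)] with log-gamma evaluation; tests compare it
  to Monte-Carlo subsampling within 3 standard errors.
* α-diversity: the index behind reported "α-diversity" comparisons is
  often unspecified in practice, so both observed richness and Shannon
  (natural log) are provided, Shannon being the default report.
* ANOSIM: R = (mean between-group rank − mean within-group rank)/(M/2)
  with M = n(n−1)/2 and mid-ranks for ties. The permutation p-value uses
  the (exceedances+1)/(n\_perm+1) convention, avoiding p = 0; when the
  number of distinct label assignments is ≤ n\_perm the null
  distribution is enumerated exhaustively instead (the identity
  assignment then plays the role of the +1). R is rank-based and hence
  invariant to monotone transforms of the distances (property-tested).
* PCA: features centered across samples, no unit-variance scaling —
  the usual convention for relative-abundance profile ordination;
  components from the SVD of the centered matrix. Sign convention:
  within each component the largest-magnitude loading is positive.
* Venn partitions are limited to 3 sets; percentages are of the union,
  reported to 1 decimal.

## Differential tests

* Fisher two-sided p-values use the minimum-likelihood ("minlike")
  convention — the sum of hypergeometric probabilities ≤ the observed
  table's probability — matching common profile-comparison software. A
  relative tolerance of 1e-12 in the ≤ comparison absorbs floating-point
  ties; the implementation (vectorized log-gamma pmf over the support)
  is tested against an exact rational-arithmetic enumeration oracle over
  all small-margin tables (max |Δp| ~ 1e-14).
* BH adjustment is the step-up q\_(i) = min\_{j≥i} p\_(j)·m/j, capped at
  1, applied within one comparison and one hierarchy level at a time
  (e.g. all genera for AVf vs AVm) — the conservative scoping when the
  correction's scope is not stated.
* CIs on proportion differences use the Newcombe–Wilson hybrid score
  method, the standard companion to exact tests in this setting.
* One-way ANOVA reports η² = SSB/SST with an effect-size floor
  (default η² > 0.01) for category-level rankings; MSW = 0 with SSB > 0
  yields F = +inf, p = 0. Tukey–Kramer post-hoc p-values come from the
  studentized-range distribution (scipy's numerical integration covers
  all parameter ranges used); the tests include a ≥10⁶-draw Monte-Carlo
  oracle of the critical value and the k = 2 equivalence q = t·√2.

## Taxon–function linkage

Edges are (enzyme, genus, group, hits) with hits summed over qualifying
best-hit records; records whose enzyme is differential but whose genus
is unresolved are tallied separately, never as edges, so hit totals are
conserved through the join. Group merging (e.g. pooling the two *Ixodes*
species per sex) sums hits per (enzyme, genus, merged group) before
analysis.

The redundancy spectrum counts distinct genera per enzyme pooled over
all groups (one count per enzyme, not per sex). Bins {1, 2–4, 5–10,
≥11} express "single genus", "a few", "five to ten", and "widespread";
bin edges are configurable, and the per-enzyme counts are always
reported so any binning can be recomputed. Genus contributions report
hit shares (summing to 100%), per-group splits for mirror plots, top-k
cumulative share, and the fraction of genera carrying exactly one
enzyme. The dual-role partition is plain set algebra on (differentially
abundant genera) × (provider genera).

## Synthetic data: what it emulates, and what it does not

The generator plants every quantity the pipeline later estimates:

* **Community**: per-species genus abundances are normalized lognormal
  (σ = 1.5) weights over 40 genera (defaults), nested under a synthetic
  lineage spanning ≥ 2 phyla so aggregation at every rank is exercised.
  Species labels default to AV/IO/IP with one pooled sample per
  species × sex (replication n ≥ 1 supported, default 1, matching the
  pooled-sample design).
* **Sex effects**: 4 genera (default) are multiplied by fold\_change = 8
  in one sex and renormalized, directions alternating. Affected genera
  are drawn from the more abundant half so the planted effect is
  observable at the default 20,000 reads/sample. Note that after
  renormalization the *proportion ratio* between sexes is
  φ/(1+(φ−1)p) < φ; the exact invariant is the odds ratio, which equals
  the fold change — recovery tests therefore check the empirical odds
  ratio. The renormalization also depresses all unaffected genera
  (compositionality), so under a planted effect more genera than the
  planted ones are genuinely differential; only the null configuration
  (fold\_change = 1) is signal-free.
* **Repertoire**: the genus×enzyme incidence realizes the configured
  redundancy spectrum exactly (largest-remainder allocation over the
  bins; infeasible configurations, e.g. a ≥11-genus bin with fewer than
  11 genera, are rejected). Default bin mass {1: 0.12, 2–4: 0.55,
  5–10: 0.27, ≥11: 0.06}: the single-genus and five-to-ten fractions are
  the reported community values this pipeline targets; the split of the
  remainder keeps very widespread enzymes rare (the most widespread
  enzyme observed in these communities reaches ~10 genera). Enzyme
  identifiers use EC dot-notation so linkage outputs look like real
  ones. Genus selection prefers still-empty genera, so every genus
  carries ≥ 1 enzyme whenever total slots suffice.
* **Annotation noise**: records fail with probability `p_fail`
  (default 0.1), drawing e-value/identity/alignment-length from a fail
  population violating all three thresholds, so the filtered fraction
  converges to `p_fail`; `p_nonbacterial` (default 0.05) plants
  eukaryote-domain contamination removed by the domain filter.
* **FASTQ**: planted low-quality reads have every base below the Phred
  floor (hence removed under any window of the minimum length); planted
  replicates copy an earlier read's prefix at equal length (hence
  removed by keep-first tie-breaking); good reads have all-passing
  qualities and pairwise-distinct prefixes. Removal counts are therefore
  exact, not approximate.

**What passing tests do not show:** the generator produces no sequence-
level realism (no alignment simulation, no real genomes — the quality
fields are distributional stand-ins), no overdispersion beyond
multinomial sampling, no correlation between taxonomic and functional
annotation quality, and no cross-sample batch structure. Benchmarks on
it demonstrate the pipeline's correctness and calibration under its own
model, not performance on real annotation servers' output.

## Benchmark scales

The recovery benchmarks (ticklink.validation) use one species at 20,000
reads/sample: 200 null replicates × 100 genera for error control
(empirical FDR = mean per-replicate false-discovery proportion; all
discoveries are false under the null, so FDP is the any-discovery
indicator), 50 seeds × 4 planted 8-fold effects for recall, and a
uniform-abundance noiseless run for exact spectrum recovery (uniform
abundance makes coverage of every genus–enzyme pair certain at this
depth). These sizes give stable estimates in a couple of minutes on one
CPU.

## Known limitations

* Fisher tests on very deep samples are sensitive to tiny proportion
  differences; the pipeline reports effect sizes (proportion difference
  with CI) alongside q-values for exactly this reason.
* The ANOSIM exhaustive-enumeration switch enumerates multiset
  permutations in Python; it is intended for the small sample counts
  (n ≤ ~10) where exhaustive inference matters.
* The linkage join requires genus and enzyme on the same feature row; a
  table whose taxonomic and functional annotations live on separate
  rows per read will produce an empty join rather than a wrong one.
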