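# Methods

## Scope and model

`lamnet` re-implements, as a tested library, the network-based workflow for
nominating transcriptional regulators of the lipid-associated macrophage
(LAM) response: metacell aggregation of single-cell counts, mutual-information
(MI) network inference with data-processing-inequality (DPI) pruning and
bootstrap consolidation, cross-network/cross-species regulon-enrichment
nomination, proxy-cistrome promoter analysis, and stratified rank-rank
hypergeometric overlap (RRHO) of expression signatures. External heritability
regression, peak calling, de novo motif discovery and differential-expression
fitting are out of scope; DE tables, peaks, motifs and genesets are consumed
as inputs.

## Synthetic cohorts

The generator produces the study conditions under which the pipeline is
validated. Each TF carries a per-cell latent activity: a log-normal draw,
standardised across cells; cells in the activated (LAM-like) state — a
`lam_fraction` of the population — receive a fixed additive activity shift
(`lam_activity_shift`, default 2 SD) for the designated driver TFs. A gene's
expected count is `baseline_mean * max(1 + beta * activity, 0.05)`, where a
TF reads out its own activity and each target reads out its regulator's.
Counts are negative binomial (variance `m + m^2 / dispersion`) with optional
independent Bernoulli dropout. Regulons are disjoint target blocks (an
overlap parameter can introduce shared targets), which makes
regulon-recovery scoring unambiguous.

Default condition ("strong signal"): 800 cells, 300 genes, 12 TFs of regulon
size 15, 3 driver TFs, `beta = 5`, `baseline_mean = 5`, `dispersion = 5`,
`dropout = 0`, `lam_fraction = 0.3`. These values were fixed once by
measuring planted-pair MI at the metacell sample size (n = 80): the median
planted-edge MI (~0.68 nats) then clearly exceeds the p = 1e-8 threshold
(~0.37-0.43 nats), which is what "strong" should mean. The moderate
condition (`beta = 2.5`, `baseline_mean = 3`, `dispersion = 3`,
`dropout = 0.05`) puts planted edges *at* the threshold, so edge recovery is
partial and nomination must rely on enrichment of the recovered partial
regulons. Two pseudo-species share one planted truth under species naming
conventions (upper-case vs title-case symbols) with an explicit ortholog
table, so the conservation logic is exercised literally.

What the generator does **not** emulate: UMI structure, batch effects,
doublets, realistic chromatin accessibility, or the empirical expression
distributions of published datasets. Passing tests therefore demonstrate
correctness of the machinery under a plausible noise model, not performance
on any real cohort.

## Metacells

CPM normalisation scales each cell to 1e6 counts; distance is 1 − Pearson r
on the normalised values (no log transform — normalisation precedes
correlation in the reference workflow). Seed cells are chosen by
farthest-point sampling (first seed = minimal total distance; ties to the
lowest index), and each seed absorbs its `num_neighbors` nearest
still-unassigned cells; raw counts are summed. The reference metacell
pipeline does not specify its partitioning, so this deterministic, RNG-free
rule is this package's own design; defaults `sub_size = ceil(n/10)`,
`num_neighbors = 9` give ~10-cell metacells. Leftover cells stay unassigned;
aggregate mass equals the mass of assigned cells exactly. The gene filter
keeps genes with non-zero counts in at least 75 % of metacells (boundary
inclusive) and is idempotent.

## Mutual information

The estimator is adaptive partitioning on rank-transformed profiles:
recursive quadrant splitting of the rank-rank plane, stopping when a cell's
four quadrants look uniform (chi-square > 7.815, i.e. 5 % on 3 df) or the
cell holds fewer than 8 points, with each leaf contributing
`(n_c/n) ln(n_c n / (w_x w_y))`. Two numerical choices matter:

- **Random tie-breaking of ranks.** Discrete or zero-inflated profiles are
  assigned ordinal ranks with ties broken uniformly at random (seeded), which
  makes tied blocks uniform in rank space — the regime the chi-square stop
  assumes. A constant vector yields MI = 0 with a warning.
- **Unconditional first split.** With rank inputs the root cell's quadrant
  counts are hypergeometric-constrained (the marginals are exact), so the
  nominal 3-df chi-square almost never fires and the null MI would collapse
  to an atom at exactly 0. The root is therefore always split once; deeper
  cells use the chi-square stop. The cost is an O(1/n) positive bias
  (≈ 0.006 nats at n = 80, < 1e-3 at n = 2000), negligible against
  thresholds of ~0.1-0.4 nats.

Accuracy, verified in tests: within 10 % of ln 8 for an 8-level discrete
identity at n = 4096; within 15 % of −½ ln(1 − r²) for bivariate Gaussians
(r = 0.3, 0.5, 0.8) at n = 5000; ≤ 0.02 nats for independent pairs at
n = 2000.

## Threshold calibration

The MI significance threshold at p = 1e-8 cannot be simulated directly. The
null is sampled with 1e5 permuted rank pairs at the observed sample size;
for p-values resolved by that sample the threshold is the empirical
quantile, and beyond it the tail is modelled as exponential above a high
anchor quantile u (the 500th-largest value) with rate 1/λ, λ the mean excess:
`t(p) = u + λ ln(p0 / p)`. The two regimes join continuously and the
threshold is monotone non-increasing in p. The calibration is verified at
testable p-values (empirical exceedance at p = 0.01 falls in
[0.005, 0.02]). The null sample is keyed by (sample size, seed) and cached;
one calibration (seed 1, mirroring the reference invocation) is shared by
all bootstraps and datasets of a run — recalibrating per dataset would let
threshold sampling noise interact badly with the consolidation null (see
below).

## Network inference, DPI, consolidation

Edges are TF-gene pairs with MI at or above the threshold; TF-TF pairs are
kept once (lexicographic). DPI enumerates all triangles (regardless of which
endpoints are TFs) and removes the weakest edge of a triangle when its MI is
below `(1 − tolerance) ×` the middle MI; decisions are simultaneous on the
input edge set, so the operation is idempotent at tolerance 0 (the default,
matching the reference tool's defaults).

Consolidation resamples metacells with replacement `n_bootstraps` times
(default 200; scaled-down runs use 25), re-infers and DPI-prunes each
replicate, and tests each edge's support count against
Poisson(mean support per distinct edge), upper tail, BH-corrected over
distinct edges; edges with FDR < 0.05 are kept (FDR = 1 keeps everything).
Consolidated edge MI is the mean over supporting bootstraps; a min-max
normalised MI per network is reported for heatmap use (the normalisation is
not specified upstream; min-max is this package's choice and is
configurable by consumers of the edge table). Pooling the bootstrap
collections of several datasets through the same test yields the
meta-analysed network; with one dataset this reduces exactly to single-
dataset consolidation.

A caveat this implementation makes explicit: the Poisson consolidation null
takes its mean from the observed support distribution, so it needs a
population of low-support (noise) edges to be calibrated. In very clean,
small networks (few TFs, strong signal, high threshold draw) nearly all
edges can reach maximal support, the null mean approaches the maximum, and
nothing is significant. Sharing one threshold calibration across a cohort
keeps the regimes comparable across datasets.

## Enrichment and nomination

Regulons are per-TF target slices (TF-TF edges count from either side). The
hypergeometric test uses the network's own gene universe — the genes that
survived the metacell filter — as the population (the universe is not
specified upstream; it is configurable). BH correction is applied per
network across all TF × geneset tests in that network. A TF qualifies in a
network iff all three genesets clear FDR < 0.2; nomination requires
qualifying in ≥ `min_networks_per_species` networks in *both* species
("half" = ceil(n/2)), conservation through the ortholog map (case-insensitive
symbol fallback), and reference expression TPM ≥ 1 (a TF missing from the
reference is treated as not expressed and flagged). TFs clearing the bar in
one species only are reported as species-specific. The nominated set is
monotone in the FDR threshold and anti-monotone in the network count, which
is property-tested.

## Proxy-cistrome

Coordinates are 0-based half-open everywhere (BED native). Promoters are
symmetric TSS ± 2000 bp windows clamped to the sequence. PWM scanning scores
log2 odds against a uniform background with a pseudocount of 1e-3 per cell,
on both strands at every offset, skipping N-containing windows; the default
threshold is 80 % of the maximal attainable score, so a strict consensus PWM
behaves as a string search (used by the oracles). A peak is a proxy-binding
site if it contains ≥ 1 hit. Promoter-bound fractions use a ≥ 1 bp overlap
rule (whether full containment was intended upstream is unknown; overlap is
assumed and configurable by filtering the inputs). Motif-position histograms
accumulate motif-start offsets relative to the region centre into
20-bp bins over a 2000-bp window; bins sum to the number of in-window hits.
Stratified annotations export as sorted BED6 and round-trip through the
module's reader.

## RRHO

Signatures are scored −log10(P) · sign(log2FC); p = 0 maps to the smallest
positive double (warned). Lists are sorted descending with lexicographic
tie-breaks. The grid covers thresholds i·step, default step ceil(sqrt(N))
for N shared genes (the upstream default is unstated). Each pixel's quadrant
follows from which side of each list's positive-score boundary its
thresholds fall: head-head (uu), tail-tail (dd), or head-tail (ud/du)
overlaps are tested with the hypergeometric upper tail, and all pixels of a
grid are BH-corrected together. Quadrant extraction returns the overlap at
the most significant pixel of uu or dd (ties: smallest combined, then A,
threshold). Spearman correlation uses a Fisher-z 95 % CI with
SE = 1/sqrt(n − 3). Note that the monotone-refinement property (finer grids
never lose significance) holds for raw pixel p-values; BH-adjusted values
can move either way as the pixel family grows.

## Problem sizes and determinism

Validation runs use 4 + 4 datasets × 800 cells × 300 genes with 25
bootstraps per network, 1e5 permutations per MI calibration, 1e5-draw
Monte-Carlo checks for the hypergeometric tests, 500-gene signatures at step
25 for RRHO, and 50 random toy genomes for the interval/motif oracles —
sizes at which every closed-form or brute-force oracle is exact or tight.
All randomness flows from explicit integer seeds through
`numpy.random.SeedSequence` derivation (child seeds < 2^31), and every
stage is bit-reproducible under a fixed seed.

## Known limitations

- The adaptive-partitioning MI has a small positive bias at small n and
  saturates below the true MI for very strong dependence at n ≲ 100; the
  pipeline operates on thresholds and ranks, so only relative ordering
  matters.
- The Poisson consolidation requires a noise-edge floor (see above); with a
  handful of TFs and extreme signal it can become conservative.
- The exponential tail extrapolation to p = 1e-8 is verified only at
  p-values large enough to test empirically.
- The mean-excess λ makes the extrapolated threshold mildly sensitive to the
  calibration seed (±0.03 nats at n = 80); a fixed calibration seed makes
  runs comparable.
- Cross-species matching assumes the provided ortholog table (or
  case-insensitive symbol equality); no ortholog inference is attempted.
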