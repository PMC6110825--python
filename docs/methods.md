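# Methods

## Site-level model

Each CpG dinucleotide carries a cytosine on both strands, offset by
one base; the two strand records are merged by summing counts at the
plus-strand coordinate before any inference, so each CpG contributes
one (m, n) observation per sample. Merging is justified empirically:
the hemimethylation diagnostic (`hemimethylation_by_coverage`) shows
strand discordance falling with coverage, the signature of binomial
sampling noise rather than genuine strand asymmetry.

The null for a single site is that all m unconverted reads are
conversion failures: m ~ Binomial(n, ε), with ε the pooled
lambda-spike-in nonconversion rate. The test is one-sided upper-tail
(methylation can only inflate m above ε, never deflate it) and exact.
Conventions at the boundary: n = 0 gives p = 1 (no data is no
evidence); ε = 0 with m > 0 gives p = 0 (an unconverted read is
impossible under a perfect-conversion null). BH correction is applied
within each sample across all of its sites; calling across samples
jointly would couple the samples' error control for no clear benefit
in a per-sample status call. ε has no silent default: absent a
spike-in, the caller requires an explicit value.

Gene-body methylation is the coverage-weighted ratio Σm/Σn over all
merged CpGs in the gene span, introns included. A gene with zero
covered CpGs has an *undefined* level (NaN), never 0 — the distinction
matters for both the methylated-gene universe and the
methylation–expression correlation. A gene is "methylated" when its
level strictly exceeds 5% in at least one sample.

## Window-level differential test

Sites entering the differential analysis must be methylation-
significant (q < 0.05) in at least one sample, covered in every
sample, and covered at most 170× in every sample (PCR-artifact
guard). The filters are applied in that order; the site table records
each step so the order can be audited. Retained CpGs are pooled into
fixed, non-overlapping 200 bp tiles (window of p is
⌊p/200⌋·200 … +200, half-open) and tiles with fewer than 2 CpGs are
dropped.

The default per-window test is the likelihood-ratio test of a
binomial logistic regression of per-sample (m, n) on group
membership. With a group-only design matrix the MLE pools coverage
within each group, so the statistic reduces in closed form to the
2×2 G-statistic on group-pooled counts with a χ²(1) reference; the
implementation uses that closed form, vectorized over windows, and is
cross-checked in the test suite against an iteratively fitted
statsmodels GLM. No overdispersion correction is applied by default.
A two-sided Fisher exact test on the pooled table is available as an
alternative backend and as the small-sample oracle. Windows where an
entire group is uncovered are untested (NA) and excluded from the BH
family rather than assigned p = 1.

A window is a DMR iff q < 0.01 (BH over tested windows) and
|diff| ≥ 5 percentage points, where diff = 100·(pooled care level −
pooled no-care level); the 5-point boundary is inclusive and
configurable. Positive diff means hypermethylated under maternal
care. Adjacent significant windows are deliberately not stitched:
windows are analysed independently.

## QAM null

For a balanced g-vs-g design the relabelings are the unordered
balanced partitions of the samples, excluding the original:
C(2g, g)/2 − 1 of them (nine for 3 vs 3). Complement collapsing is
essential — counting label-swapped assignments separately would
double the count and change nothing statistically, since the test is
symmetric in the two labels. Each relabeling re-runs the complete
window analysis (its own BH family, same thresholds), and window r
receives null probability k_r/K. The genome-wide null count is then
the sum of independent Bernoulli(k_r/K) draws — region independence
is an explicit modelling assumption, ignoring spatial correlation of
windows; 50,000 Monte-Carlo draws are the default, and the exact
Poisson-binomial pmf (O(R²) dynamic-programming convolution, skipping
zero-probability regions) serves as an oracle and as an exact
alternative for ≤ ~10⁵ regions.

Summaries: the empirical p uses the add-one estimator
(1 + #{draws ≥ observed})/(1 + n_iter), ties counting as
exceedances, so it can never be zero; the per-DMR chance is
100 · null mean / observed count — the expected share of the observed
tally that relabeling noise alone would produce. Both are undefined
(None) when there is nothing to compare (no draws, zero observed).

## Synthetic-data generator

The generator produces what the pipeline consumes — Bismark-style
cytosine reports, GFF3 gene models, gene lists, BED splice events —
with full ground truth. Design of the defaults:

* **Genome/annotation**: genes of 5 × 200 bp exons with 100 bp
  introns placed without overlap at jittered regular spacing; CpGs
  placed as independent Bernoulli(0.02) per bp, matching the roughly
  uniform CpG landscape of an AT-rich insect genome.
* **Methylation truth**: a configurable fraction of genes is
  methylated; each methylated gene draws a beta-distributed gene-body
  level around 0.7 (concentration 30), and exonic CpGs decay
  geometrically with exon rank (factor 0.7) to emulate the 5′-exon
  bias; intronic CpGs are attenuated (factor 0.3); unmethylated genes
  draw a small positive level (mean 0.005) so gene-level truth is
  continuous — real measured levels are never exactly tied at zero
  either, and the rank-based expression coupling needs tie-free
  truth.
* **Counts**: per-strand coverage ~ NB(mean = coverage_mean/2,
  dispersion α = 0.2; variance μ + αμ²), so the strand-merged depth
  matches the configured ~30×, inside the 21–37× range the design
  targets; methylated count ~ Binomial(cov, π + (1−π)ε) with
  ε = 0.005. The lambda spike-in is 5,000 sites at π = 0 on a
  pseudo-chromosome named `lambda`.
* **Planted DMRs**: 200 bp tiles wholly inside methylated-gene spans
  with ≥ 2 CpGs; within a planted tile the groups differ by exactly
  `dmr_delta` at every CpG (base level clamped to keep π + δ ≤ 1),
  hypermethylated in "care" for 84% of tiles by default, mirroring
  the direction bias such studies report.
* **Biological variance**: off by default — samples within a group
  share π exactly. An optional beta jitter
  (π_i ~ Beta(cπ, c(1−π))) is exposed for sensitivity analyses; the
  default reflects that within-group variance of these methylomes is
  not separately characterized, and tests calibrated without jitter
  say nothing about robustness to it.
* **Gene sets**: three sets (DE/AS/selection) with marginal
  membership 0.1; AS and selection membership is drawn conditionally
  on DE membership with conditional rates solved (Brent root-find) so
  each pairwise table has the configured odds ratio in expectation.
* **Expression**: Gaussian copula on the ranks of true gene-body
  methylation with latent Pearson r = 2·sin(πρ/6), so the realized
  Spearman correlation approximates the target ρ (default 0.24);
  ρ = ±1 short-circuits to an exact monotone copy.

What the generator does **not** emulate: read-level artifacts
(mapping bias, duplicates beyond the coverage cap), spatial
autocorrelation of methylation beyond gene/exon structure,
non-CpG contexts, unbalanced designs, and within-group biological
variance by default. Passing parameter-recovery tests therefore
demonstrates correctness of the inference machinery under the stated
sampling model, not robustness to every artifact of real libraries.

## Numerical choices and edge cases

* Coordinates are 0-based half-open everywhere internally; 1-based
  only in the cytosine-report and GFF3 dialects at the file boundary.
  Interval overlap anywhere in the package means a non-empty
  half-open intersection (adjacent intervals do not overlap).
* The exact binomial tail is computed by `scipy.stats.binom.sf` and
  is verified against brute-force pmf summation to 10⁻¹² for all
  n ≤ 50.
* Chi-square enrichment uses no continuity correction by default
  (configurable); a degenerate margin (a set empty or equal to the
  universe) returns statistic 0, p = 1 by convention. Odds ratios add
  a Haldane half-count only when a cell is zero.
* Spearman correlation uses mid-rank ties and the large-sample
  p-value; fewer than 3 pairs or a constant vector is an error, not a
  silent NaN.
* All generator randomness derives from `(seed, stream)` seed
  sequences, one stream per stage, so stages are independently
  reproducible and identical configs give byte-identical outputs.

## Problem sizes

The test suite and acceptance script run compact studies — 80 genes
on a 400 kb chromosome (~8,000 CpGs, ~270 tested windows), 60 planted
DMRs, 3 vs 3 samples at 30×, 50,000 null draws — chosen so that each
planted window carries group-pooled coverage (~2–4 CpGs × 3 samples ×
30×) comparable to a genome-scale study's per-window depth, which is
what governs the test's operating characteristics; the window count
only scales the BH family. Calibration claims (FDR, type-I rates,
null coverage) are averaged over 10–20 independent seeds.

## Known limitations

* The region-independent null understates null-count variance when
  neighbouring windows are correlated (shared genes, linked
  coverage); the paper-style design shares this assumption.
* The closed-form G-test, like any binomial LRT without overdispersion,
  is anti-conservative if replicates within a group are more variable
  than binomial; the optional π jitter in the generator exists to
  probe exactly this.
* Unbalanced or >2-group designs are out of scope; the relabeling
  enumerator refuses them explicitly.
* DMRs are single windows; no stitching or boundary refinement.
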