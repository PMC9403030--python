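# Methods

## The folding-specificity statistic

Proximity-ligation assays (RPL, PARIS, SPLASH) produce chimeric reads whose
two mapped anchors evidence an intramolecular RNA duplex. For one gene, let
`M_ij` be the read weight supporting the unordered anchor pair (i, j) and
`c_i` the pooled anchor coverage of base i (both read sides counted, so
`sum(c) = 2 x total read weight`). The normalized score is
`Mnorm_ij = M_ij / (c_i c_j)`, and the binned score `M*_ij` sums `Mnorm` over
the `(2h+1) x (2h+1)` window centred on (i, j) with half-width h = 10 nt,
pooling reads that support the same duplex with minor anchor offsets.

With weights `w_k` (`M*` by default, raw `M` optionally) over the `n`
observed pairs and `p_k = w_k / sum(w)`:

    S_obs = -sum_k p_k ln p_k,   S_max = ln n,   S = S_max - S_obs  (nats)

`S` is zero when every observed pair is equally supported (maximally diverse
folding) and grows as support concentrates; it equals the Theil T inequality
index of the weight vector, and subtracting `S_obs` from `S_max` controls for
sequencing depth and the number of supported sites. The same formula applies
to a region (pairs with both anchors inside the region) and to a single
nucleotide (pairs involving that site). Per-site values are missing — never
zero — where a site occurs in no pair: zero means "observed and perfectly
diverse", which is a different statement.

Numerical conventions: natural logarithms throughout; `M*` is evaluated on
the observed-pair support only (memory linear in reads, and `n` counts pairs
"revealed by at least one chimeric read"); each unordered pair is counted
once in a window, in whichever orientation it falls; windows truncate at the
gene ends (transcripts are linear); coordinates are 0-based half-open
internally with 1-based text I/O by default.

Two modes are exposed because binning changes limiting behaviour: with
`mode="raw"` nearby offsets do not reinforce, so a gene whose reads all
support distinct pairs has S = 0 exactly; `mode="binned"` is the default
used everywhere else.

## Circularization subsetting

The circularization score of a read is `|pos3 - pos5| / length`, in [0, 1).
`specificity_by_circularization` keeps the `ceil(fraction x reads)` most
distal or most proximal reads per gene (ties broken by (score, pos5, pos3)
so the subset is deterministic), rebuilds the map and recomputes S. This
tests whether an S-covariate association is driven by long-range
(end-to-end) folding alone.

## Association machinery

* **Binned trends** — equal-size rank bins of x (remainder to the leading
  bins), mean +/- SE of y per bin, with Spearman (default) and Pearson on the
  unbinned pairs. Undefined correlations (constant input) are reported as 0
  with an explicit flag.
* **Bootstrap SE** — stat over B resamples of genes with replacement
  (default B = 1000), seeded.
* **Down-sampling test** — every gene is reduced to k = 5 reads without
  replacement, S recomputed, and the observed statistic is the mean Spearman
  correlation with a per-gene covariate over `reps` replicates. The null
  statistic has the same form: for each covariate permutation, the mean over
  the same replicates of the permuted correlation (computed exactly via
  averaged standardized ranks). The p-value is the smoothed one-sided
  fraction `(1 + #{null >= observed}) / (reps + 1)`. Comparing a
  mean-of-replicates against single-replicate nulls would concentrate p near
  0.5; the mean-vs-mean form is calibrated (verified uniform under the
  null in the test suite).
* **Odds ratios** — per gene, sites are cross-classified by "S strictly
  above the gene mean" against "covariate strictly above its mean" (OR1,
  conservation) or "strictly below" (OR2, melting temperature, so OR2 > 1
  marks low-Tm/high-S co-occurrence); ties at the mean go to the low class.
  Each cell gets a +1 pseudocount, then OR = ad/bc. Tables combine across
  genes by the Mantel-Haenszel estimator
  `sum(a_i d_i / N_i) / sum(b_i c_i / N_i)` with the
  Cochran-Mantel-Haenszel chi-square (0.5 continuity correction by default,
  matching R's `mantelhaen.test`); the implementation is checked against
  statsmodels' `StratifiedTable` in the tests. Expression stratification
  uses equal-size rank tertiles, remainder to the lower strata.
* **Shuffle nulls** — per gene, the covariate is permuted over defined sites
  and the statistic (within-gene Spearman or OR1) recomputed; observed
  per-gene values are compared to the pooled null by a two-sample KS test.
* **Exact tests** — two-sided binomial sign test (minimum-likelihood method;
  the sidedness is a package choice, checked against full enumeration for
  n <= 12) and the two-sided Mann-Whitney U (scipy; checked against
  permutation enumeration at small n).

## Ribosome-stalling meta-gene analysis

Normalized ribosome density is Ribo-Seq coverage divided by the transcript
mean (whole-transcript mean, per the definition of the input; output mean is
exactly 1). The focal site of a gene is the 5'-most nucleotide of maximal
per-site S at position >= 200 nt (excluding the 5' elongation ramp), and the
gene must show specific folding at all (max S > 0): a zero-S "focal" site
would be indistinguishable from the control class and, in simulation,
contaminates the control profiles with the injected stall. Controls are a
uniform random S = 0 site with nonzero proximity-ligation coverage, or
additionally matched on the focal site's exact coverage (nearest coverage
with a log entry when no exact match exists — the matching rule has no
published fallback). Profiles average the per-offset signal across genes
("upstream" = smaller transcript coordinate), window [-100, +50] nt by
default; per-offset SE is across genes (not bootstrap), and offsets with
fewer than 3 genes are masked in plots but kept in tables. The
start-anchored variant (`positional_profile`) aligns genes on the first CDS
nucleotide to profile the first ~150 nt, where translation-regulatory
hairpins (e.g. Dhh1-resolved structures near nucleotide 70) appear; the
activated/repressed/unaffected gene sets are caller-supplied.

The CDS-vs-UTR contrast averages defined per-site S per region (a pair
belongs to a region only if both anchors are inside), excludes genes lacking
defined sites in either region, drops exact ties, and feeds the cohort
counts to the binomial sign test.

## Elongation-speed fitness model

A mutation that increases ribosome density on p codons by q-fold changes
the gene's average elongation speed from v to `v' = Lv / (L - p + pq)`
(L in codons), so `dv = v(p - pq)/(L - p + pq) ~ (p - pq) v / L` for p << L.
The selection coefficient combines three components, all constants living in
`src/foldspec/data/fitness_params.yaml` (configuration, not code):

1. proteome-time cost: with a fixed translating-ribosome pool, a relative
   slowdown `dv/v` on a gene delays proteome synthesis in proportion to the
   gene's share of translation, `expression x L / proteome_size_aa`;
2. speed-accuracy trade-off: per-codon mistranslation changes linearly with
   relative speed (slope x baseline error rate);
3. misfolding cost: a fixed fraction of mistranslated molecules misfold,
   each costing `misfolding_cost` fitness units per cell.

Both benefit and cost scale with molecules produced, so s is linear in
expression: with the shipped configuration, one codon stalled 1.2-fold on a
400-codon gene (dv = -0.01 codons/s) gives s ~ 3e-4 at 5000 molecules/cell
(selectable in yeast, Ne = 1e7) and s ~ 6e-8 at 1 molecule/cell
(effectively neutral, |s| < 1/Ne; the boundary |s| = 1/Ne is classified
neutral). The shipped constants are round plausible yeast values chosen to
reproduce the published model's reported selection coefficients at order of
magnitude; the model's exact internal parameters are not re-derived here.
Species comparisons (e.g. human, Ne ~ 1e3) go through the Ne parameter only.

## Synthetic-data generator

The generator emulates the statistical structure of a proximity-ligation
cohort with known ground truth:

* Gene lengths uniform in [500, 1500] nt, 10% 5' UTR, 15% 3' UTR, K = 3
  latent duplexes per gene whose 2K arm centres are >= 30 nt apart and
  >= jitter from the ends (an error if they cannot fit).
* Each read is promiscuous with probability 0.5 (two random nucleotides
  >= 10 nt apart) — the scattered single-read pairs ubiquitous in real
  chimeric data — otherwise it picks a duplex from a
  Dirichlet(alpha_g/K)-multinomial allocation and lands within +/-5 nt
  (uniform jitter) of the arm centres. Uniform jitter makes support bounds
  exactly testable.
* Expression is log-normal (ln-mean 3, ln-sd 1); read depth is linear in
  expression, floored at 5 and capped at 40 reads (library-size
  saturation — the real deposits are shallow, hundreds of genes with only
  >= 5 chimeric reads). Per-gene concentration
  `alpha_g = alpha x (expr/median)^(-coupling)` couples expression to
  specificity (coupling = 0 gives the null).
* Conservation and Tm per defined site are `+/-beta x z(S) + Normal(0,
  sigma)`, so the within-gene correlation approaches
  `beta / sqrt(beta^2 + sigma^2)`; gene-level importance is coupled to
  gene S the same way.
* Ribosome coverage is Poisson(30) per nt with the single nucleotide at
  (focal - 42) multiplied by q = 1.2; the deterministic variant has the
  closed-form normalized stall density `q L / (L - 1 + q)`.

All generators are pure functions of (config, seed).

The background fraction and the shallow-depth regime are load-bearing, not
cosmetic. The statistic measures *inequality* among binned pair weights: if
every read supports one duplex cluster, the binned weights are uniform over
that cluster and S ~ 0 despite perfect concentration — specificity is only
visible as contrast against promiscuous pairs, exactly as in real data.
Likewise, because `Mnorm = M/(c_i c_j)` divides by coverage twice, a cluster
of m reads jittered over (2j+1) positions carries per-pair binned weight
~ m while per-base coverage stays near 1, but is *suppressed* once depth
pushes coverage well above 1; at high depth the concentration signal
inverts. Within the default regime (depth <= 40, jitter 5, background 0.5),
mean gene S is decreasing in alpha, S couples positively to expression, and
the per-site coupling drives OR1 > 1 — the recovery properties the test
suite asserts. What passing these tests shows is that the pipeline
faithfully recovers planted structure of this kind; the generator does not
model sequence content, thermodynamics, crosslinking bias, ligation-distance
bias, or inter-molecular chimeras, so quantitative agreement with any real
cohort is out of scope.

## Problem sizes in the test suite

The recovery tests use cohorts of 150 genes x 20 seeds (alpha sweep),
500 genes (stall meta-gene; one seed, fixed up front), 500 genes x 20 seeds
(OR1 recovery and its null), and 150 genes x 1000 replicates plus
20 x 60-gene null cohorts (down-sampling); these sizes give the planted
effects comfortable margins over their standard errors while keeping the
whole suite under a minute. The control-profile check accepts up to 2 of
151 offsets beyond 3 SE — the chance level for that many comparisons — and
requires flatness at the stall offset itself.

## Known limitations

* Gene-level S depends on read depth through n and through the coverage
  normalization; cross-gene comparisons should use the down-sampling test
  when depth is heterogeneous (the full-data S-expression correlation is
  partly depth-driven by construction, in real and synthetic data alike).
* Anchors are consumed as single-nucleotide fragment centres; duplex-group
  assembly, crosslink-site correction and base-pair-resolution structure
  inference are out of scope.
* The fitness model is a forward model with shipped constants; it is not an
  estimator and its parameters are not fitted to data.
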