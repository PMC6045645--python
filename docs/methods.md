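# Methods

## Count model and per-CpG test

Methylation evidence at one CpG in one sample is a pair of counts: `k` reads
supporting methylation out of `N` covering reads. The model is
beta-binomial, `k ~ Binomial(N, p)` with `p ~ Beta(alpha, beta)`: the
binomial layer is read-sampling noise, the Beta layer is biological
replicate-to-replicate variance. We parameterize by mean and concentration,
`mu = alpha/(alpha+beta)` and `phi = alpha+beta`; large `phi` means
replicates agree tightly, `phi -> infinity` recovers the binomial.

Forward- and reverse-strand cytosines of one CpG dinucleotide are summed
before testing (keyed at the forward-C position; a reverse-only cytosine at
`q` maps to `q-1`). This uses all reads of the dinucleotide and suppresses
artifacts from CpG-destroying mutations on one strand.

The per-site test compares a pooled maximum-likelihood fit (one
`(alpha, beta)` for all samples) with per-group fits, referring
`Lambda = 2(l_alt - l_null)` to chi-square with 2 df (mean and dispersion
both freed per group). A 1-df variant with per-group means around one shared
concentration is available (`df_mode: shared`). `delta` is the difference of
fitted group means — model-consistent and shrinkage-free — not a ratio of raw
counts. A site is testable when each group has at least one covered sample;
untestable sites are carried through assembly with a flag and excluded from
testing.

### Optimization

Fits maximize the summed log beta-binomial likelihood in
`x = (logit mu, log phi)` with Nelder–Mead, starting from method-of-moments
estimates; `mu` is clamped to `[1e-6, 1-1e-6]` and `phi` to `[1e-2, 1e6]`,
with a small quadratic penalty outside the box so the simplex settles on the
boundary instead of wandering on the flat clipped region. Group fits are
additionally started from the pooled optimum, which guarantees
`l_alt >= l_null` (so `Lambda >= 0`) by construction. Convergence is judged
by function-value stability — a restart from the best point must improve the
log-likelihood by less than 1e-6 — because on boundary ridges (e.g. all-zero
counts, where `phi` is unidentifiable) the simplex legitimately cannot
contract in `x` while the likelihood is fully converged. Fits were checked
against exhaustive 30-point multistarts (agreement within 3e-8) and against
a refined 200x200 log-spaced grid search (within 1e-3, see the acceptance
suite). Fitting is deterministic: no randomness anywhere in the analysis.

### Known calibration limits

Two finite-sample properties of this test family are worth knowing and are
deliberately documented rather than patched:

* With 3+3 samples the chi-square(2) reference is slightly anticonservative:
  in matched-model null simulations (coverage ~ NegBin mean 30, `p ~
  Beta(3,7)`) the empirical rejection at nominal 0.05 is ~0.08. The 1-df
  shared-dispersion variant is worse (~0.12), because its single degree of
  freedom understates the freedom the two extra mean parameters actually buy.
* The free dispersion gives the null an escape hatch at extreme sites: for a
  complete 0/30 vs 30/30 (3v3) split the pooled null fits a bimodal Beta
  (mass ~1/2 at each extreme, `phi` at its lower clamp), so `Lambda` caps
  near `-2 * 6 ln(1/2) ~ 8.3` and the p-value floors around 0.014. Interior
  splits (e.g. 0.1 vs 0.67) cannot hide in that bimodal null and are detected
  far more strongly. This effect bounds per-CpG power at heavily shifted,
  near-saturated sites.

Both behaviors are inherent to per-site maximum-likelihood beta-binomial
LRTs at n=6; fixing them would require cross-site dispersion sharing or
bootstrap calibration, which is outside this package's scope.

## Neighborhood combination, FDR, labels, DMRs

Raw site p-values are combined across each site's +/- `window_bp`
chromosome neighborhood (default 200 bp) by equal-weight Stouffer:
`z_j = Phi^{-1}(1 - p_j)`, `Z = sum z_j / sqrt(m)`, `p_comb = 1 - Phi(Z)`,
with the site itself included and missing-p sites excluded from every
window. Combined p-values are Benjamini–Hochberg adjusted (own step-up
implementation, cross-checked against statsmodels; missing values are
ignored and returned missing). Labels: `hyper` if `fdr < fdr_threshold` and
`delta >= min_delta`; `hypo` symmetric; else `ns`. Defaults
`fdr_threshold = 0.01`, `min_delta = 0.1` are conservative and
config-exposed; nothing downstream hard-codes them.

DMRs are maximal runs of same-label significant CpGs on one chromosome with
consecutive-significant-site gaps <= `max_gap_bp` (default 1000).
Non-significant sites inside a run neither break it nor count toward
`n_cpgs`; an opposite-label significant site always breaks it — a region is
directionally coherent by construction (this coherence rule is a design
choice; mixed-direction regions are simply split). Runs shorter than
`min_cpgs` (default 3) are dropped. Spans are `[first_pos, last_pos + 2)`:
half-open, BED-native, covering the dinucleotide.

## Feature arithmetic

* TSS association: a DMR associates with every gene whose TSS lies within
  `max_dist` bp (default 1000) of the region; the distance is 0 inside and
  otherwise the distance to the nearest covered base
  (`min(|tss - start|, |tss - (end-1)|)`), so with `max_dist = 0` only TSSs
  strictly inside are returned. Associations are many-to-many.
* Enrichment: for each named interval set, among profiled CpGs (those with a
  test result) lying inside any interval of the set — membership, counted
  once however many intervals overlap — report the fractions labeled hyper
  and hypo. Over the set of all profiled CpGs this reproduces the global
  direction summary exactly, which the tests assert as a cross-module
  consistency check.
* Interval membership is a sorted sweep over merged intervals
  (`searchsorted`), verified against a per-position linear scan.
* PWM scanning: additive log-odds scores over `{A,C,G,T}`; both strands
  (the reverse strand scores the reverse complement against the same
  matrix); windows containing `N` are skipped; the threshold is an absolute
  score (no p-value calibration — deliberately out of scope).
* Beta-matrix group comparison: per probe, the difference of group means
  over non-missing entries (probes missing an entire group are excluded),
  then one global two-sided Wilcoxon signed-rank test of the per-probe
  differences against zero (normal approximation above n = 25). A
  per-probe Mann–Whitney alternative was considered and rejected for the
  default because a single global test matches the "one shift across all
  probes" question this readout answers.

## Expression stage

Size factors are DESeq-style median-of-ratios: reference = per-gene
geometric mean over samples (genes containing any zero excluded), factor =
median ratio to the reference. Note the algebra: scaling one sample by `c`
scales its factor by `c` *relative to the other samples* (the reference
rescales by `c^(1/n)`), and renormalizing a matrix by its own factors makes
the factors constant, not necessarily 1.

The per-gene test normalizes counts by the factors, estimates one gene-wise
dispersion by method of moments pooled within groups (`var = mu + a*mu^2`,
floored at 1e-8), and applies a two-sided Wald test on the difference of log
group means with delta-method variances; `log2fc` uses pseudocount 0.5.
This is an intentionally simplified stage — no cross-gene dispersion
shrinkage, no independent filtering — adequate for the integration readouts
and calibrated (null rejection ~3–5% at nominal 5% on Poisson data, the
model-variance Wald construction being mildly conservative when the
method-of-moments dispersion floors at zero).

Integration joins TSS-associated DMRs to DE results per gene (one row per
gene–DMR pair) and attaches the Spearman correlation between DMR methylation
change and `log2fc`; a TF-oriented table joins each feature set's enrichment
fractions to the expression change of the TF's own gene via a name map.

## Synthetic data generator

The generator emulates the study conditions the analysis assumes, at desk
scale, and is the package's only data source in tests:

* One pseudo-chromosome ("chrS1") of 1 Mb by default; CpG positions are
  sorted uniform even integers (spacing >= 2). The standard fixture has 5000
  CpGs, i.e. ~200 bp mean spacing.
* Baseline methylation is the bimodal mixture `0.7 Beta(1,10) +
  0.3 Beta(10,1)` (unmethylated promoter-like mode, methylated gene-body
  mode).
* 20 hyper- and 10 hypomethylated regions of 5–8 consecutive CpGs are
  implanted with mean shift +/-0.4, clipped into `[0.02, 0.98]`, regions
  mutually separated by >= 3 kb. Hypermethylation regions are placed on
  low-baseline (promoter-like) CpGs and hypomethylation regions on
  high-baseline CpGs — mirroring promoter hypermethylation biology and
  ensuring the implanted shift survives the clipping.
* Counts: per strand, coverage ~ NegBin(mean `coverage_mean/2`, size 5);
  one methylation level per sample and CpG, `p ~ Beta(mu*phi, (1-mu)*phi)`
  with `phi = 10` by default (noticeable biological variance), shared by
  both strands; methylated reads binomial. Zero-coverage strands are
  omitted (absence = not profiled). A lognormal mode for `p` provides a
  deliberately misspecified generator for robustness checks.
* Features: an "enriched" BED set covering affected CpGs at `multiplier` x
  the background coverage probability (default background 0.15), plus two
  neutral sets.
* Expression: NegBin(size 10) counts around uniform base means with
  per-sample depth factors in [0.7, 1.4]; genes with a TSS placed at an
  implanted region get `log2fc` of sign opposite to the methylation shift
  (magnitude 1–2); other genes are null.
* Beta matrices: probe values `clip(baseline + shift*[mutant] +
  N(0, noise_sd), 0, 1)`, default shift 0.05 and noise 0.02, 2 vs 2 samples.

Every generator is a pure function of (config, seed); repeated calls are
byte-identical, and generated files round-trip through the package's own
readers. What the generator does **not** emulate: restriction-fragment
(MspI) coverage structure, CpG-island clustering of positions, spatially
correlated biological noise along a region, mapping or conversion errors,
and real genome annotation. Passing recovery tests therefore demonstrate
the statistical machinery under the stated model, not performance on real
RRBS libraries.

With these conditions (coverage 30, `phi = 10`, 3v3, shift 0.4) roughly
60–70% of truly affected CpGs reach `fdr < 0.05` (asserted in the test
suite), so region recovery at the conservative defaults
(`fdr_threshold = 0.01`, `min_cpgs = 3`) sits near 50–60% — the acceptance
script reports the exact recall it measures. The defaults stay at their
stated values rather than being tuned to the fixture.

## Pipeline

`dmrkit run --config config.yaml` chains: read + strand-merge counts ->
per-site tests -> site table; DMR calling -> BED6 + TSV; TSS association;
feature enrichment; expression DE; methylation–expression join; and a
`manifest.json` echoing the config, package version, seed and per-output row
counts. Outputs are a pure function of (inputs, config) — no timestamps, no
randomness — so reruns are byte-identical (the manifest differs only in the
echoed output directory when runs target different directories). Any stage
failure exits non-zero and records the failed stage in the manifest. The
config is YAML key-value with unknown keys rejected and thresholds
range-checked; all stages are also exposed as separate subcommands and as
plain library functions. Stages run serially; outputs never depend on
execution order.

## Problem sizes used in the test and acceptance suites

Calibration runs use 5000 null CpGs (3v3); the standard recovery fixture is
5000 CpGs / 30 implanted regions; oracle-equivalence checks use >= 100
random instances of size up to 500 per operation; the expression null uses
5000 Poisson genes; beta-matrix recovery uses 2000 probes. The end-to-end
determinism check runs the full pipeline twice on the standard fixture.
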