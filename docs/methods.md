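# Methods

## Scope and data model

The package evaluates candidate reference genes for qRT-PCR normalization
across the five sugarcane ovule developmental stages (AC, MMC, Meiosis,
Mitosis, Mature; three biological replicates each — the default design of
all generators). It consumes a gene × condition RPKM matrix for screening
and a gene × sample Ct matrix for stability analysis; it does not compute
RPKM from reads or perform any wet-lab QC (melt curves, gels, outlier
replicate rejection).

Sample metadata (stage, replicate) comes from a separate metadata file,
which is authoritative; `<stage>_<replicate>` sample-name parsing is only a
fallback. Missing Ct values (no amplification) are stored as missing and
excluded pairwise per statistic; `CtMatrix.drop_sparse_genes` excludes any
gene with more than 20% missing values with a logged warning — there is no
community convention here, so the threshold is deliberately conservative
and adjustable.

## Screening

CV is computed on stage-level values with the sample SD (n−1 denominator);
replicate-level columns are first averaged per stage when a column → stage
mapping is supplied. The defaults (CV < 0.6, top 18 by mean RPKM) are the
thresholds of the sugarcane workflow. Ties in mean RPKM are broken by
ascending CV and then gene id so screens are reproducible. Genes with zero
mean have an undefined CV and are reported, not fatal.

## Efficiency and quantities

The standard curve is OLS of Ct on log10 template amount;
E = 10^(−1/slope) − 1, and assays with slope ≥ 0 are rejected outright.
When no curve is available the default efficiency is E = 1 (perfect
doubling) — published efficiencies for the sugarcane assays cluster at
0.97–1.04, so the approximation is mild.

Quantities are Q = (1+E)^(−ΔCt) with ΔCt measured from each gene's minimum
Ct, so Q ∈ (0, 1] and the most abundant sample of each gene sits at exactly
1. The negative sign convention is immaterial to every stability statistic
downstream (all are SDs of log-ratios, invariant to per-gene rescaling) and
matches the conventional geNorm input.

Target validation divides the target quantity by the geometric mean of the
reference quantities and rescales so the calibrator (a stage label or a
single sample; default the first stage, AC) has mean ratio 1. With one
reference of equal efficiency this reduces exactly to ΔΔCt (verified in the
tests). Either one reference or several jointly may be supplied; both modes
are supported since published validation figures are ambiguous on this
point.

## geNorm

Pairwise variation is the sample SD of per-sample log2 expression ratios;
M is its mean over partners. Stepwise exclusion removes the highest-M gene
(ties broken by excluding the lexicographically smallest id, logged) and
recomputes. The *reported* M of a gene is its M at the step of exclusion —
this reproduces the classic strictly-increasing published M columns with a
tied final pair, and it is the score fed to the consensus (the final pair
shares dense rank 1; the pair is printed in lexicographic order).
V_n/n+1 values are computed on whatever gene set is given to the ranking
call; the optimal count is the smallest n with V < 0.15 (the conventional
cutoff), or the full panel size with a warning when no V passes.

## NormFinder

Implemented from the two-way mixed model: within each group, log2
quantities are double-centred; gene-specific residual variances use the
unbiased finite-panel moment estimator
σ̂²_ig = (u_ig − ū_g/(k−1))·k/(k−2) with u_ig = RSS_ig/(n_g−1), floored at
zero (the k/(k−1) factor alone unbiases only the panel-average variance).
Intergroup deviations d_ig are the interaction contrasts
(gene-in-group mean − gene mean − group mean + grand mean); their
across-gene dispersion net of sampling noise gives γ̂², and each d is
shrunk by γ̂²/(γ̂² + σ̂²_ig/n_g). Stability is the group-average of
|shrunk d| plus the shrunk estimate's posterior SD. Logs are base 2
throughout so NormFinder stabilities are commensurate with geNorm M values
(both SD-like quantities on the log2 scale).

Groups default to the five stages. A design without at least two groups of
two samples falls back to the ungrouped variant (warned): the SD of a
gene's doubly-centred log quantities with the k/(k−1) panel correction.

## BestKeeper

Computed on raw Ct: mean, dispersion, CV% = 100·dispersion/mean, the
per-sample geometric-mean index and each gene's Pearson r with it.
Dispersion defaults to the sample SD because the published sugarcane
statistics satisfy CV% = 100·SD/mean exactly; the original spreadsheet
tool's mean absolute deviation is available via `use_mad=True`. Ranking is
by ascending SD (CV% and gene id as tie-breaks); whether SD or CV% is the
primary published key is ambiguous, but the two agree on the top genes.

## Consensus

Dense ranking (1,1,2,3,…) is used for ties, not competition ranking
(1,1,3,4,…): only dense ranking of the tied geNorm pair reproduces the
published sugarcane geometric means (e.g. FAB2 with ranks (4,2,1) → 2.00;
competition ranking would give (5,2,1) → 2.15). Within NormFinder and
BestKeeper, scores are continuous and printed columns tie only through
rounding; the bundled published table therefore carries each method's
column *positions*, which reflect the full-precision ordering, and those
positions are the rank inputs for reproduction (geNorm's exact tie is the
one genuine shared rank). Final order is ascending geometric mean with
lexicographic tie-break; geomeans are clamped into each gene's
[min rank, max rank] envelope to absorb float round-off.

The bundled study tables transliterate EF1α as `EF1a` and normalise the
study's inconsistent spellings (FAB2/FBA2, TIC110/TIV110) to FAB2 and
TIC110.

## Synthetic data

Ct values follow Ct = baseline + stage effect + N(0, sd²): Gaussian noise
on the Ct scale, i.e. multiplicative log-normal noise on the quantity
scale, the standard qPCR error model. Baselines are U(18, 30) Ct, matching
the range observed for moderately expressed ovule transcripts. Stable
genes: |stage effect| ≤ 0.25 Ct, replicate SD ≤ 0.3 (defaults 0.2/0.2);
unstable genes: peak stage effect ≥ 1.5 Ct or replicate SD ≥ 1.0 (defaults
2.0 Ct peak effect, SD 0.3). These envelopes are chosen to make the two
truth classes unambiguous for recovery testing and are adjustable.

RPKM generation draws a log-normal shape per gene and *solves* the
log-scale dispersion (Brent's method) so each gene's realized sample CV
equals a target drawn from its class range (low: 0.05–0.35, high:
0.9–1.5), giving deterministic class separation at the 0.6 threshold;
shapes whose attainable CV saturates below the target (nearly tied top
deviations) are redrawn. Standard-curve series place Ct exactly on the
line implied by the true efficiency plus optional Gaussian noise. Target
genes encode a fold profile as Ct shifts of −log(f)/log(1+E) around a
baseline.

What the generators do *not* emulate: technical-replicate structure below
the biological replicate, inter-run calibration drift, efficiency
differences between genes (all default to E = 1), heteroscedastic noise at
high Ct, and correlated co-regulation among candidates. Passing recovery
tests therefore demonstrate correctness of the statistics under the
declared error model, not robustness to those real-data effects.

## Problem sizes and numerical choices

Recovery checks run 100 seeded datasets of 6 genes × 15 samples and
Monte-Carlo curve fits of 100 series — sizes chosen to make rate estimates
(≥ 95/100 criteria) meaningful while keeping the whole suite fast on a
laptop. All randomness flows through `numpy.random.default_rng(seed)`;
every generator is deterministic given its seed. Equality of stability
scores uses exact float comparison only where values are identical by
construction (the geNorm final pair); elsewhere tolerances are 1e−9 for
algebraic identities and 10%/25% for parameter-recovery bands on noisy
data.

## Known limitations

* The raw 18-gene sugarcane Ct table exists only as a journal supplement
  and is not redistributable here, so the full-data headline statistics
  (final-pair M = 0.15, MOR1 NormFinder 0.09, FAB2 BestKeeper 5.48 ± 1.52)
  are documented as expected outcomes in the test suite rather than
  verified in-repo; the published-moments and published-column
  reproductions are verified exactly.
* NormFinder's published stability values depend on the particular build
  of the original tool; this implementation follows the published model
  with the estimator details above, so third-party values should be
  compared with a modest tolerance (±0.05 is reasonable).
* The CLI `consensus` command runs the three algorithms directly from the
  Ct table rather than re-reading per-method TSVs, preserving the tied-pair
  and optimal-n structure that flat score files lose.
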