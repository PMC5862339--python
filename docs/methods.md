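# Methods

This note documents the statistical models behind `protnorm`, the
parameter choices that matter, what the synthetic spike-in generator does
and does not emulate, and the package's known limitations.

## Data model and preprocessing

Input is a protein × sample grid of non-negative raw intensities with a
sample → group design. Exact zeros are interpreted as abundance below
detection and converted to missing values before any transform; real
exports show zero fractions of roughly 0.06–0.6 % of all cells, and the
generator's default (0.3 %) sits inside that band. All methods then
operate on log2 intensities, except variance stabilization, which
requires the untransformed scale because its arsinh transform plays the
role of the log itself. Missing values are never imputed anywhere:
regression and smoothing fits use complete observations per fit, quantile
normalization maps through rank interpolation over the non-missing
values, and correlations are pairwise-complete.

## Normalization methods

### Shift methods (median, progenesis)

Median normalization shifts each sample so all medians equal the mean of
the per-sample medians. Progenesis-style normalization shifts each sample
by the median of its per-protein log-ratios to a reference sample; the
vendor's reference rule is proprietary, so `reference="auto"` picks the
sample with the highest mean pairwise Pearson correlation — a documented
approximation, surfaced as a parameter.

### Robust linear regression (rlr, rlr_ma, rlr_ma_cyclic)

These assume bias linear in log-intensity. Line fits use iteratively
reweighted least squares with Huber weights (tuning constant 1.345, max
50 iterations, tol 1e-8; statsmodels RLM); on exactly collinear noiseless
data the IRLS scale degenerates and the fit falls back to plain least
squares, which is then exact. `rlr` regresses each sample on the
per-protein median reference and inverts the line; `rlr_ma` fits M
against A with A the median sample and subtracts the fit;
`rlr_ma_cyclic` fits every unordered sample pair on its own MA transform
and moves each sample by half the fitted bias, sweeping pairs in
lexicographic index order for exactly 3 full cycles.

The cyclic sweep is a gossip-averaging scheme: each pair update replaces
both samples by (partially) their average. Three cycles leave a residual
of roughly 1 % of the initial bias scale, with a weak dependence on the
sweep order; this is documented behavior, not a convergence failure, and
matches the package's residual-trend contract (< 10 % of the initial
trend) rather than exactness.

### Local regression (loess_f, loess_cyc)

Same MA logic with a degree-2 local polynomial smoother: tricube
neighborhood weights, span 0.75, 3 bisquare robustness iterations,
evaluated on a 128-point quantile grid of A with linear interpolation in
between (the classical `delta` shortcut). `loess_f` uses the per-protein
mean sample as reference and iterates 3 times against the recomputed
reference, mirroring the cyclic cycle count; `loess_cyc` half-corrects
every pair for 3 cycles. Span and degree are package defaults — the
method family fixes only "local regression" — and are exposed as
estimator parameters. With span 0.75 a gently curved trend is removed to
well over 90 %; sharply oscillating trends (period comparable to the span
window) are outside the smoother's capacity.

### Variance stabilization (vsn)

Model: raw intensity y_ip for sample s follows an additive–multiplicative
error model, under which the per-sample transform

    h_s(y) = arsinh(a_s + b_s · y),  b_s > 0

has approximately intensity-independent variance. Estimation profiles the
per-protein means and the error variance out of the Gaussian likelihood
(with the transform's Jacobian), leaving 2 parameters per sample,
optimized by L-BFGS-B with an analytic gradient (the objective's
magnitude, N·log RSS over thousands of cells, makes finite-difference
gradients numerically worthless). Robustness comes from a
least-trimmed-squares outer loop that keeps the best-fitting 90 % of
proteins, so differentially abundant proteins cannot drive the
calibration. b_s is parameterized as exp(β_s) for positivity; convergence
is declared when parameters move less than 1e-8 between outer
alternations. Output is h_s(y)/ln 2 ("glog2"): for b_s·y ≫ 1 it equals
log2(y) + log2(2·b_s), so high-intensity values are directly comparable
to log2 data up to a per-sample constant.

Two degenerate regimes are handled explicitly. The profiled error
variance is floored at 1e-12 (arsinh-scale units²) so that noiseless
input, whose likelihood is otherwise unbounded below, does not make the
fit depend on an arbitrary floor location. A single usable sample leaves
the likelihood unidentified; the transform then falls back to a pure
glog with the linear region placed below the smallest observed intensity,
which reproduces log2 + constant to within arsinh curvature (< 1e-4 over
a 10-unit log2 range). A genuine limitation remains: on *noiseless*
multi-sample data the profile likelihood prefers an interior (a, b) with
the arsinh knee inside the data range — with any realistic noise the RSS
term dominates and the fit is well-behaved, as the variance-stabilization
tests show.

### SVD bias removal (eigenms)

Per-protein group means are estimated first (one-way ANOVA) so trend
removal cannot erase the treatment effect; the SVD runs on the residual
matrix of the proteins observed in every sample (incomplete proteins pass
through unchanged and are reported). Significance of the leading
components is decided by a permutation test: each protein's residual
vector is permuted across samples, group means are re-removed, and the
observed per-component variance fractions are compared with the 95th
percentile of the permuted fractions, sequentially, at α = 0.05 with 99
permutations (seeded, default 17).

Two details of this test are load-bearing. Permuting *within columns*
(across proteins) would leave any protein-flat trend — exactly the
per-sample offset pattern that dominates real bias — completely intact,
because a constant column is invariant under permutation; permuting each
protein's residuals across samples destroys protein-coherent sample
patterns of every shape. And the comparison must use variance fractions,
not absolute singular values: the ANOVA projection concentrates the
residual variance into S − G dimensions, so absolute singular values of
the observed matrix are systematically larger than those of permuted
matrices even under the null (measured: the absolute-value test calls a
trend in 100 % of pure-noise runs; the fraction test with re-projection
calls h = 0 in 96–99 %). With h = 0 the output is bit-identical to the
input — in particular per-sample total intensities are untouched, a
signature of this method among the normalizations here.

## Evaluation machinery

**Intragroup variation.** Per protein: PMAD = mean over groups of
1.4826·median(|x − median|) (log2 units; the consistency constant fixes
the scale, not the rankings); PCV = mean over groups of SD/mean on the
analysis scale, with near-zero means flagged rather than suppressed;
PEV = Σ(n_g−1)·var_g / Σ(n_g−1) (squared log2 units). Proteins lacking
two observations in some group are dropped and reported. Method contrasts
on paired per-protein metrics use the two-sided Wilcoxon signed-rank test
(zero differences dropped; exact tail for ≤ 25 non-zero pairs).

**Differential expression.** Welch's unequal-variance t (robust default
with 3 replicates) and ROTS. The ROTS statistic family is
d_α(p) = |mean₁ − mean₂| / (α₁ + α₂·s_p), s_p the pooled standard error;
candidates {(α₁, 1) : α₁ ∈ 0, 0.01, 0.05, 0.1, 0.5, 1, 2, 5} plus the
pure fold change (1, 0). (α, k) maximize the reproducibility Z-score: the
mean top-k overlap across B within-group bootstrap dataset pairs, minus
the same overlap on permuted-label data, standardized by the bootstrap
overlap spread; k ranges over {25, 50, 100, …, n/4}. Defaults B = 100
(desk scale; more is better and is a parameter), seed explicit
everywhere; degenerate resamples (a group collapsing to one distinct
sample) are redrawn up to 10 times. Reported per-protein error control is
a permutation FDR for the selected statistic. A note on behavior: with
per-protein variances equal by construction the pooled SE carries no
ranking information and ROTS correctly prefers the fold-change end of the
family; the t-like end wins when variances vary across proteins and
effects scale with them.

**ROC/AUC.** Ranking score is |statistic| (spike concentrations move in
both directions across comparisons); AUC is the Mann–Whitney pair
statistic with ties counted ½, verified in tests against exhaustive pair
enumeration; proteins with missing statistics are excluded and counted.
DeLong's test compares correlated AUCs from placement values.

**Ranking.** Methods are ranked per comparison by descending AUC with
tie averaging (rank sums are always M(M+1)/2); per-dataset mean ranks
carry SE = SD/√n over comparisons. Pooling across datasets weights
dataset means by their comparison counts, with the pooled SE from the
Satterthwaite combination of the weighted variances and its effective
degrees of freedom reported alongside — the weighting rule is a package
choice, surfaced in the API, since only the structure (pooled mean ± SE)
is externally fixed.

**logFC.** Per protein, mean(group₂) − mean(group₁) on the analysis
scale (exactly antisymmetric); theoretical spike expectation
log2(c₂/c₁) from nominal concentrations; density summaries use a Gaussian
KDE with Silverman bandwidth.

## Synthetic spike-in generator

The generator emulates the structure of UPS1-style benchmarks: a constant
background proteome (log2 abundances ~ N(20, 2.5²), matching the broad
dynamic range of Orbitrap protein-level data); spike proteins whose
latent abundance shifts by log2(concentration) around the geometric mean
of the series (defaults: 2, 4, 10, 25, 50 fmol/μl, 3 technical
replicates, 2000 proteins of which 10 spikes); optional clustering of
spike base abundances (`spike_loc`, `spike_scale`) because an equimolar
spike mix occupies a narrow intensity band; per-sample bias
(offset/affine/bounded random cubic); log2-scale Gaussian noise (default
SD 0.2, a typical technical-replicate CV) plus optional additive raw
noise for heteroscedasticity (used when exercising variance
stabilization); and zeros placed preferentially at low intensity
(probability ∝ 1/intensity-rank), at a rate inside the observed
0.06–0.6 % band.

By default the drawn bias parameters are centered within each sample
group: nonbiological bias is taken to be orthogonal to the design, as a
balanced run order achieves experimentally. This matters for one method
family — a group-confounded bias component is indistinguishable from a
treatment effect, and a method that deliberately preserves group
differences (eigenms) must preserve that component too, making
"background logFC ≈ 0 after normalization" unattainable for it. Study
conditions that *want* group-confounded bias (to show the log2 baseline's
AUC loss) set `center_within_groups=False` explicitly.

Not emulated: peptide-level structure and rollup, retention-time or
run-order drift, correlated protein blocks (complexes/pathways), and
missingness beyond below-detection zeros. Passing tests therefore show
that the methods remove the bias classes they model from data with this
covariance structure — not that any method is best on a particular real
dataset.

### Study conditions used by the checks

Sizes are chosen so the full suite runs on a laptop-scale machine in
about a minute: 600–2000 background proteins, 10 spikes, 3 replicates,
ROTS bootstrap B = 60 in the end-to-end benchmark. Three scenario
families recur:

* *Benchmark direction* (every normalization ≥ log2 baseline in mean AUC,
  ≤ in median PMAD): 4 groups at 2-fold concentration steps, iid affine
  bias (offsets ±1, slopes 0.95–1.05, not group-centered), ROTS. The
  baseline's loss comes from the group-mean bias component corrupting
  every numerator; removing it restores detection. With the plain t
  statistic this ordering provably does not hold for eigenms: a shared
  within-group bias acts as a variance floor that stabilizes the
  baseline's t denominators, and stripping it while keeping the corrupted
  numerators lowers AUC — ROTS's α₁ regularization supplies the floor
  explicitly and removes the artifact.
* *logFC contract* (background logFC median within ±0.02 after every
  method): group-centered bias with offsets ±0.5, noise SD 0.05, adjacent
  2-fold comparisons. The tolerance bounds the admissible offset scale
  because of the ~1 % cyclic-sweep residual, and asymmetric spike content
  pulls cyclic fits by an amount growing with the concentration distance
  (~0.04 background shift at 8-fold, within tolerance at 2-fold) — both
  real properties of these algorithms, reproduced by the generator.
* *Pairwise vs global*: 5 concentration groups with
  concentration-trending per-sample offsets (the total-intensity pattern
  real spike-in series show) plus smooth curvature specific to the two
  compared groups. Normalizing only the compared pair leaves a 3–6×
  smaller residual M-vs-A trend than normalizing all 15 samples at once,
  for both cyclic methods: the trending offsets misalign the A-axis of
  cross-group pair fits, and corrections evaluated at misaligned A do not
  cancel. Under iid per-sample bias the ordering reverses — global mode
  sees more pairs per sweep and converges better — so the pairwise
  advantage is a property of group-structured bias, not of the mode per
  se.

## Numerical choices and degenerate inputs

Ties in quantile normalization receive the mean of their reference
values; ties in AUC count ½; ties in ranking share average ranks. Loess
windows are k-nearest on sorted A with a 1e-10 ridge on the local normal
equations for constant-y windows. Zero estimated slope in rlr, all-missing
samples, groups of size 1, fewer than 3 (regression) or 20 (loess)
complete proteins, single-class truth, and B < 50 are rejected with named
errors; stage failures inside the benchmark are recorded per
method × comparison and do not abort the run. Every stochastic step
(bootstraps, permutations, simulation) takes an explicit seed; identical
seeds give byte-identical reports (TSVs are written with a fixed float
format, JSON with sorted keys).

## Known limitations

* The Progenesis reference auto-selection approximates an undocumented
  vendor rule.
* Vsn parameters are weakly identified on noiseless multi-sample input
  (see above); the fitted b_s is a relative, not absolute, calibration.
* EigenMS applies trend removal only to proteins complete across samples;
  incomplete proteins pass through.
* The cyclic methods' 3-cycle sweep leaves a ~1 % residual of the initial
  bias and a slight sweep-order dependence.
* ROTS at B = 60–100 gives reproducible selections for the effect sizes
  used here but the original procedure favors substantially larger B for
  small effects.
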