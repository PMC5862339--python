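# protnorm

Normalization methods and spike-in benchmarking for label-free proteomics
intensity data.

Protein-level intensities from label-free LC-MS/MS carry strong
nonbiological variation: per-run offsets, intensity-dependent bias, and
noise whose variance depends on the mean. `protnorm` implements the
normalization methods practitioners choose between and the machinery to
compare them on data with known ground truth — spike-in designs, in which
a small set of proteins (e.g. the UPS1 mix) is added at known
concentrations to a constant background proteome.

It is written for computational proteomics researchers and method
developers who want to (a) normalize a Progenesis-style protein × sample
abundance export, or (b) benchmark normalization choices on synthetic
spike-in data that emulates real study structure.

## What's inside

**Eleven methods behind one registry** (`log2`, `median`, `quantile`,
`rlr`, `rlr_ma`, `rlr_ma_cyclic`, `loess_f`, `loess_cyc`, `vsn`,
`progenesis`, `eigenms`), implemented as scikit-learn-style transformers
with functional wrappers. All operate on log2 intensities except `vsn`,
which consumes raw intensities. Most share an MA-transform core: express a
sample against a reference as A = average intensity and M = difference,
model the M-vs-A trend and subtract it —

* **median / progenesis** — constant trend (per-sample shift);
* **rlr / rlr_ma / rlr_ma_cyclic** — robust line (IRLS, Huber weights),
  against a median reference sample or cyclically over all sample pairs
  (3 cycles);
* **loess_f / loess_cyc** — degree-2 local polynomial trend (span 0.75,
  tricube weights, bisquare robustness), against a mean reference or
  cyclically;
* **quantile** — replace each value with the mean of its order statistic
  across samples;
* **vsn** — per-sample arsinh transform h_s(y) = arsinh(a_s + b_s·y)
  fitted by robust profile maximum likelihood under an
  additive–multiplicative error model; output in glog2 units
  (≈ log2(y) + const at high intensity);
* **eigenms** — remove per-protein group means (ANOVA), find systematic
  trends in the residual matrix by SVD with a permutation test on the
  component variance fractions, subtract the significant trends, restore
  the group means.

**Evaluation**: pooled intragroup variation per protein (PMAD, PCV, PEV),
replicate Pearson similarity, Welch t and the reproducibility-optimized
test statistic (ROTS) for two-group differential expression, tie-aware
ROC/AUC against spike-in truth, DeLong's test for correlated AUCs,
AUC-based method ranking with tie averaging and Satterthwaite-pooled mean
ranks, and logFC diagnostics against the theoretical log2(c₂/c₁).

**Synthetic data**: a seeded spike-in generator (constant background,
concentration-scaled spikes, per-sample offset/affine/smooth-nonlinear
bias, additive + multiplicative noise, below-detection zeros) with exact
ground-truth records for recovery scoring.

## Worked example

Simulate a four-point concentration series (2, 4, 8, 16 fmol/μl; 3
technical replicates each; 600 background + 10 spike proteins; per-sample
affine bias), then benchmark every method with ROTS-based differential
expression:

```python
from protnorm import (BiasModel, GroupSpec, SimulationConfig,
                      simulate_spikein)
from protnorm.pipeline import BenchmarkConfig, run_benchmark

cfg = SimulationConfig(
    n_background=600, n_spike=10,
    groups=tuple(GroupSpec(label=f"fmol{c:g}", concentration=c)
                 for c in (2.0, 4.0, 8.0, 16.0)),
    bias=BiasModel(kind="affine", offset_range=(-1, 1),
                   slope_range=(0.95, 1.05), center_within_groups=False),
    noise_sd_log2=0.15, zero_rate=0.003, seed=11)
matrix, design, truth = simulate_spikein(cfg)

result = run_benchmark(matrix, design,
                       BenchmarkConfig(test="rots", rots_B=60, seed=11))
summary = result.auc_table.mean(axis=1).to_frame("mean_auc")
summary["mean_rank"] = result.rank_table.per_dataset["mean"]
summary["pmad_median"] = [result.variation_summary[(m, "PMAD")]["median"]
                          for m in summary.index]
print(summary.round({"mean_auc": 4, "mean_rank": 2, "pmad_median": 3}))
```

```
               mean_auc  mean_rank  pmad_median
log2             0.9638       6.67        0.295
median           1.0000       5.33        0.107
quantile         1.0000       6.25        0.095
rlr              1.0000       5.83        0.098
rlr_ma           1.0000       5.33        0.099
rlr_ma_cyclic    0.9999       7.25        0.097
loess_f          1.0000       5.33        0.097
loess_cyc        0.9999       6.08        0.096
vsn              0.9999       6.08        0.105
progenesis       1.0000       5.33        0.105
eigenms          0.9675       6.50        0.102
```

`mean_auc` is the mean area under the ROC curve over the six two-group
comparisons (spikes = true positives): the unnormalized log2 baseline
loses sensitivity to the per-sample bias while every normalization
restores near-perfect detection. `pmad_median` is the median per-protein
pooled MAD between technical replicates — normalization cuts replicate
variation roughly threefold here. `eigenms` deliberately preserves group
differences (including any bias confounded with them), which is why it
tracks the baseline's AUC more closely while still reducing replicate
variation. `mean_rank` is the tie-averaged AUC rank (1 = best) averaged
over comparisons.

The same workflow is scriptable from a shell:

```bash
protnorm simulate --seed 11 --out data/
protnorm benchmark data/abundance.tsv data/design.tsv \
    --truth data/truth.tsv --test rots --seed 11 --out report/
protnorm normalize data/abundance.tsv data/design.tsv \
    --method vsn --out normalized_vsn.tsv
```

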