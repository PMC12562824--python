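# Methods

## The statistical model

The package targets the screening situation of a two-group ocular cohort
(control vs glaucomatous eyes) with three blocks of variables: clinical
covariates, OCT/OCT-A structural and perfusion measures, and a multiplex
analyte panel quantified in plasma and aqueous humor. Three inferential
layers are implemented.

**Descriptive comparisons.** Continuous variables are routed by
Shapiro-Wilk normality at the analysis alpha (default 0.05): a two-sample
t-test when both groups look normal, otherwise the Wilcoxon rank-sum test.
The t-test is Welch's by default — the groups differ in size (30 vs 87)
and there is no reason to assume equal variances; a pooled-variance option
exists. The Wilcoxon branch uses the exact null distribution when both
groups have at most 50 observations and no ties, the tie-corrected normal
approximation otherwise. Nominal variables use the chi-square test
(no continuity correction by default) on a 2×2 table when every cell holds
at least five observations, Fisher's exact test otherwise; for 2×k tables
with k > 2 the chi-square is used regardless, since the exact test is
defined here only for 2×2. Descriptive summaries follow the convention
mean ± SD for n > 30 or normal-looking samples, median [25%–75%]
otherwise. p-values are Benjamini–Hochberg adjusted *within each analysis
block* (one family per `compare_variables` or `correlation_screen` call);
the composition of each family is therefore explicit in the call and
recorded in the outputs.

**Weighted generalized correlation.** Every (dependent, independent) pair
is fitted as a single-predictor GLM with intercept. Family dispatch
follows the dependent's scale: continuous → Gaussian; dichotomous →
quasibinomial logistic (binomial deviance, dispersion estimated from the
Pearson chi-square, so Wald p-values are quasi-likelihood-robust);
nominal with more than two levels → multinomial. Observation weights
taper Gaussian-fashion outside percentile fences:
t_low = p10 − 1.5(p90−p10), t_high = p90 + 1.5(p90−p10),
w(x) = exp(−½(d/s)²) with d = max(0, t_low−x, x−t_high) and
s = ½(t_high−t_low). This is the only parse of the fence construction
that makes w ≡ 1 inside [t_low, t_high] and a smooth taper outside.
Weights are computed from the predictor margin; when the response is also
continuous, the response margin's weights are multiplied in (both choices
configurable via `weighting`), so an outlying observation in either
variable is discounted. A degenerate spread (p90 = p10) falls back to
unit weights with a warning.

Model fit is summarized by the deviance-ratio pseudo-R²,
1 − D_res/D_null, clipped to [0,1], with D_null from the intercept-only
model under the same weights. For the Gaussian family this equals the
classical (weighted) R²; for binomial it is McFadden's measure on the
deviance scale. The signed correlation index is ρ = sgn(β)·√R², banded
|ρ| ≤ 0.10 irrelevant, (0.10, 0.30) weak, [0.30, 0.50) average, ≥ 0.50
strong (the band anchors are fixed; the half-open conventions are this
package's choice). For the linear family with unit weights ρ equals
Pearson's r exactly — the test suite asserts this to 1e-10. Multinomial
fits have one coefficient per non-reference level, so ρ is reported
unsigned with a `sign_undefined` flag rather than guessing a convention.
Perfect separation in a logistic fit yields a flagged non-converged
record, never a crash.

**Volcano tables.** Per analyte and compartment: log2 of the ratio of
group means (glaucoma over control, computed on stored concentrations,
censored zeros included) against −log10 of the *unadjusted* routed
p-value. Labeling thresholds sit at |log2FC| ≥ 2 and −log10 p ≥ 1.3
(equivalent to p < 0.05). A zero group mean flags the record
undefined-FC; no pseudo-count is invented.

## The five-step multivariable procedure

1. **Filtering.** Constants, variables under 66% completeness, and
   categorical variables with any level held by fewer than 7 samples are
   discarded. Detectability is counted over the pooled cohort.
2. **Clustered chained-equations imputation.** The pairwise
   single-predictor pseudo-R² matrix over all candidates is symmetrized
   with the maximum of the two directions (conservative grouping);
   distance 1 − R² feeds average-linkage agglomerative clustering cut at
   k = max(3, ⌈(p − 50)/8⌉) for p candidate variables (fractional values
   rounded up). Continuous–continuous entries use the closed form
   (squared Pearson, identical to the linear deviance ratio); entries with
   a binary target use the logistic deviance ratio. Each variable with
   missing cells is then imputed by chained equations whose predictor set
   is exactly one representative per cluster — the medoid, i.e. the
   member with the smallest mean within-cluster distance — excluding the
   target itself. Continuous targets use predictive mean matching
   (5 donors nearest in predicted value, one drawn at random), binary
   targets a Bernoulli draw from a logistic fit; 10 cycles, one completed
   dataset, fully seed-controlled. Observed cells are never altered.
3. **Stability selection.** 100 runs of 5-fold cross-validated Lasso on
   internally standardized predictors (nominal variables enter as
   reference-dropped dummies, each dummy counted individually toward the
   model size m). Every run re-randomizes the fold partition. The
   per-run penalty is chosen by the 1-SE rule — the largest λ whose CV
   error is within one standard error of the minimum — which is the
   convention glmnet reports by default; the error-minimizing λ is
   available via `lambda_rule="min"`. A variable selected in fewer than
   5% of runs (i.e. fewer than 5 of 100) is discarded. A concluding
   Lasso at the median of the per-run λ picks the working set; if its
   size violates the permissive bound n ≥ 35 + 6.5·m, λ is raised
   (×1.1 steps) until it holds.
4. **Backward reduction.** The working set is refit unpenalized; the
   variable with the largest Wald p-value is dropped iteratively until
   the strict bound n ≥ 50 + 8·m holds. Reported signs always come from
   unpenalized refits on original scales.
5. **Refit on original data.** The model is refit on the non-imputed
   data (complete cases for the model's variables) and reduced again
   until the strict bound holds at that n. The emitted model reports the
   complete-case n, residual and null deviance, pseudo-R² and per-variable
   coefficient signs, plus a full audit trail (every exclusion, the λ
   sequence, every backward step).

At the study's glaucoma-group size n = 87 the bounds give m ≤ 8 at the
Lasso stage (87 = 35 + 6.5·8 exactly) and m ≤ 4 in the final model.

## The synthetic cohort generator

The generator emulates the study conditions the analysis assumes: 30
control and 87 glaucomatous eyes; clinical and OCT/OCT-A variables drawn
normally with per-group location/scale taken from the published cohort
table (e.g. RNFL 96.79 ± 8.72 vs 74.32 ± 13.87 µm; whole-ONH vessel
density 47.00 ± 2.52 vs 35.97 ± 6.86%); sex and glaucoma-entity categories
from the published counts; a 36-analyte panel (ET-1 plus 35 cytokines and
vascular/metabolic factors) log-normal in both compartments with log-SD
0.5 and baseline abundances spread deterministically over ~3 decades.

Planted structure: plasma ET-1 and the 11 aqueous-humor analytes the
study reports elevated carry a log2 fold change of 1.0 — a modest effect
consistent with a volcano plot where points clear the p line but sit
inside the ±2 FC lines; and six analyte → vessel-density couplings
(APN −0.45 to peripapillary VD; C3a, MMP-3 −0.35 to peripapillary VD;
resistin, sTIE-2, ZAG −0.35 to whole-ONH VD) on standardized scales,
matching the reported ρ ≈ −0.3 pattern. A coupled target's standardized
residual is Σ cⱼ zⱼ + √(1−Σc²)·ε, so couplings with unit squared norm
leave no independent noise and regression recovers the planted
coefficients exactly — the basis of the coupling-fidelity test.

Corruption is applied in measurement order: couplings → left-censoring at
the detection limit (below-LOD values stored as 0 with the detected flag
cleared, so the "values above 0" recoding rules apply verbatim) → outlier
contamination (each continuous cell independently with probability 0.02,
analytes multiplied by 10, other variables moved 10× from their center) →
missingness (MCAR at 0.05, never on an already-censored cell, so the
masks partition). The assays' true detection limits are not public;
defaults sit at the 2nd percentile of each analyte's control distribution
(exp(μ − 2.054σ)) and are configurable per analyte. All draws derive from
one master seed through per-stage child streams, so outputs are
byte-identical across runs and enlarging one rate does not perturb the
other stages.

What the generator does **not** emulate: spatial correlation between
OCT-A sectors, correlated (non-MCAR) missingness, assay plate/batch
effects, upper quantification limits, and the within-participant
correlation of bilateral eyes. Passing recovery tests therefore shows the
statistics behave correctly under the stated generative assumptions, not
that real cytokine data meet those assumptions.

## Numerical choices

- Quartiles and percentiles use linear interpolation between order
  statistics everywhere (the fence rule exposes the convention for
  sensitivity checks).
- Outlier "removal" before the multivariable stage is per-cell masking to
  missing, preserving n for imputation, not row deletion.
- Analytes whose positive values are all outliers are withheld from
  continuous analyses; only their dichotomous recode is tested, via the
  nominal route.
- pseudo-R² with zero null deviance is defined as 0 (nothing to explain);
  the report layer refuses to print a model whose pseudo-R² disagrees
  with 1 − D_res/D_null by more than 5e-3.
- Lasso convergence: coordinate descent capped at 5000 iterations;
  single-predictor GLM fits at statsmodels defaults (IRLS, deviance
  tolerance 1e-8); non-convergence is flagged, not fatal.
- Ties in backward selection resolve by pandas' first-maximum rule;
  selection order is column order, which the stability frequencies are
  provably invariant to (tested by permutation).

## Problem sizes in the test suite

Simulation-based checks run at the study geometry (30 + 87): type-I
calibration over 4,000 null variable-comparisons, coupling detection over
40 seeds, multivariable recovery over 100 seeds with one planted driver
(standardized coefficient 0.6) among 30 noise candidates, and large-n
fidelity checks at n = 4,000. These sizes give binomial standard errors
comfortably inside the asserted tolerances while keeping the default
suite in the tens of minutes on one core.

## Known limitations

- The multivariable stage models all dependents with the linear family;
  ordinal dependents (staging scores) are treated as interval-scaled.
- Quasibinomial models have no likelihood; the binomial deviance is used
  in the pseudo-R², which is the standard working-likelihood convention.
- Fisher's exact routing applies only to 2×2 tables.
- A single completed imputation dataset is used for model selection;
  between-imputation variance is not propagated.
- ρ and p are deliberately not combined into a single "significance"
  statement; the effect-size bands and the BH-adjusted p are reported
  side by side.
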