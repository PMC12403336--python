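# Methods

This note documents the statistical model behind each pipeline stage, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical and design choices that were genuinely open.

## Data model and preprocessing

The quantitative object is a protein × sample matrix of label-free DIA
intensities with an explicit missingness mask and a processing-state tag
(`raw → log2 → imputed → scaled`; transitions are enforced so stages cannot
be applied out of order).

* **Presence filter** — a protein is retained when observed in at least
  `min_presence_fraction_per_group` (default 2/3) of the samples of *every*
  group. The published description of this filter admits two readings
  ("remove proteins with over 66 % missing in at least one status" would keep
  proteins present in ≥ 34 % per group); the stricter ≥ 2/3-per-group reading
  is the default and the fraction is configurable. A 1e-12 tolerance keeps
  exact boundary counts (36 of 54 = 2/3) on the retained side of the
  comparison.
* **Imputation** — missingness in TF proteomics is dominated by abundance
  (left-censoring at the detection limit), so missing values are drawn from
  a normal down-shifted from the observed distribution:
  mean `μ_obs − downshift·σ_obs`, SD `width·σ_obs`, with defaults
  downshift = 1.8 and width = 0.3 SD. The downshift is the published value;
  the width is the convention of the software family this emulates and is
  exposed in config. Scope is per sample column (each sample has its own
  detection limit); a whole-matrix scope is available. A column needs ≥ 2
  observed values, otherwise the stage aborts naming the column.
* **Scaling** — per protein row, (x − min)/(max − min); a constant row maps
  to all zeros (an arbitrary but fixed convention; 0.5 would be equally
  defensible). Scaling feeds only the classifiers; differential abundance
  runs on the imputed log2 matrix, where differences are log2 fold changes.

## Differential abundance

Per protein, d = (mean_case − mean_control)/(se_pooled + s0) with s0 = 0.1;
se_pooled is the classical pooled-variance two-sample standard error, so
d reduces to Student's pooled t at s0 = 0 (a test asserts this to 1e-10).
The permutation FDR draws `n_permutations` (default 250) distinct group-label
assignments — exhaustive when the number of distinct assignments is smaller —
and estimates, at each observed |d| as a candidate cutoff,

    FDR(|d*|) = mean_perm #{|d_perm| ≥ |d*|} / #{|d_obs| ≥ |d*|},

clipped to [0, 1]. The raw curve is made monotone (non-increasing in |d*|)
by assigning each cutoff the minimum raw FDR over all cutoffs at or below
it — the q-value convention: the best achievable FDR among cutoffs that
would still call the protein. Ties in |d| share one FDR value by
construction. Signed fold changes are reported as FC = 2^L for L ≥ 0 and
FC = −2^|L| for L < 0, so a halving reads −2.0 rather than 0.5; rounding
happens only at presentation.

The test is two-sided via |d|; no covariate adjustment is implemented (the
two-sample permutation scheme has no covariate slot).

## Classifier bench

Each bootstrap run draws a stratified 80/20 train/test split (per-class
shuffling with rounded class quotas, both sides kept non-empty), tunes
hyperparameters by inner stratified k-fold CV maximising AUROC (default 10
folds, capped at the minority-class size with a warning; ties go to the
earliest grid point), refits on the full training portion and scores the
held-out 20 %. AUROC uses the Mann-Whitney tie convention (ties count ½).
Sensitivity and specificity are taken at each estimator's native decision
point (probability 0.5 for the logistic model, margin 0 for SVMs), since no
operating point was published.

Models and default grids: L1 logistic regression with the literal λ grid
0–100 in steps of 0.1 (λ maps to scikit-learn's `C = 1/λ`; λ = 0 is
implemented as `C = 1e10`); linear SVM with C ∈ {0.01, …, 100}; RBF SVM over
a small C×γ grid; random forest with 500 trees and `max_features` 1–5. The
drivers and tests thin these grids for tractability; grids are plain data on
`ModelSpec` and every choice is recorded. "Bootstrap" means repeated
stratified re-splits by default, matching the pairing of the published
procedure with an 80/20 split; a with-replacement mode (`mode="resample"`,
out-of-bag testing) is available.

Per-run weights are stored for the linear models (lasso coefficients,
linear-SVM weights); a protein is "selected" in a run when its lasso
coefficient is non-zero. For random forests the impurity-based feature
importances are stored: out-of-bag permutation importance would be
preferable in principle but costs another factor of the feature count per
run, and nothing downstream consumes RF importances (the tier list uses
lasso selections only).

## Signature selection

The tier list keeps proteins with lasso selection fraction ≥ 20 % whose
bootstrap weight SD is below the absolute mean weight, intersected with DA
significance. "SD below the mean" is interpreted per protein, with zeros
for runs that did not select it; the alternative reading (moments over
selected runs only) is available behind `stability_rule`. Writing f for the
selection fraction and (m, s) for the conditional weight moments, the
zero-inclusive rule is equivalent to s²/m² < 2f − 1, i.e. it demands
selection in more than half the runs plus a bounded conditional coefficient
of variation — a usefully strict stability notion.

Candidates are ranked by |mean weight| descending, and for k = 1..K a lasso
is fitted on the top-k candidates under the same resampling protocol
(common split seeds across k, so adjacent panel sizes are compared on paired
splits); the optimal panel is the smallest k attaining the maximal mean test
AUROC. Forward nested panels, not exhaustive subset search: the published
curve is cumulative per protein, and 2^24 subsets were never on the table.
One practical caveat documented here because it shapes expectations: when
per-protein effects are strong the panel AUROC saturates early and the
smallest-argmax rule stops before the full planted set; the curve is a
model-selection device, not an effect-size estimate.

For the signature stage the lasso grid is concentrated on one penalty scale
(λ ∈ {0.1, 0.3, 0.5, 1.0}): mixing unpenalized and heavily-penalized refits
across bootstrap runs puts weights on incomparable scales and inflates the
weight SD artificially, which would starve the tier list.

## Densitometry validation

Normalised abundance = log10((band / pooled-standard) / total protein µg);
the pooled standard is loaded on every membrane, so the transform is
invariant to membrane-wide intensity rescaling (asserted as a property
test). Triplicate lanes are averaged (mean) before export by the generator;
median aggregation would also be defensible. Mindet imputation replaces each
missing band with the protein's minimum observed value across samples — per
protein, not global, because proteins occupy different dynamic ranges on
different membranes. Group differences use the equal-variance Student
t-test (Welch behind a flag) with Bonferroni correction over the panel size;
both D'Agostino-Pearson and Shapiro-Wilk normality tests are run and
reported, and the t-test is applied regardless with a warning when either
rejects at α = 0.05, mirroring how these panels are analysed in practice.
The in-silico evaluation re-benches the panel proteins singly and combined
and reports a lasso selection profile across outer CV folds.

## Clinical statistics

ΔFRS assumes the full ALSFRS-R of 48 at symptom onset (the universal
convention) unless a baseline is provided; classes are fast (> 1.11), slow
(< 0.47) and intermediate (boundaries inclusive to intermediate, matching
the stated 0.47–1.11 range). Disease duration uses the mean Gregorian month
(30.4375 days). Quartiles use linear interpolation (numpy default). The
normality gate for "parametric" requires *both* tests non-rejecting — a
conservative arbitration, configurable via α. 2×2 categorical contrasts use
Fisher's exact test; r×c contrasts use chi-square without continuity
correction; multi-group quantitative comparisons use Kruskal-Wallis. A
variable observed in only one stratum (e.g. onset site, defined only for
patients) is reported without a test.

## Synthetic data: what it emulates, what it does not

`generate_proteome` draws per-protein base log2 abundances uniformly on
(12, 24), adds the planted group effect to case samples and i.i.d. normal
noise (SD 1.0 log2 units), and exponentiates. A cell is missing when a
Bernoulli detection draw with probability logistic((x − 18.0)·0.8) fails
(x the cell's log2 intensity), plus a 1 % MCAR floor. The midpoint/slope
defaults were chosen so that roughly 40 % of proteins survive the 2/3
presence filter, matching the published ratio of consistently quantified to
identified proteins; cohort-size defaults are 54 controls / 49 cases
(discovery) and 52/51 (validation). Planted signal proteins default to a
base of 21 — the consistently-detected regime — because the published
signature proteins were all consistently quantified; set
`signal_base_log2=None` to randomise them like any other protein.

The generator emulates: log-normal intensities, abundance-dependent
missingness, group effects, densitometry membranes with pooled standards and
scale factors, triplicate lanes, occasional missing low bands, and clinical
fields with the ≥ 5 mm wetting-length inclusion rule. It does **not**
emulate: correlated protein modules (co-regulation), batch/run drift,
peptide-level quantification, sex- or age-linked proteome structure, or
heavy-tailed technical outliers. Passing tests therefore demonstrate that
the pipeline recovers what it claims under its own assumptions — not that
those assumptions hold in any particular real cohort.

`generate_wb_panel` writes band = true abundance × membrane scale ×
multiplicative log2-normal noise (SD 0.15), with per-sample total protein
uniform on 10–60 µg and the lowest-decile bands censored at an elevated rate
(~3 % overall), echoing the published per-protein missing-band counts.

## Canned experiments and problem sizes

`lacrimark.experiments` freezes the two simulation studies the acceptance
tests score:

* **Null calibration** — 5 cohorts (500 proteins, 50/50 samples, no
  effects); 15 bootstrap bench runs per model per cohort over reduced grids;
  expected: mean AUROC within [0.45, 0.55] for every model family,
  (almost) nothing at FDR < 0.1, and the s0 = 0 statistic's type-I error at
  α = 0.05 within binomial error.
* **Parameter recovery** — 12 cohorts (200 proteins, 50/50 samples, six
  planted effects of magnitude 1.0 log2 unit alternating in sign, censoring
  disabled so the score reflects the selection machinery rather than the
  imputation); 25 bench bootstraps, forward curve over ≤ 12 candidates with
  40 resplits per panel size; expected: ≥ 5 of 6 planted proteins inside the
  optimal panel in ≥ 80 % of cohorts.

Seed counts, bootstrap counts and protein counts are the package's own
tractability choices (a full test run completes in minutes on one CPU);
effect sizes, sample sizes and noise levels are the study conditions and are
fixed.

## Known limitations

* The lasso λ grid is interpreted on scikit-learn's 1/C scale; glmnet-style
  per-observation scaling differs by a factor of n, so λ values are not
  numerically portable across implementations.
* The permutation FDR shares one null distribution across proteins (as the
  emulated software does); proteins with atypical variance are shrunk toward
  the pooled behaviour by s0 but not modelled individually.
* The forward-AUROC panel rule (smallest argmax) is greedy and noise-prone
  near its plateau; with strong effects it returns panels smaller than the
  planted truth by design.
* Sensitivity/specificity at the native decision point are not comparable
  across models with different calibration; AUROC is the primary metric.
* The synthetic clinical table is marginal-realistic (ranges, missingness)
  but carries no dependence between clinical fields and the proteome.
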