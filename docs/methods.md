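# Methods

## Study design and data model

The package targets a small fixed CpG panel measured on Illumina 450K
beta-values. The bundled annotation lists 22 probes of the *GSDME* locus
(6 gene-body, 14 putative-promoter, 2 upstream probes on chromosome 7,
GRCh37 coordinates); the bundled cohort registry lists 14 multi-cancer
datasets totalling 719 solid-tissue-normal (NT) and 5,783 primary-tumor (TP)
samples. A cohort qualifies for analysis when its normal/tumor ratio is at
least 10% or it has at least 10 normals; every bundled dataset satisfies
this. All file formats are TSV (UTF-8, `NA` for missing); beta-values are
validated into [0, 1] on load, and each sample joins exactly one metadata
record (tissue, tumor type, patient barcode, stage I–IV, age, gender,
ethnicity, optional log-scale expression).

## Synthetic cohorts

No raw consortium data are shipped; all end-to-end behavior is demonstrated
on synthetic cohorts from `methpanel.synthetic`. For probe j, tumor type t
and tissue class c, a patient's mean methylation is

    m = inv_logit( logit(mu0_j) + u + 1[c=TP] * delta_{t,j} ),
    u ~ Normal(0, patient_sd),   beta ~ Beta(m * phi, (1 - m) * phi),

with the patient intercept u shared between a patient's NT and TP samples.
Effects act on the logit scale so values stay in (0, 1); values are clipped
to [1e-6, 1 − 1e-6] before any logit. Defaults, chosen once as realistic for
450K data and used throughout the tests:

- baseline normal-tissue means by region: promoter 0.15 (unmethylated CpG
  island), gene body 0.70, upstream 0.60;
- Beta concentration `phi = 50` (per-probe SD ≈ 0.05–0.07, a typical
  array-level spread);
- patient random-intercept SD 0.5 logits;
- planted tumor effect `delta = 2.0` logits on a six-probe panel, shared
  across tumor types, all other probes null;
- expression = 8.0 − Σ_promoter beta_j + Normal(0, 0.5) (inverse
  methylation–expression coupling on promoter probes only);
- stage drawn uniformly over I–IV independent of methylation (an optional
  `stage_interaction` switch couples them for power studies);
- sample counts default to the bundled registry rows; `scale_counts` shrinks
  the whole design proportionally (minimum 4 per class) for desk-scale runs.

What the generator does *not* emulate: probe-to-probe correlation beyond the
shared patient intercept, copy-number or tumor-purity confounding, batch
effects, and genome-scale probe sets. Passing tests therefore demonstrate
the correctness and calibration of the statistical machinery under the
declared model, not robustness to those real-data artifacts.

A second, inverse generator (`generate_label_model_data`) draws
(beta, stage, tissue) from an explicit logistic label model; it is the
forward model for calibration and power studies of the interaction test,
with beta ~ Beta(2, 2) and stage uniform on 1–4.

## Differential methylation

Each probe is tested within each dataset with the random-intercept model
beta ~ tissue + (1 | patient). Estimation is profiled REML over the variance
ratio (block-diagonal algebra; patients contribute 1×1 or 2×2 blocks), and
the tissue effect is F-tested with a Satterthwaite denominator df computed
from the observed REML information by finite differences. When the
random-intercept variance hits the zero boundary — including fully unpaired
designs, where it is unidentifiable — the test reduces exactly to the OLS
F-test with n − 2 df. The implementation is cross-checked in the tests
against statsmodels MixedLM (variance components, coefficients) and against
R's lmerTest Satterthwaite F-test on the same data.

Simulated calibration at the null (patient_sd = 0, 50 pairs, Beta noise):
rejection ≈ 0.054 at α = 0.05 — the mild anticonservatism expected of a
plain Satterthwaite correction without the Kenward-Roger covariance
adjustment; the acceptance study verifies the rate stays within
[0.035, 0.065]. Tests run on beta-values directly (no M-value transform),
raw p-values by default, optional Benjamini–Hochberg. Direction (hyper/hypo)
is assigned from the significant model coefficient; in rare unbalanced
designs where the GLS sign contradicts the raw mean difference, no call is
made (`ns`), keeping the reported direction consistent with the group means.

## Combination search

`enumerate_subsets` yields subsets in deterministic (size, lexicographic)
order; over the 22-probe panel there are 74,613 six-probe and 1,540
three-probe subsets (110,055 across sizes 1–6). The AUC primitive is the
rank-based Mann–Whitney statistic with ties counted ½, asserted exactly
equal to O(n²) pair counting.

Bootstrap scoring draws `n_per_class` samples per class (default 700)
per replicate — without replacement when a class is large enough, with
replacement otherwise, so per-dataset runs remain defined — fits an
unpenalized logistic regression, and records the in-replicate AUC of the
fitted scores, matching a design that evaluates no held-out fold inside the
bootstrap. This in-sample AUC is optimistic under the null (≈ 0.536 for six
null probes at 2×700); an `oob=True` flag scores the out-of-bag samples
instead and calibrates to 0.5, which is what the null-calibration tests
assert. Quasi-separation (|coef| > 1e3 or non-convergence) triggers a
logged ridge-penalized refit; replicates that still fail are skipped, and
more than 10% skipped is an error.

Filters are inclusive on both thresholds (mean AUC, worst per-dataset AUC);
survivors are ordered by descending mean AUC with lexicographic
tie-breaks. A threshold sweep over a configurable grid (0.01 or 0.1 steps
from 0.80 up to the maximum observed mean) supports filter selection. Probe
subsets are also rankable by AIC = 2p − 2·loglik of the full-data logistic
fit (lower is better). Each subset's bootstrap stream is seeded from the run
seed and the subset itself, so results are independent of evaluation order
and of any parallel chunking.

## Pan-cancer classifier

The fixed panel (default probes 3, 12, 14, 18, 20, 21 — one gene-body, four
promoter, one upstream) is evaluated by stratified 10-fold CV: folds are
stratified jointly by tissue and tumor type when every stratum can fill the
folds (falling back to tissue-only on small cohorts); held-out fold
probabilities are pooled into a single ROC. Tumor is the positive class and
the cut-off comparison is ≥ (default 0.55). Optional age/stage covariates
can enter the model; stage, recorded only on tumor samples, is imputed for
normals from the same patient's tumor stage so it carries no class signal —
with stage simulated independent of methylation, adding it moves the CV AUC
by < 0.01. External validation refits the panel (with internal CV) on each
external cohort; coefficients are never transferred. Models serialize to a
plain-text key-value file.

## Tumor-specific signatures (PLSDA)

PLSDA is PLS2 regression of the one-hot tumor-type matrix on column-centered
beta-values; a sample's class score is the predicted indicator value. Two
routes are provided: NIPALS (scikit-learn `PLSRegression`, tolerance
tightened to 1e-12) and an in-package SIMPLS (successive dominant singular
directions of the deflated cross-product matrix). Their predictions coincide
to ~1e-8 whenever the centered response is effectively rank one (any
two-class problem), with one latent component, or at full component count
(both collapse to OLS); generic multiclass fits at intermediate component
counts can differ — including under predictor duplication, which reweights
the PLS directions — so consistency is asserted in the exact regimes.
Per-class performance is the cross-validated one-vs-rest rank AUC of the
class's own score (stratified folds, held-out scores pooled). The signature
scan evaluates every k-probe subset (k = 6 by default; deterministic seeded
subsampling for desk-scale runs) and reports per-class best subsets, the
best subset by class-mean AUC, and the grand mean. `n_components` defaults
to 2 and is an explicit, reportable hyperparameter; class imbalance is left
unweighted by default.

## Covariate associations

Expression is regressed on beta by OLS; age enters as a covariate only if
its own effect is significant at 0.05, mirroring a
keep-if-significant covariate policy. The single-df F-test (t²) on the beta
slope is reported with the Spearman rank correlation; the per-dataset table
flags whether the two criteria agree. Clinical covariates are tested with
beta as the outcome (OLS for numeric, one-way ANOVA for categorical). The
stage × methylation interaction is tested by a likelihood-ratio test between
logistic models tissue ~ beta + stage (+ beta:stage), stage coded numerically
1–4 (one interaction df; factor coding with 3 df by flag), complete-case
with a warning when stage is mostly missing. Simulated calibration: null
rejection 0.043–0.064 at n = 400–800 (the calibration study uses n = 800);
the power of the test at n = 800 reaches ~0.27 at an interaction of 0.5
logits per stage unit and exceeds 0.8 from ~1.5 — the power test asserts
this simulated curve.

## Pipeline and determinism

`run_pipeline` executes simulate → diffmeth → search → fit → signatures →
assoc → report from a single YAML config; each stage writes TSVs plus a JSON
manifest (inputs, seed, row counts, version). Reruns with the same config
are byte-identical; all randomness flows from explicit seeds
(`numpy.random.default_rng`), and subset-level seeding makes search results
independent of worker count or evaluation order.

## Problem sizes in the shipped studies

The acceptance studies run at the bundled cohort design (6,502 samples) for
the planted-panel recovery (5 seeds; the planted subset is scored with 100
bootstrap replicates and compared against all 8,008 disjoint six-probe
subsets at one balanced replicate each — the same mean-bootstrap-AUC
statistic throughout), a ~100,000-sample fresh draw for the generator-oracle
AUC, 1,000 simulated probes for mixed-model calibration, 1,000 replicates
at n = 800 for LRT calibration, and a reduced-scale pipeline for the
byte-determinism check. Unit tests use proportionally scaled-down cohorts;
AUC-band assertions are made on cohorts large enough that the stated bands
hold with Monte-Carlo margin.

## Known limitations

- The mixed model covers a single random intercept (patient); no nested or
  crossed random effects, and no Kenward-Roger covariance adjustment.
- The combination search is exhaustive by design; no greedy/stepwise path is
  provided beyond AIC ranking of explicit subsets.
- PLSDA offers no sparse variants or variable-importance scores.
- The generator's independence assumptions (above) bound what the test
  suite can certify about real array data.
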