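# Methods

`sphingostate` implements two analysis pipelines for melanoma
immunotherapy studies — a transcriptomic differentiation-state scoring
framework and a plasma sphingolipid biomarker pipeline — together with
synthetic-data generators that reproduce the statistical structure each
pipeline assumes, so every stage is testable without access to patient
data.

## Differentiation-state scoring

**Model.** Melanoma cells move along a differentiation axis (MITF-high
melanocytic → transitory → NGFR-high dedifferentiated).  The framework
assumes that literature gene signatures tracking this axis fall into
three coherent groups: signatures of the same state correlate positively
across tumors, signatures of opposite states negatively.

Given a non-negative expression matrix X (genes × samples) and a
signature G (a gene set), the per-sample signature score is a geometric
mean with additive pseudocount c:

    s_G(j) = exp( (1/|G|) Σ_{g∈G} ln(x_gj + c) ) − c

The pseudocount (default c = 1, suited to count-like data; configurable)
keeps the score defined at zero expression and preserves the identity
s_{g}(j) = x_gj for single-gene signatures.  Scores are compared between
signatures by Spearman correlation across samples (average ranks on
ties); the signature × signature correlation matrix is clustered by
agglomerative complete linkage on the distance d = 1 − ρ, cut at k = 3.
The agglomeration is written in-package with a defined tie rule (merge
the lexicographically smallest equal-distance cluster pair) so results
are deterministic on any input; it matches `scipy`'s complete linkage on
tie-free inputs and an exhaustive bipartition search on block-structured
inputs.

Cluster → state labeling is extrinsic (the three clusters have no
intrinsic order).  The caller either supplies labels or designates an
*anchor* signature marking the differentiated pole; clusters are then
labeled Differentiated / Transitory / Dedifferentiated by decreasing
mean correlation with the anchor.

State features are per-cluster averages of signature scores.  Because
geometric means of different signatures live on incomparable scales, each
signature row is z-scored across samples before averaging (on by
default; the cross-state argmax is meaningless otherwise).  A sample's
state call is the argmax of its three features, with exact ties resolved
by the fixed priority Differentiated > Transitory > Dedifferentiated
(logged; ties have probability zero on continuous data).

The differential-expression helper `filter_de` applies the conventional
threshold rule |log2FC| > 1 AND adjusted p < 0.05, both strict, to an
externally produced DE table; the package does not fit DE models itself.

**Per-sample enrichment.**  For correlating state features with pathway
activity (e.g. sphingolipid-metabolism GO terms), `sample_es` provides a
normal-scores statistic: within a sample, all n genes are ranked
(average ranks on ties), rank r is mapped to u = r/(n+1) and then to
s = Φ⁻¹(u); a set of m present genes scores ES = √m · mean(s over the
set).  Under random set membership ES is asymptotically N(0, 1) — the
test suite verifies mean and variance on 2000 null draws.  This is *not*
the GSVA kernel-density KS-walk statistic; it is a deliberately simple,
exactly specified single-sample enrichment score.  Since it feeds only
Spearman correlations downstream, any monotone-consistent per-sample
statistic yields the same qualitative output; the choice is flagged here
prominently.

**TF activity.**  Regulons (TF → targets with activation/repression
modes, confidence grades A–E; the lowest E grade is excluded by default)
are scored against a per-gene contrast (a Welch-t-like statistic with a
small variance floor, ε = 1e−8) by the same normal-scores construction:
NES = Σ_t mode_t · s_t / √m.  Repression of down-regulated targets
thereby counts toward positive activity.  Significance comes from
permuting gene labels of the contrast vector (two-sided,
p = (1 + #{|NES_π| ≥ |NES_obs|}) / (n_π + 1)), which is assumption-free
and exactly calibrated; the suite checks the type-I error at nominal
0.05.  The likelihood-weighted two-tail/three-tail refinements of full
aREA are intentionally not reproduced.

## Sphingolipid biomarker pipeline

**Input.**  A paired panel: plasma concentrations of a lipid species
set (78 species at the study design size) per patient at baseline and
week 6 of treatment, plus a binary response label (R = complete or
partial response; NR = progression or stable disease) and a treatment
cohort label.  Concentrations must be strictly positive; the per-patient
predictor is the treatment-induced *evolution*
fc = log2(week6 / baseline).

**Feature selection.**  Classic Boruta, written in-package: each
iteration appends one shadow copy of every undecided feature (values
independently permuted), scores real + shadow features with a pluggable
importance function, and counts a *hit* for a real feature whose
importance strictly exceeds the maximum shadow importance.  After each
iteration, a two-sided exact binomial test of the hit count against
Binomial(iterations, ½), Bonferroni-corrected over the *full original
feature set*, confirms (upper tail) or rejects (lower tail) at level α
(default 0.01, the conventional Boruta level); undecided features at
`max_iter` (default 30) are tentative.  The Bonferroni divisor is kept
at the original feature count throughout the run: the tested family is
every feature that entered, and letting the divisor shrink as features
get decided loosens exactly the late decisions made when the shadow
pool has dwindled — simulations at the study's panel size show that
variant confirms chance-associated features in ~8–10% of null runs,
versus ≤5% with the constant divisor.  The default importance backend
is impurity importance from 25 extremely randomized trees
(`ExtraTreesClassifier`, `max_features="sqrt"`), seeded from the Boruta
iteration RNG.  Twenty-five trees is deliberately small: on ~50-patient,
~100-feature panels the shadow-max comparison needs only the top of the
importance ranking, per-iteration noise is averaged by the binomial
aggregation, and the repetition scheme below averages what remains; the
tree count is a parameter for callers who want a heavier ensemble.

Selection is repeated (default 1000 runs; tests and the acceptance
script use 100 and 10 at their stated problem sizes) with independent
derived seeds; each lipid's confirmation count across runs defines the
predictive ranking.  **Stability rule:** only lipids confirmed in at
least 60% of runs are signature candidates.  This majority-support
threshold follows the stability-selection literature (selection
probability thresholds of 0.6–0.9): a genuinely predictive lipid is
confirmed in nearly every run, whereas a finite-sample accident — a null
lipid that happens to correlate with the outcome in one dataset — rarely
sustains majority support.  When no lipid reaches the threshold the
pipeline reports *no predictive signature* rather than ranking noise;
without this rule, simulations show the downstream association test is
badly anti-conservative on null panels, because direction assignment and
dichotomization are fitted on the full cohort.

**Score.**  The top-k (default 8) stable lipids are split by direction:
*higher_in_NR* if the mean fold change over non-responders exceeds that
over responders, else *lower_in_NR* (an exact tie is degenerate and
raises).  Per patient,

    score = mean(fc over higher_in_NR lipids) − mean(fc over lower_in_NR lipids)

with an empty direction group contributing 0 (logged).  Scores are
dichotomized at 0: > 0 → high, < 0 → low, exactly 0 → low with a warning
(conservative toward the responder-like class).  The high/low × R/NR
table is tested by Pearson chi-square (1 df, no continuity correction by
default; Yates available via flag); a zero margin is an error.

**Cross-validated AUC.**  Discrimination is estimated by repeated
stratified k-fold cross-validation (default 5 folds × 100 repeats): per
repeat, a shuffled stratified partition; per fold, an unpenalized
binomial (logistic) model on the selected lipids' fold changes fitted on
the training folds predicts held-out non-response probabilities; the
repeat's pooled out-of-fold predictions give one ROC AUC by the
Mann–Whitney rank formula with tie correction.  The summary is the mean
and sd over repeats.  Note the deliberate fidelity choice: by default the
lipid set is selected on the *full* cohort before cross-validation, so
the AUC inherits that selection optimism; `nested=True` re-runs
selection inside each training fold and reports a leakage-free AUC
alongside.  A degenerate single-class training fold triggers a logged
repartition (at most 10 attempts).

**Cohort comparison.**  Per lipid, a two-sided Welch t-test of fold
changes between the two treatment cohorts, reported without multiplicity
adjustment — a screening comparison mirroring how such panels are
typically displayed, not a confirmatory inference.

## Synthetic data

`gen_expression` emulates a bulk cohort with latent differentiation
states.  Defaults: 3 states × 3 signatures × 20 genes, 500 background
genes, 20 samples per state.  Per sample, state factors f ~ N(0, Σ) with
unit variance and equicorrelation −0.5 between states (the PSD boundary
for three states, giving the characteristic red/blue block structure of
the signature correlation matrix); a signature gene's log expression is
base (2.0) + 0.3·f_state + δ·1[sample's state = signature's state]
+ N(0, 0.5), with δ = 1.0.  The factor loading of 0.3 keeps shared
sample-level variation strong enough to shape the correlation blocks yet
subordinate to the δ state shift, so the state call is recoverable —
with loadings near 1 the factor noise would dominate the argmax and no
scoring method could recover the labels.  Expression is the exponential
of log expression (hence strictly positive); background genes carry
base + noise only.

`gen_lipidomics` emulates the paired panel.  Defaults match the study
design: 25 R + 23 NR patients, 78 lipids, 4 up- plus 4 down-effect
species, baseline ~ LogNormal(μ=1.0, σ=0.8) (plasma-like right-skewed
concentrations), log2 fold changes ~ N(0, 0.7) for null lipids, with the
effect shift ±δ_fc applied to non-responders only (δ_fc default 1.0;
recovery tests use 1.5 as their stated condition).  The effect is
planted on the fold change, not the baseline, because the pipeline's
premise is that the *evolution* under treatment predicts resistance.
Cohort labels are split 27/21 and randomly interleaved across response
classes.

What the generators do *not* emulate: measurement batch effects,
missing values, censored/imputed concentrations, lipid-lipid metabolic
correlations, library-size artifacts, or signature genes shared between
states.  Passing recovery tests therefore demonstrates the pipeline's
correctness and calibration under its own assumptions, not performance
on real cohorts.

## Numerical and design notes

- All randomness flows from explicit seeds; repeated runs are
  bit-identical (child seeds derive from `numpy.random.SeedSequence`).
- Text round-trips of matrices use 17-significant-digit formatting and
  round-trip float parsing, so write → read is bit-exact.
- Spearman requires ≥3 samples and no constant rows (error naming the
  offending signature); enrichment correlations require ≥4 shared
  samples.
- The clustering is O(n³)-ish and intended for signature panels
  (tens of rows), not genome-scale inputs.
- Exact-zero handling is always explicit: score 0 → class "low" with a
  warning; state-feature ties → fixed priority; equal direction means →
  error.
- Problem sizes in the test suite (100 Boruta runs × 10 seeds for
  recovery, 10 runs × 40 seeds for the null, 2000 draws for statistic
  calibration) are scaled-down stand-ins for the 1000-run design,
  chosen to keep the full suite runnable on a laptop core while leaving
  the binomial decisions and support thresholds meaningful.

## Known limitations

- The per-sample enrichment statistic is not GSVA; absolute ES values
  are not comparable to GSVA scores (rank correlations are).
- The default AUC reproduces the whole-cohort-selection design and is
  optimistic; use `nested=True` for an honest generalization estimate.
- No gene-symbol alias resolution, no missing-value support, no
  GEO/TCGA retrieval; inputs must arrive in the documented formats.
- The cohort t-test table is unadjusted for multiplicity by design.
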