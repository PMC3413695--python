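# Methods

## Quantification model

Expression is measured on the threshold-cycle scale.  For patient *i*
and target gene *g*, the normalized quantity is

    ΔCt_ig = Ct_ig − Ct_i,GAPDH

under the standard assumption of ~100% amplification efficiency for all
assays, so one cycle ≈ one doubling of template and *lower* ΔCt means
*higher* relative expression.  No efficiency correction or standard
curves are applied: the pure 2^ΔΔCt model is the analysis contract.

Group-level over-expression is summarized on medians, which are robust
to the heavy tails typical of brush-specimen expression data:

    ΔΔCt_g = median ΔCt_g(benign) − median ΔCt_g(malignant)
    fold change = 2^ΔΔCt

The orientation is chosen so that fold change > 1 means over-expression
in malignancy (a marker over-expressed by 3.5 median cycles gives
2^3.5 ≈ 11-fold).  Medians use the midpoint convention for even n.

**Censoring.**  A reaction that never crosses threshold within the
40-cycle protocol is encoded as Ct = 40 with a censored flag — a
real observation of *undetectably low* expression, distinct from a
missing measurement.  Its ΔCt (40 − Ct_ref) is a lower bound on the
true ΔCt, hence rank-meaningful: censored values participate in
medians, Spearman ranks and threshold classification, but are excluded
from means, SDs and t-tests, where an imputed bound would silently bias
moment estimates.  A censored *reference* gene makes normalization
impossible; such records are rejected with an explicit reason.

**Group tests.**  ΔCt groups are compared by the Welch (unequal
variance) two-tailed t-test.  The groups' SDs genuinely differ (e.g.
2.87 vs 2.38 cycles for IGF2BP3), so pooling is not assumed; a property
test bounds the Welch-vs-pooled divergence on equal-variance data at
the cohort sizes used (mean |Δp| < 0.01 across replicates — single
replicates with mid-range p can diverge by ~0.01–0.03, which is why the
bound is on the average, not per replicate).  Within-group marker
dependence uses Spearman rank correlation (average ranks for ties,
two-sided p via the t approximation), which is invariant to the
monotone distortions that plague expression scales.

## ROC analysis and cutoff selection

Markers are over-expressed in malignancy, so positivity is
ΔCt ≤ cutoff with the cutoff *inclusive*.  Candidate cutoffs are the
observed marker values (not midpoints), which is what allows a derived
cutoff to land on observed-value precision.  The empirical AUC is
computed from mid-ranks, i.e. the Mann–Whitney concordance probability
P(diseased more positive than non-diseased) with ties counted ½; this
is exactly the trapezoidal area under the empirical ROC polygon, and a
property test asserts the identity to 1e-12 against a brute-force
pairwise oracle.  The SE uses the Hanley–McNeil formula

    Var(AUC) = [A(1−A) + (n₊−1)(Q₁−A²) + (n₋−1)(Q₂−A²)] / (n₊ n₋),
    Q₁ = A/(2−A),  Q₂ = 2A²/(1+A)

with a normal 95% CI clipped to [0, 1].  Other CI constructions
(binomial-exact, DeLong) differ at the second decimal for these sample
sizes; the Hanley–McNeil choice is conventional and documented rather
than fitted to anything.

The operating cutoff maximizes the Youden index J = sens + spec − 1
over the candidate cutoffs; ties break toward higher sensitivity
(rule-out priority in a screening context).  If no cutoff achieves
J > 0 the marker is useless at every threshold (typically an
orientation error) and the lowest candidate is returned with a warning
flag rather than a silently arbitrary "optimum".

For normal marker distributions in each class, the closed form

    AUC = Φ( (μ_benign − μ_malignant) / √(σ²_mal + σ²_ben) )

serves as the independent reference in simulation tests (0.826 for the
IGF2BP3 moments, 0.693 for NEK2).

## Panel rules and cytology integration

A panel rule fixes one ΔCt cutoff per marker and a Boolean combination:
any-one, all, or an m-of-n vote (sensitivity is non-increasing and
specificity non-decreasing in m — verified both by exhaustive truth
table and on simulated cohorts).  Routine cytology enters dichotomized:
"M only" counts only outright malignant read-outs as positive; "S&M"
adds suspicious.  Atypical, inadequate and missing cytology count as
test-negative rather than excluding the patient — this keeps the
denominators of every column at the full 72/47, matching how a
retrospective cohort with indeterminate read-outs is scored.  Missing
marker values likewise count negative with a per-patient flag
(configurable to exclusion).  Cytology combines with the gene panel as
a logical OR: a patient is positive if either component is.

## Diagnostic performance

From the 2×2 counts: sens = TP/(TP+FN), spec = TN/(TN+FP),
PPV = TP/(TP+FP), NPV = TN/(TN+FN), accuracy = (TP+TN)/n.  Predictive
values with empty denominators are *undefined*, never 0.  Binomial 95%
CIs use the Wilson score interval by default (Clopper–Pearson exact
optional); both contain the point estimate, and exact coverage is
verified ≥95% by simulation.  Predictive values at an externally stated
prevalence p follow Bayes' theorem

    PPV = sens·p / [sens·p + (1−spec)(1−p)]
    NPV = spec(1−p) / [spec(1−p) + (1−sens)p]

and agree exactly with the count ratios at the cohort's own prevalence
(a property test over random confusion matrices).  Display rounding is
half-up to one decimal on the percent scale and applied only in
dedicated display fields; stored values are unrounded.

## Synthetic cohort generator

The generator defines the study conditions under which the pipeline is
exercised: 72 malignant / 47 benign patients; per group and marker,
normal ΔCt marginals at the reported means/SDs (the only distributional
information available — the binormal AUC check shows normality is an
adequate approximation); dependence between markers via a Gaussian
copula calibrated with the exact rank relation
ρ_linear = 2·sin(π·ρ_Spearman/6), so generated data hit the reported
Spearman values (HOXB7–IGF2BP3 0.602, HOXB7–NEK2 0.259, NEK2–IGF2BP3
0.333 in malignant; 0.158/−0.086/0.273 in benign) in expectation.
FOXM1 and KIF2C correlations are unreported and default to
independence.  Reference-gene Ct is N(18, 1.5²) cycles — a typical
housekeeping abundance, documented as arbitrary since it cancels in
ΔCt.  Target Ct is reconstructed as reference + ΔCt and censored at the
40-cycle limit.  Cytology categories are drawn per group from the
reported frequencies (malignant: 12/72 positive, 19/72 suspicious,
22/72 negative, 19/72 indeterminate, split 10 atypical / 9 inadequate
by assumption; benign: 7/47 positive, 40/47 negative, with all 7 false
positives placed in "positive" — the split is unreported, and this
choice reproduces the identical 40/47 specificity of both cytology
read-outs).

Seeding is hierarchical: each (group, variable) pair draws from its own
substream derived from the master seed, so cohorts are bit-reproducible
and adding a marker never perturbs existing draws.  A correlation
matrix that is not positive semidefinite after rank-to-linear
conversion raises by default; an explicit `repair=True` projects onto
the nearest PSD correlation matrix.

**What the generator does not emulate.**  Cytology is drawn
independently of marker values within group, whereas in real patients
cytologic and molecular false calls are likely dependent; joint
information is not available.  Real ΔCt marginals need not be normal,
derived cutoffs resample around the reported ones rather than equalling
them, and no PCR-efficiency variation, technical replicates or
batch effects are simulated.  Passing tests therefore demonstrate the
*statistical consistency* of the method with the reported group-level
structure — not a patient-level reproduction, which would require the
undeposited raw data.

## Problem sizes and numerical choices

Simulation-based tests use cohorts at the study size (n = 119) with
100–200 seeded replicates, parameter-recovery checks at 100 000
patients per group, and AUC-consistency checks at 100 000 draws per
class — sizes at which the sampling tolerances asserted (±0.03 cycles
on moments, ±0.01 on Spearman, ±0.02 on AUC) follow from normal theory
with wide margins.  All randomness flows from explicit seeds; reports
and cohorts are deterministic given seed and configuration.  Degenerate
inputs (zero SDs, constant marker columns, single-class labels, empty
groups, boundary prevalences) return defined values where a definition
exists and explicit errors or undefined flags where it does not.

## Known limitations

Confidence intervals for the AUC and the proportions are asymptotic
or score-based choices among several defensible constructions; ΔCt
censoring is handled by rank-conservative inclusion rather than a
parametric censoring model; the m-of-n rule space is Boolean by design
(no weighted or logistic combination); and the generator's independence
assumptions above bound what synthetic agreement can show about real
cohorts.
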