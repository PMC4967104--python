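# Methods

## The problem

In Linda-style probability-judgment tasks, participants estimate the
probability of single statements (T: "Linda is a bank teller", F: "Linda is
active in the feminist movement") and of compounds built from them (T ∧ F,
T ∨ F). Probability theory requires P(A ∧ B) ≤ min(P(A), P(B)) and
P(A ∨ B) ≥ max(P(A), P(B)). Violations are graded: a *single* fallacy
places the compound between the constituents, a *double* fallacy beyond
both, *zero* neither. The package classifies estimates into these classes,
stratifies constituent pairs by likelihood type (Unlikely ∧ Unlikely,
Likely ∧ Unlikely, Likely ∧ Likely, or *intermediate* when a constituent
sits exactly at 0.5), and tests mechanistic accounts of the violations.

## Fallacy taxonomy

`classify_compound` implements, for conjunctions: p_c ≤ min → zero,
min < p_c ≤ max → single, p_c > max → double, mirrored for disjunctions.
The classes are exhaustive and mutually exclusive over [0,1]³ and symmetric
in the two constituents. Exact equality with a constituent resolves toward
the less fallacious class under the default `strict` tie policy (equality
is not evidence of a violation); a `tie_class` policy returns an explicit
TIE class so tie sensitivity can be reported. The likelihood boundary
follows the convention under which 0 counts as unlikely, 1 as likely, and
exactly 0.5 as "no difference": it is the only rule that assigns every
estimate a unique class, and it is applied uniformly to both study designs.
Intermediate-type responses are excluded from type-stratified counts (a
0.5 constituent gives the pair no discriminable likelihood structure) but
retained in overall tallies. Fallacy percentages are per *response* (two
compounds per participant), not per participant.

## The equate-to-differentiate model

ETD assumes a judge comparing two alternatives equates all paired
dimensions except the most distinct one — the pair with the largest
absolute outcome difference — and prefers the alternative that wins on
that single pair. In this application a dimension's outcome is the
probability estimate of the corresponding component statement; the general
utility transform is taken as the identity on estimates.

*Pairing.* When two compounds each contribute two dimensions, two
one-to-one matchings exist. The implementation picks the matching that
contains the globally largest absolute difference, fixes its argmax pair
as most distinct, and equates the rest. Argmax ties are broken by
lexicographic dimension id and flagged in the audit output; when tied
maximal pairs disagree in sign the model has no discriminating dimension
and the prediction is indifference (this also covers identical outcome
lists).

*Within-compound prediction.* Comparing a compound with either constituent
shares one dimension, so the decision falls to the other constituent's
estimate; the predicted weak ordering is always larger-component ≽
compound ≽ smaller-component, identically for ∧ and ∨. ETD therefore
predicts single fallacies and never double or zero fallacies on strictly
distinct constituents.

*Scoring.* `between` mode compares the predicted compound preference
(from the participant's own four component estimates) with the observed
compound estimates; `within` mode checks the predicted ordering per
compound. Observed-preference matching is weak (≥) by default, mirroring
the model's ≽; a strict mode is available because published consistency
rates do not state which was used. A predicted indifference counts as
consistent under weak matching and requires equal observed compounds under
strict matching; with continuous estimates the case has measure zero.

## Rival models

**CWA.** The configural weighted average predicts
P̂(compound) = β·P(smaller) + (1−β)·P(larger) with β ∈ (0.5, 1) for
conjunctions and (0, 0.5) for disjunctions (open intervals enforced). Any
CWA value on distinct constituents is a strict convex combination, so the
mechanism generates single fallacies. `fit_cwa` tests the account by the
direction of standardized OLS weights: smaller constituent dominates
conjunctions, larger dominates disjunctions. The potential-surprise
framework makes the same directional prediction and is represented only by
this check; its internal formalism is out of scope.

**Signed sum.** Operationalized as a peak pattern over the UU/LU/LL
strata: zero-fallacy share peaks in UU, single in LU, double in LL. Shares
are within-stratum proportions because strata differ in size; each verdict
requires a strict maximum and ties fail (no published tie rule exists, so
the conservative reading is used).

**Misinterpretation.** Reading A ∧ B as ¬A ∧ B has probability
(1−t)·f under independence of the constituents (assumed exactly), and
exceeds the base statement precisely when t < (1−t)·f (strict). Reading
∧ as ∨ predicts compounds above both constituents. Venn-diagram options
code interpretations: C → intersection, B → disjunction, all else →
other, with D flagged as depicting ¬A ∧ B. `venn_consistency`
cross-tabulates interpretation against behavior per participant; the
option-D inequality is evaluated at each participant's own base and added
estimates for the compound their Venn task referenced.

## Inferential statistics

Chi-square statistics are uncorrected Pearson (no Yates continuity
correction — the correction would not reproduce the published values of
15.364, 0.123 and 9.730); goodness-of-fit uses a uniform expectation with
df = k−1. The two-predictor OLS reports standardized coefficients
(slope × sd(x)/sd(y)), partial correlations by residualization, and
two-sided coefficient p-values (published tables do not state sidedness;
two-sided is assumed). Percentages are rounded half-away-from-zero to one
decimal; test statistics to three decimals. Collinear predictors are
flagged and partials set to NaN; a constant response yields R² = 0 and
zero coefficients.

## Synthetic cohorts

No raw participant data for these studies was ever deposited, so cohorts
are simulated with the structure the analyses assume. Component estimates
are drawn uniformly from likelihood-class intervals — unlikely on
[0.05, 0.45], likely on [0.55, 0.95]. The intervals stay clear of 0.5 so
every draw's intended class is unambiguous; a degenerate "intermediate"
interval pins mass at exactly 0.5 to exercise the exclusion path. The
published tables give only means, medians and standard errors, so uniform
sampling within the class interval is a choice, not an inference; the
intervals are configurable per statement.

Response models and their analytic signatures: `probability_rule`
(independence: ab, a+b−ab) never commits a fallacy; `cwa` with σ = 0,
`averaging` and `etd_ordinal` (placement min + γ·(max−min), γ uniform on
(0.02, 0.98)) always commit exactly a single fallacy on distinct
components; `signed_sum` realizes the class its stratum predicts;
`random_error` adds symmetric uniform error to the normative value,
clipped to [0, 1]; `reversed` is a negative control that places compounds
outside the constituent interval and swaps the pair of compound estimates
against the ETD-predicted preference, driving between-mode consistency to
exactly zero. Gaussian CWA noise is added before clipping; clipping is
immaterial at the default σ because predictions sit well inside [0, 1].

Each participant draws from an independent substream keyed by
(master seed, participant index), so enlarging a cohort never perturbs
earlier records and identical configurations are byte-reproducible.
Group assignment is round-robin by default or block-wise under explicit
group sizes. The default Venn mixture uses the published option shares
(C 57.8 %, B 14.7 %, D 14.7 %) with the unpublished remainder split evenly
over A, E, F. The optional interpretation–behavior linkage
(C → probability rule, B → disjunctive reading, D → (1−t)·f) is a stylized
mechanism used to validate the crosstab, not an empirical claim.

What the cohorts do not emulate: within-participant response consistency
beyond the generating model, anchoring or scale-use habits (round numbers
dominate real estimate distributions), demographic covariates, and any
dependence between a participant's component estimates. Passing tests
therefore certify the pipeline's arithmetic and the models' structural
signatures, not distributional fidelity to human data.

## Problem sizes and determinism

Test and acceptance simulations use 100–500 participants — enough that the
generator signatures (100 %/0 % class rates, β recovery within ±0.05 at
σ = 0.05) are stable across seeds, chosen as desk-scale defaults. Noiseless
recovery is asserted to 1e−10; chi-square and OLS implementations are
cross-checked against direct Σ(O−E)²/E and normal-equations evaluation to
the same tolerance. All randomness flows from explicit seeds through
numpy Generators; report rendering is byte-deterministic given a report.

## Known limitations

- Participant-level results of the original studies (regression tables,
  paired-t values, the pooled and pairwise chi-squares computed from raw
  stratified counts) cannot be reproduced without the undeposited data;
  the operations exist and are oracle-tested instead.
- The between-mode ETD score presumes exactly two same-connective
  compounds per group; designs with more compounds per group would need
  the deferred multi-compound extension of the model.
- `etd_ordinal` guarantees the within-compound ordering only; its
  between-compound preference is incidental, so the 100 % consistency
  signature is asserted in within mode.
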