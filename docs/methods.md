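# Methods

This note records the modelling assumptions, parameter choices and
numerical conventions behind `trialterm`, in the spirit of a model
documentation page: enough detail that a careful reader can predict what
the code computes without reading it.

## Problem setting and labels

The unit of analysis is one registered interventional clinical study.
The outcome is binary: class 1 ("success") for studies whose overall
status is *Completed*; class 0 ("failure") for *Terminated* (stopped
prematurely) or *Withdrawn* (never enrolled). All other registry
statuses — recruiting, suspended, unknown, and so on — are non-final and
excluded before modelling, as are observational studies and patient
registries. Status strings are normalized case-insensitively with
punctuation collapsed; anything outside the 14 known registry statuses
maps to an `other` status that the filters remove, because real exports
are inconsistent.

The registration-year cutoff (default 2011) is anchored on the **study
start year**. Registries do not distinguish cleanly between
"registered" and "started" in flat exports, so the anchor field is a
deliberate choice, exposed through the column map; records with no
parseable start year are removed, since a year filter is otherwise
undefined for them. Ages given as "18 Years" / "6 Months" strings are
converted to fractional years; unparseable ages become missing rather
than errors.

## Feature construction

**Study characteristics.** Eight numeric features (enrollment, site,
arm, outcome and country counts, age limits in years), seven
categoricals (randomisation, intervention model, masking, FDA
regulation, healthy-volunteer acceptance, sex eligibility, enrollment
type), one binary indicator per observed intervention type, and one
indicator per phase. A study recorded under two phases (e.g. "Phase
2/Phase 3") sets both indicators and belongs to both phase-specific
subsets; phase-subset multiplicity is therefore conserved, not
partitioned.

**Eligibility text.** The free-text field is split at case-insensitive
"Inclusion Criteria" / "Exclusion Criteria" headers; text before any
header counts as inclusion. Within a section, criteria are segmented on
newlines with leading bullet markers (`-`, `*`, `•`, `1.`, `2)`)
stripped — registries do not standardise this, so the segmentation rule
is ours. Four statistics per study: criterion counts per side, total
whitespace-delimited words, and mean words per criterion (0 when there
are no criteria).

**Search features.** An annotated corpus supplies (side, entity
category, value) rows over eight entity categories (Condition,
Procedure, Person, Temporal, Drug, Observation, Mood, Visit). Values
are normalized — lower-cased, punctuation replaced by whitespace, digits
kept — and tokenized; values longer than five tokens are dropped for
tractability, duplicates collapse, and term ids come from a
deterministic (side, category, value) sort. A term matches a study iff
its token sequence occurs **contiguously** in the normalized text of the
matching section only (inclusion terms never search exclusion text and
vice versa). Matching is token-exact, never substring — "art" cannot
match inside "heart" — and the batched matcher is verified cell-for-cell
against a naive token-window scan. No stemming or synonym expansion: the
annotated values are taken literally. Terms identical across sides are
two distinct features, since side is part of a term's identity.

**Disease categories.** Conditions and MeSH terms are matched against a
category lexicon with the same n-gram convention, but n-grams are built
*within* each condition/MeSH item, so two adjacent items can never
splice into a spurious multi-word match. Categories are multi-label by
design. The genuine registry category list is not redistributable; the
package ships a small illustrative lexicon and accepts any
`{category: [terms]}` JSON.

## Encoding

**Imputation.** Numeric features are completed with a single-imputation
chained-equations procedure: missing cells start at column means, then
features are revisited — most-missing first, ties alphabetical — and
each feature's originally-missing cells are overwritten by a ridge
regression (α = 1e-3) on all other features, fitted on rows where the
feature is observed. Iteration stops when the largest imputed-cell
change, divided by the feature's observed standard deviation, drops
below `tol = 1e-3`, or after `max_iter = 30` sweeps. The cap is 30, not
the 10 customary in multiple-imputation software, because this is a
*convergent single imputation*: with strongly correlated predictors and
rows missing several features, the fixed-point updates contract
geometrically at roughly 0.8 per sweep, and tol = 1e-3 is first reached
near sweep 30. Imputations are clamped to the observed range by default;
observed cells are never modified; no posterior noise is drawn, so the
procedure is exactly reproducible. Test-time tables are completed in a
single pass through the stored train-time predictors — no refitting, no
leakage. A feature with no observed training values is an error, not a
guess.

**Categoricals.** One binary column per (feature, level) seen in
training. Missing values encode as an all-zero block, and a level never
seen in training is treated the same way — the natural extension of the
missing-as-zeros convention.

## Split, rebalance, select

Order matters and is fixed: split → undersample → score → select.
The 70:30 split is stratified (keeping the ~15:85 failure:success mix in
both partitions) and seeded. Undersampling deletes majority-class
**training** rows uniformly at random until the classes are exactly 1:1;
every minority row is kept and the test partition is untouched, so test
metrics reflect the realistic imbalanced distribution.

Features are scored on the undersampled training data with the one-way
ANOVA F statistic (for a binary target, identically the squared
equal-variance two-sample t statistic — this identity is the test
oracle). Zero-variance columns get an undefined score and rank last;
ties break by ascending column name so selection is deterministic and
nested in k. The feature count k comes from an ablation curve (error vs
k): both axes are min-max normalized and the interior grid point
furthest from the chord joining the endpoints is the elbow, ties (within
1e-12, which absorbs float noise on exactly linear curves) going to the
smallest k.

## Models, evaluation, comparison

Three families, all consuming sparse matrices and seeded: logistic
regression, random forest, and extreme gradient boosting (the reference
model; default depth 4, 200 trees, learning rate 0.1). Evaluation is
fivefold stratified cross-validation with undersampling redrawn inside
each training fold, reporting per-fold values and means of: ROC-AUC,
balanced accuracy (mean of the two class recalls — by construction
always their mean, which the report type enforces), F1 with the failure
class as positive (the clinically interesting class), and per-class
accuracies. The classification threshold is 0.5 throughout.

Hyperparameter search is two-staged: first model complexity (max depth ×
minimum child weight), then, with stage-1 winners fixed, randomness (row
and column subsampling). Ties keep the smaller-complexity
configuration.

Two models sharing a test set are compared with McNemar's test on the
2×2 paired-correctness table (a both-correct, b only-model-1, c
only-model-2, d both-wrong). The default statistic applies the
continuity correction, χ² = (|b−c|−1)²/(b+c); the uncorrected variant
(b−c)²/(b+c) is exposed as an option. On the published worked example
(b = 1,642, c = 2,261) the corrected statistic is 97.85 with p =
4.50e-23; the uncorrected one is 98.17. One degree of freedom, α = 0.01,
upper-tail p. If the models never disagree the test is degenerate and
raises rather than returning a fake zero.

## Attribution and flagging

Per-prediction Shapley values are computed for the tree ensemble in
**margin (log-odds) space** under the interventional convention: the
value of a coalition S is the model margin with features in S taken from
the instance and the rest from a background row, averaged over a seeded
background subsample (default 200 training rows). For trees this is
computed exactly by path recursion — wherever the instance and the
background row part ways at a split, both coalition assignments are
explored and each reached leaf contributes closed-form weights
±|A|-dependent factorials — and, by linearity of the Shapley value,
averaging per-row attributions equals attributing the averaged game.
The implementation is verified against full 2^d coalition enumeration
(shipped as `exact_shapley_oracle`, guarded to d ≤ 12) to 1e-6, and
satisfies local accuracy — base value plus contributions equals the
margin — to machine precision against the parsed trees' float64 margin.
Two numerical details matter: inputs are rounded through float32 before
routing, and thresholds parsed from the booster dump are cast back to
float32, because the booster compares in single precision and a
double-precision comparison can flip a branch for values lying exactly
on a threshold. The booster's own reported margin agrees with the
float64 tree margin to ~1e-6 (its accumulation is single-precision).

Positive contributions push toward success (class 1), negative toward
failure. A protocol is flagged when its predicted **success**
probability falls below the threshold — the wording "termination
probability below a threshold" appears in registry-prediction
discussions but is the same trigger with the complementary quantity, and
the success-probability form is the one used consistently here. Flagged
reports attach the top-8 contributors by absolute value,
failure-direction entries first, plus a plain-text narrative.

## Synthetic registry generator

The generator is the package's test bed and defines its study
conditions. It emulates: a 15:85 failure:success imbalance (intercept
calibrated by bisection on the empirical rate, to ±2 points at n =
5,000); log-normal enrollment, Poisson site/arm/outcome/country counts;
a phase mix loosely following the registry's published phase table
including two-phase studies; eligibility text with proper headers,
bulleted criteria and embedded corpus terms; an annotated term corpus
across all eight categories and both sides with token counts 1–6 (some
deliberately exceeding the 5-token filter); conditions/MeSH terms drawn
from the lexicon; MCAR missingness at per-field rates (3–20%); and a
sprinkling of records the filters must remove (observational studies,
non-final statuses, pre-cutoff years, ~5% each).

Labels are drawn from a logistic model over standardized
characteristics, disease-category indicators and ten planted
exclusion-side Condition terms with coefficient −1.6 at ~30% prevalence
— strong enough that eligibility features genuinely carry signal beyond
the characteristics, which is the construction the feature-set
comparison needs. All coefficients, the intercept and per-record linear
predictors are returned as ground truth, so recovery tests are sharp.
Setting every coefficient scale to zero yields the null mechanism used
as a negative control (cross-validated balanced accuracy ≈ 0.5).

What the generator does **not** emulate: real marginal distributions of
any registry field beyond plausible shape, MAR/MNAR missingness,
temporal drift, free-text realism beyond header/bullet structure, or
correlation between eligibility wording and characteristics. Passing
tests therefore demonstrate correctness of the machinery and
recoverability of planted signal under known conditions — not clinical
performance on real registry data, which depends on the full external
extracts.

## Problem sizes

The test suite and the reproduction script run at desk scale, chosen so
the full suite completes in well under a minute of compute per heavy
case: 300–5,000 synthetic records end to end, 50 documents × 100 terms
for the matcher-equivalence check, d ≤ 12 features for Shapley
enumeration, n = 1,000 with 20% MCAR for the imputation comparison. The
headline metric tables of full-registry analyses (hundreds of thousands
of studies, ~12,864 search features) require the external registry and
corpus extracts and are deliberately out of scope.

## Known limitations

- The category lexicon shipped is illustrative, not the registry's
  official condition taxonomy; users should supply their own.
- Imputation is a convergent single imputation: no between-imputation
  variance, no Rubin pooling, no predictive-mean matching.
- Attribution is margin-space only; probability-space attributions
  would require a different (non-additive) decomposition.
- The flagging loop is human-in-the-loop by design: the package flags
  contributors, it does not rewrite protocols.
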