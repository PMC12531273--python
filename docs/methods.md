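# Methods

`cohortcapture` estimates the total size of a disease cohort whose members
are scattered across many partially overlapping clinical databases, none of
which is complete on its own. The motivating setting is inflammatory bowel
disease (IBD) in a single secondary-care institution, where the cohort is
spread over eleven databases — diagnostic (ICD-10) and surgical (OPCS-4)
billing codes, two clinician-curated registries, event databases
(prescriptions, flare-line calls, clinic appointments, fecal calprotectin
results) and three free-text sources (clinic letters, endoscopy reports,
histopathology reports) — but the machinery is disease-agnostic.

## The capture-recapture protocol

Each database contributes a *flagged* set: patients it marks as suspected
of having the disease. Against a chart-reviewed gold standard, each
database also has a measured precision (PPV). The protocol integrates the
flagged sets in order of decreasing precision, starting from a designated
primary database (billing codes):

1. Initialize the running "Combined" set with the primary database's
   flagged set; the base true-positive (TP) estimate is
   round(|flagged| × precision).
2. For each remaining database B, in precision-descending order (ties keep
   the declared order): compute the Jaccard index
   J = |Combined ∩ B| / |Combined ∪ B| (reported to 3 d.p.), take the
   patients unique to B (|B| − |Combined ∩ B|), add
   round(unique × precision_B) to the cumulative TP estimate, and absorb
   B into the Combined set.
3. Repeat until no databases remain.

Two invariants define the bookkeeping: the Combined set tracks *flagged*
patients (so overlaps are computed on raw flags), while the cumulative
total tracks precision-discounted TPs; consequently cumulative TP ≤
|Combined| at every step. All integer rounding is half away from zero.

The method's key assumption is that a database's precision is the same for
patients it shares with the running union and for patients unique to it.
In practice unique strata are less precise (easy, multi-database cases are
over-represented wherever databases agree), so the protocol overestimates
— it is an upper estimate. The test suite reproduces this empirically: with
precisions measured on an enriched multi-database gold standard, the
set-based estimate exceeds the true flagged-positive count of the synthetic
population. No correction is attempted; a complementary *lower* estimate
comes from the penalized classifier below (missing-as-zero imputation makes
it conservative), and a combined estimate adds the unaccounted-for unique
TPs of selected databases to the classifier's confident predictions.

Two execution modes exist: `set_based` (actual patient-id sets; overlaps
exact, equal to brute-force enumeration by construction and by test) and
`summary_replay` (printed flagged/intersection/precision rows from a
published table). Replay consumes printed intersection counts directly
rather than re-deriving them from 3-d.p. Jaccard values, which would
introduce ±1 rounding errors.

## Per-database validation metrics

Accuracy, precision, NPV, recall, specificity and F1 are computed from the
confusion table of each database's flags against the gold standard, with
95% percentile-bootstrap intervals over patient-level resamples (default
1000 replicates, seeded). Zero-denominator cells — common for registry
databases that flag every member, leaving no flagged-negative patients —
are reported as 0 with a structured `DegenerateCellWarning` rather than
NaN, matching clinical-table convention. BCa corrections are not used; the
percentile interval is the stated method. Databases are ranked by precision
(stable ties) because PPV drives the integration order of the protocol.

## Text flagging

Free text is screened in two stages. First, synonym normalization rewrites
surface forms ("UC", "crohns", "IBD-U", …) to one of five normalized terms
(Ulcerative Colitis, Crohn's Disease, IBD, Inflammatory Bowel Disease,
Proctitis) via a longest-match-first, case-insensitive alternation; the
normalized terms participate as fixed points, making the operation
idempotent. A licensed meta-thesaurus cannot be bundled, so the package
ships a small abbreviation dictionary with a hook for a user-supplied
thesaurus file. Second, five case-insensitive substring patterns flag a
document: `olitis`, `rohn`, `octitis`, `flammatory bowel disease`, `ibd`.
No word boundaries are added: `olitis` deliberately matches every colitis
(ischemic, diverticular, infective …), trading precision for screening
recall; this over-match is a designed, tested property, and the confounder
templates in the synthetic generator exercise it. Whether `ibd` should be
word-bounded is genuinely open (it also matches inside longer words); the
default matches the bare substring, with `ibd_word_boundary=True` as a
config switch. A patient is flagged for a document source if *any* of
their documents of that type is flagged; patients with no documents score
0 (missing-as-zero).

## Sample-size calculator

The minimum gold-standard size for developing the classifier follows the
binary-outcome criterion N = K / (p(1−p) · S · ln(1−R²)), with K candidate
predictors, outcome prevalence p, target shrinkage S and anticipated
Cox–Snell R². ln(1−R²) is negative, so the magnitude is taken and rounded
up. K enters directly (the "effective" numerator is taken equal to the
number of candidate predictors — an interpretation, since the source
formulation is ambiguous, that reproduces the reference result). At the
defaults (K=11, p=0.165, S=0.9, R²=0.05) the calculator returns 1730
patients, splitting 519/1211 at a 30% holdout.

## Penalized classifier

A logistic regression over the eleven binary flags with a 50:50 elastic-net
penalty. Demographic columns (age, sex, ethnicity, IMD, referral year) are
excluded by name pattern: they are audit variables, not predictors, and
including them is known to worsen calibration in this setting without
fixing bias. λ follows the glmnet convention (objective
(1/n)Σ logloss + λ[α‖β‖₁ + (1−α)/2 ‖β‖²]), mapped to scikit-learn's SAGA
solver as C = 1/(nλ). Because the intercept is unpenalized but SAGA can
declare convergence at extreme λ without moving it, the intercept is
profiled out after each fit by a monotone 1-D root solve — at the optimum
this is a no-op, in the full-shrinkage limit it restores the base-rate
logit.

λ is selected by nested cross-validation (10-fold inner, 10-fold outer;
outer repeats default to 5 at desk scale, with the 100-repeat setting a
config change that only smooths the outer AUROC distribution) using the
one-standard-error rule on inner-fold AUROC: the most-regularized λ whose
mean inner AUROC is within one SE of the best. Scaling statistics are
learned inside training folds only (z-scores; constant columns are kept
with unit scale and zero weight plus a warning). Platt recalibration —
σ(a·logit(p) + b) — is fitted exclusively on out-of-fold scores.
Discrimination is summarized by AUROC and the Brier score before/after
recalibration; calibration by three views: a binned
predicted-vs-observed curve, a LOWESS smooth, and a logistic recalibration
fit whose slope/intercept are (1, 0) for a calibrated model. Threshold
sweeps report precision/recall/accuracy with bootstrap CIs on the labeled
validation set, the count of population patients above each threshold, and
the projected TP total round(count × precision); bootstrap resampling uses
the labeled set only, rescaling population counts by the resampled flag
rate so the paired intervals share resamples. Threshold selection offers
max-F1 and Youden's J (plus a fixed override); neither is claimed
canonical.

## Fairness audit

AUROC is recomputed within each level of sex, ethnicity, decadal age band
and IMD band (deciles collapsed to quintiles by default; band edges are
configurable since no canonical boundaries exist). Groups below a minimum
size (default 30) are flagged underpowered rather than dropped; one-class
groups get an explicit "undefined" note. The per-attribute maximum pairwise
gap is the headline number. The audit measures disparity; it does not
attempt mitigation.

## Synthetic data generator

The generator emulates the study conditions the pipeline assumes, at the
reference scale by default: 37,947 referral patients (2007–2023), disease
prevalence 0.344 (the ratio of the combined cohort estimate to the
referral population), demographics matched to reported marginals (mean age
51.79 truncated-normal with SD 24 at ≥18 years, 60.27% female, 85.04%
white ethnicity, IMD deciles linearly tilted to mean 5.91 — fields sampled
independently, as only marginals are reported). Each database flags a
patient if covered (per-database coverage) and then with
sensitivity/false-positive-rate depending on disease status; registries
flag every diseased member. False-positive rates are derived from target
precisions via PPV = πse/(πse + (1−π)fpr), so empirical per-column
precision converges to the published per-database values. Missing records
are encoded 0, never null.

The gold standard samples only patients flagged in ≥2 databases
(reproducing the validation-cohort sampling restriction), stratified to
75% label prevalence, with a seeded 30% validation split; labels copy true
disease status (chart review assumed perfect). This restriction is what
induces the *edge-node* effect the audit tests for: single-database true
positives receive systematically lower model probabilities. Template
documents carry normalized terms, raw abbreviations (exercising the
normalizer) or confounder colitides concentrated in clinic letters (so
letter precision lands below endoscopy precision, as observed in
practice).

What the generator does *not* emulate: longitudinal visit streams,
referral-pathway exclusions, realistic clinical prose, correlated
demographics, label noise in chart review, or inter-database dependence
beyond the shared disease status. Flags are conditionally independent
given disease status, which makes the synthetic classification task easier
than the real one (near-perfect AUROC at default settings); passing tests
therefore demonstrate correctness of the machinery and directional
reproduction of the documented biases, not real-data performance levels.

## Numerical conventions and problem sizes

Counts round half away from zero; Jaccard indices print at 3 d.p.
(half-up); missed-cohort fractions at 1 d.p. Bootstrap and CV seeds are
explicit everywhere; two runs of any stage with the same seed and config
are byte-identical (reports embed the seed and a config hash). Tests run
the generator at 6,000–12,000 patients and nested CV at reduced
fold/repeat/grid settings; these are validation scales chosen for tight
feedback loops — the estimators are identical at full scale, and the CLI
defaults expose the reference sizes.
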