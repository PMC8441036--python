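# Methods

## Scoring model

An attempt at a CVC target is scored by articulatory-feature agreement,
slot by slot. Consonants carry three features — voicing
(voiced/voiceless), place (bilabial, labio-dental, dental, alveolar,
palatal, velar, glottal) and manner (stop, fricative, affricate, nasal,
liquid, glide) — and vowels four: height (low/mid/high), advancement
(front/central/back), rounding, tenseness. Each matching feature earns
1 point, so the raw score ranges 0–10 (3 + 4 + 3). Features are defined
only within a phoneme class, so a wrong-class production in a slot (or
an omission) scores that slot 0; inserted phonemes neither add nor
subtract points, keeping the 10-point ceiling fixed.

The packaged feature table covers a General-American inventory in
ARPAbet-style symbols with an IPA mapping. Only a handful of rows are
pinned down by the scoring conventions themselves (e.g. /ae/ low front
unrounded lax; the *cake* vowel mid front unrounded tense; /k/–/t/
agreeing on voicing and manner but not place); the remainder follows
standard clinical phonetics — /w/ a bilabial glide, /r/ and /l/
liquids, affricates single phonemes, diphthongs assigned their nucleus
features. The table is data (`data/feature_table.tsv`) and can be
replaced by the user with any file of the same layout; it is a
documented convention, not a finding.

**Alignment.** Productions rarely arrive as neat CVC strings. The
aligner is greedy first-match: consonants before the first vowel
compete for C1 (first wins), the first vowel takes V, the first
consonant after it takes C2, everything else becomes unscored extras.
Two consequences worth knowing: removing an *extra* phoneme never
changes a score, but removing an *aligned* one can re-align the rest
and occasionally raise the total (a vowel-initial error production can
shield a later consonant from the C1 slot). No global monotonicity in
production length holds, and none is claimed.

**Pass rules.** An attempt passes at raw score ≥ 6 with a fully
correct initial consonant (all three C1 features; with purely
within-class comparison this is equivalent to producing the target
phoneme itself). Both the threshold and the initial-consonant gate are
configurable (`ScoringConfig`). A word is passed in a session on 2-of-3
attempts — generalized to ceil(2k/3) for k attempts — and a set is
mastered at 3-of-5 words.

## Derived variables

Predictors come from the week-4 probe (the session whose intervention
week index is 4, regardless of active set; absent means error, never
substitution): total phonemic score / trials (`ps_tw4`, 0–10) and words
passed / trials (`wp_tw4`). Outcomes: per-trial phonemic score and
words passed of the *best* post-week-4 session of the outcome set — the
first set probed after week 4 — each maximized under its own criterion
with ties to the earliest week (`ps_ts2`, `wp_ts2`), and average words
passed per post-week-4 week (`wp_wasw`), whose denominator is the count
of observed post-week-4 probe weeks unless a total-weeks integer is
supplied.

The words-passed-per-trial metrics have two denominations because the
two are in genuine tension: dividing *distinct words passed* by trials
matches the canonical worked value (5 words / 15 trials = .33) but is
capped at 1/3, while dividing *passing trials* by trials is the
definition bounded by 1.0. The primary definition is distinct-words;
the trials-denominated variant sits behind
`DerivationConfig(words_passed_definition="trials")` and carries the
1.0-bound property.

## Statistics

*ICC.* Two-way random-effects absolute-agreement coefficients in the
McGraw–Wong mean-squares formulation (equivalent to Shrout–Fleiss
ICC(2,1)/(2,k)), computed directly from the row/column/error mean
squares of the complete items × raters matrix. The error sum of squares
is clamped at zero so perfect agreement returns exactly 1.0 despite
floating-point cancellation; a matrix with no variance at all returns
NaN with `defined=False` rather than a misleading number. Tests verify
against both a naively-summed oracle (1e-10) and pingouin.

*Hierarchical regression.* All variables are z-scored (ddof=1) before
fitting, so coefficients are standardized βs; models are fit per
cumulative block via OLS (statsmodels). The increment test is
ΔF = (ΔR²/p_added) / ((1−R²_full)/(n−k_full−1)) with the full model's
residual df. Part correlations are signed square roots of the R² drop
when the predictor alone is removed from its containing model, the sign
taken from its coefficient. Missing values are dropped listwise within
each analysis. Note that the sum of squared part correlations may
*exceed* R² under suppression; only the per-predictor bound
part² ≤ R² is an invariant.

*p-values* use classical t and F reference distributions; no
multiple-testing correction is applied, matching ordinary practice for
this design.

## Synthetic cohort generator

The generator exists so every pipeline stage and the inference code are
exercisable end-to-end. It emulates the probe protocol (5 words × 3
presentations; weekly probes; advancement on mastery or after 4 weeks)
for a default cohort of 23 participants over 4 word sets.

Each participant has a latent ability a ~ Normal(0, 1). At week w the
operative skill is `ability_slope·a + learning_rate·(w−1)`
(defaults 1.0 and 0.1 logits). Generation is *feature-level*: given an
attempt, each target feature is realized correctly with probability
sigmoid(intercept + skill − difficulty), with per-feature difficulty
offsets (place hardest at 0.6; rounding and voicing free at 0). The
produced phoneme is then drawn from the same-class inventory phonemes
whose feature agreement with the target matches the realized pattern
(nearest pattern when the exact one is phonotactically unrealizable).
Feature-level generation makes the phonemic score the natural
sufficient statistic for ability — the premise under study. Two
thresholding processes create the floor in the pass-based measures:
whole-trial non-response with probability sigmoid(−1.2 − 0.8·skill),
and final-consonant omission with probability sigmoid(−0.3 − 0.8·a).
The Vineland adaptive-behavior covariate is a noisy linear transform of
ability onto a 55/9.4 scale with correlation 0.3, matching the level
and weak coupling typical of this population.

Slope and intercept defaults were fixed once by a small calibration
sweep against the qualitative structure the generator is required to
reproduce — a majority-zero week-4 words-passed distribution alongside
a graded phonemic score, and the phonemic score carrying the unique
outcome variance — and are not tuned per analysis. Participants who
master all four sets before week 5 have no outcome window and are
dropped from derived tables with a log message (a realistic
missing-data mechanism; at the defaults this affects roughly one
participant per cohort).

What the generator does **not** emulate: transcription ambiguity and
consensus coding, within-child week-to-week dependence beyond a linear
learning trend, word-specific difficulty, set-ordering effects, and any
calibration to the clinical cohort's published moments. Passing tests
therefore demonstrate the pipeline's correctness and the *direction* of
its statistical behavior, not clinical effect sizes.

## Problem sizes

The test suite runs cohorts of 6–200 participants; the structure check
uses 50 seeded cohorts of 23. Oracle comparisons use 100 random
matrices/fixtures; parameter recovery uses n = 10 000 with 200 null
replicates. The full suite completes in well under a minute on one CPU.

## Known limitations

- The feature table is one defensible General-American convention;
  dialectal or clinical alternatives change scores and should be passed
  in as an override table rather than edited in place.
- Alignment is positional and greedy; it does not attempt
  edit-distance or phonetically weighted alignment, so heavy insertions
  can shadow a later, better-matching consonant.
- The inference layer is strictly cross-sectional OLS on derived
  variables — no mixed-effects or growth modeling.
- ICC assumes a complete ratings matrix; incomplete designs are
  rejected rather than approximated.
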