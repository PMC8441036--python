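# cvcscore

Phonemic feature scoring of CVC word attempts, probe-session metrics, and
the reliability and regression analyses used to study early word learning
in minimally verbal children with autism.

## The problem

Minimally verbal children (fewer than ~40 words, no word combinations,
past age 5) make gains during speech intervention that binary
"said the word / didn't" measures miss entirely: a child who says /dae/
for *cake* has produced two of four vowel features and the right manner of
articulation, yet scores the same zero as a child who said nothing.
`cvcscore` implements a graded articulatory-feature score for attempts at
consonant–vowel–consonant (CVC) target words, the weekly-probe
aggregation rules built on it, and the statistics that ask whether early
phonemic approximation predicts later word learning better than early
word passes do.

## The score

For a CVC target, each slot is compared feature-by-feature with the
production, 1 point per match:

| slot | features | max |
|------|----------|-----|
| C1 (initial consonant) | voicing, place, manner | 3 |
| V (vowel) | height, advancement, rounding, tenseness | 4 |
| C2 (final consonant) | voicing, place, manner | 3 |

giving a raw total of 0–10. An omitted or wrong-class slot scores 0. An
attempt **passes** when the total is ≥ 6 *and* the initial consonant is
fully correct. At the session level a word is passed on 2-of-3 attempts,
and a 5-word set is mastered at 3-of-5 words. From scored sessions the
package derives the standard predictor/outcome variables: week-4 phonemic
score per trial and words passed per trial (predictors), and the best
post-week-4 set's phonemic score and words passed per trial plus average
words passed per subsequent week (outcomes).

The statistics layer provides two-way random-effects absolute-agreement
ICC — ICC(A,1)/ICC(A,k) — for rater reliability, pairwise Pearson
correlations, and blockwise hierarchical OLS with ΔR², ΔF, standardized
β and part (semipartial) correlations. A synthetic cohort generator
produces trial-level data from a latent-ability model so the entire
pipeline is testable without clinical recordings.

## Worked example

```python
from cvcscore import default_inventory, default_word_list, score_attempt

inventory = default_inventory()
words = default_word_list()
production = inventory.parse_transcription("/baek/", notation="ipa")
score = score_attempt(words["bat"], production, inventory)
print(score.raw_total, score.c2.credits, score.passed)
```

prints

```
9 {'voicing': 1, 'place': 0, 'manner': 1} True
```

— /baek/ for *bat* earns the full 3 for /b/ and 4 for /ae/, and 2 of 3
for /k/ in place of /t/ (both voiceless stops; velar vs alveolar place
differs), a 9/10 passing attempt. Scoring /dae/ against *cake* instead
gives 3/10 and no pass: 1 point for manner at C1 (/d/ and /k/ are both
stops), 2 for the vowel (front, unrounded shared), 0 for the omitted
final consonant.

The `examples/` scripts walk through each capability — attempt scoring,
session aggregation, rater reliability, hierarchical regression, and a
full synthetic-cohort analysis:

```sh
python examples/05_synthetic_cohort_analysis.py
```

A thin CLI mirrors the pipeline stages (`cvcscore score | sessions |
derive | analyze | simulate`); see `cvcscore --help`.

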