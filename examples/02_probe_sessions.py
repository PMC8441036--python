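"""Aggregate a weekly probe session into pass/mastery metrics.

A weekly probe presents each of the active set's 5 words 3 times
(15 trials).  A word is passed when 2 of its 3 attempts pass; the set
is mastered — triggering advancement — when 3 of the 5 words pass.
"""

from cvcscore import (
    ProbeSession,
    TrialRecord,
    compute_session_metrics,
    default_inventory,
    default_word_list,
    score_attempt,
)

inventory = default_inventory()
words = default_word_list()

# productions for one child's week-4 probe of set 1: 'bat' and 'cake'
# approximated well twice, 'dog' twice, 'fish' once, 'cup' never attempted
productions = {
    "bat": ["B AE K", "B AE T", ""],
    "cake": ["K EY", "G EY K", "K EY K"],
    "dog": ["D AO G", "D AO", "D AO G"],
    "fish": ["F IH SH", "", ""],
    "cup": ["", "", ""],
}

records = []
for word, attempts in productions.items():
    for text in attempts:
        production = inventory.parse_transcription(text)
        records.append(
            TrialRecord(word, production.symbols,
                        score_attempt(words[word], production, inventory))
        )
session = ProbeSession("P01", week=4, word_set="set1", trials=tuple(records))
m = compute_session_metrics(session)

print(f"total phonemic score: {m.total_phonemic_score} over {m.n_trials} trials")
print(f"phonemic score per trial: {m.phonemic_score_per_trial:.2f}  (0-10 scale)")
print(f"words passed (2-of-3 rule): {m.words_passed} of {m.n_words}")
print(f"words passed per trial: {m.words_passed_per_trial:.2f}")
print(f"set mastered (3-of-5 words): {m.set_mastered}")
print()
print("The per-trial phonemic score is the graded predictor; words passed is")
print("the thresholded one — the same session can be floored on passes while")
print("still showing measurable phonemic progress.")
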