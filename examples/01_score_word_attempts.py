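"""Score single word attempts against CVC targets.

A child's production earns 1 point per articulatory feature shared with
the target phoneme in each slot: 3 points for the initial consonant
(voicing, place, manner), 4 for the vowel (height, advancement,
rounding, tenseness), 3 for the final consonant — a 0-10 scale that
credits close approximations, not just whole-word accuracy.
"""

from cvcscore import default_inventory, default_word_list, score_attempt

inventory = default_inventory()
words = default_word_list()

for word, transcription in [("bat", "/baek/"), ("cake", "/dae/"), ("bat", "/baet/")]:
    production = inventory.parse_transcription(transcription, notation="ipa")
    score = score_attempt(words[word], production, inventory)
    print(f"target '{word}' {words[word]}, produced {transcription}:")
    for slot in score.slot_scores:
        earned = [name for name, credit in slot.credits.items() if credit]
        print(f"  {slot.slot}: {slot.subtotal} point(s) for {', '.join(earned) or 'nothing'}")
    print(f"  raw total {score.raw_total}/10, initial consonant correct: "
          f"{score.initial_consonant_correct}, passing attempt: {score.passed}")
    print()

print("An attempt passes when it scores at least 6 AND the initial consonant")
print("is fully correct — so /baek/ for 'bat' (9) passes while /dae/ for 'cake' (3) does not.")
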