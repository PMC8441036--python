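"""Phonemic feature scoring of one word attempt against a CVC target.

Each attempt earns 1 point per articulatory feature shared with the
target phoneme in each slot: up to 3 points for the initial consonant
(voicing, place, manner), 4 for the vowel (height, advancement,
rounding, tenseness) and 3 for the final consonant, for a raw total of
0-10.  An omitted or wrong-class slot scores 0 — features are defined
only within a phoneme class, so no cross-class credit is given.  An
attempt passes when the raw total reaches the threshold (default 6)
and the initial consonant is fully correct (all three C1 features).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .inventory import (
    CONSONANT_FEATURE_NAMES,
    VOWEL_FEATURE_NAMES,
    AlignedProduction,
    FeatureInventory,
    PhonemeSequence,
)

C1_MAX = 3
V_MAX = 4
C2_MAX = 3
MAX_RAW_SCORE = C1_MAX + V_MAX + C2_MAX


class NonCvcTargetError(ValueError):
    """The target does not decompose into consonant-vowel-consonant."""


@dataclass(frozen=True)
class ScoringConfig:
    """Pass rule parameters: score threshold and the initial-consonant gate."""

    pass_threshold: int = 6
    require_initial_consonant: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.pass_threshold <= MAX_RAW_SCORE:
            raise ValueError("pass_threshold must be in [0, 10]")


@dataclass(frozen=True)
class SlotScore:
    """Per-feature credit for one scoring slot (C1, V or C2)."""

    slot: str
    credits: dict[str, int] = field(compare=False)
    subtotal: int = field(init=False, compare=True)

    def __post_init__(self) -> None:
        object.__setattr__(self, "subtotal", sum(self.credits.values()))


@dataclass(frozen=True)
class AttemptScore:
    """Full scoring result for one trial: slot breakdown, raw total, pass flags."""

    target: tuple[str, ...]
    production: AlignedProduction
    c1: SlotScore
    v: SlotScore
    c2: SlotScore
    raw_total: int = field(init=False)
    initial_consonant_correct: bool = field(init=False)
    passed: bool = field(init=False)
    config: ScoringConfig = ScoringConfig()

    def __post_init__(self) -> None:
        total = self.c1.subtotal + self.v.subtotal + self.c2.subtotal
        ic_correct = self.c1.subtotal == C1_MAX
        passed = total >= self.config.pass_threshold and (
            ic_correct or not self.config.require_initial_consonant
        )
        object.__setattr__(self, "raw_total", total)
        object.__setattr__(self, "initial_consonant_correct", ic_correct)
        object.__setattr__(self, "passed", passed)

    @property
    def slot_scores(self) -> tuple[SlotScore, SlotScore, SlotScore]:
        return (self.c1, self.v, self.c2)


def score_consonant_slot(
    target_symbol: str,
    produced_symbol: Optional[str],
    inventory: FeatureInventory,
    slot: str = "C1",
) -> SlotScore:
    """Score one consonant slot: 1 point per matching feature, 0 on omission.

    A produced symbol of the wrong class (a vowel in a consonant slot)
    scores 0 on every feature.
    """
    target = inventory.lookup_consonant(target_symbol)
    credits = dict.fromkeys(CONSONANT_FEATURE_NAMES, 0)
    if produced_symbol is not None and inventory.is_consonant(produced_symbol):
        produced = inventory.lookup_consonant(produced_symbol)
        for name, t_val in target.as_dict().items():
            credits[name] = int(t_val == getattr(produced, name))
    return SlotScore(slot, credits)


def score_vowel_slot(
    target_symbol: str,
    produced_symbol: Optional[str],
    inventory: FeatureInventory,
) -> SlotScore:
    """Score the vowel slot: 1 point per matching feature among the four."""
    target = inventory.lookup_vowel(target_symbol)
    credits = dict.fromkeys(VOWEL_FEATURE_NAMES, 0)
    if produced_symbol is not None and inventory.is_vowel(produced_symbol):
        produced = inventory.lookup_vowel(produced_symbol)
        for name, t_val in target.as_dict().items():
            credits[name] = int(t_val == getattr(produced, name))
    return SlotScore("V", credits)


def validate_cvc_target(
    target: Iterable[str], inventory: FeatureInventory
) -> tuple[str, str, str]:
    """Check that a target decomposes into exactly C, V, C inventory symbols."""
    symbols = tuple(target)
    if len(symbols) != 3:
        raise NonCvcTargetError(f"target {symbols} is not three phonemes")
    c1, v, c2 = symbols
    if not (inventory.is_consonant(c1) and inventory.is_vowel(v) and inventory.is_consonant(c2)):
        raise NonCvcTargetError(f"target {symbols} is not consonant-vowel-consonant")
    return c1, v, c2


def score_attempt(
    target: Iterable[str],
    production: PhonemeSequence | Iterable[str],
    inventory: FeatureInventory,
    config: ScoringConfig = ScoringConfig(),
) -> AttemptScore:
    """Align a production to C1/V/C2 and score it against a CVC target.

    Parameters
    ----------
    target
        The target word's phonemes (exactly consonant, vowel, consonant).
    production
        The child's transcribed production; any length, including empty
        (no attempt).
    """
    t_c1, t_v, t_c2 = validate_cvc_target(target, inventory)
    aligned = inventory.align_to_cvc(production)
    return AttemptScore(
        target=(t_c1, t_v, t_c2),
        production=aligned,
        c1=score_consonant_slot(t_c1, aligned.c1, inventory, slot="C1"),
        v=score_vowel_slot(t_v, aligned.v, inventory),
        c2=score_consonant_slot(t_c2, aligned.c2, inventory, slot="C2"),
        config=config,
    )
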