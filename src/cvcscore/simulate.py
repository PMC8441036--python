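"""Synthetic trial-level probe data with the structure the analyses assume.

The generator emulates a cohort of minimally verbal children on a
weekly CVC naming-probe protocol.  Each participant carries a latent
speech-production ability ``a ~ Normal(mean, sd)``; a trial at
intervention week *w* reflects the skill level
``skill = slope * a + rate * (w - 1)``.  Given an attempt, each
articulatory feature of each target phoneme is realized correctly
with probability ``sigmoid(intercept + skill - difficulty(feature))``,
and the produced phoneme is drawn from the inventory phonemes whose
feature agreement with the target matches the realized pattern (or
comes closest when no phoneme realizes it exactly).  The final
consonant is omitted with a probability decreasing in ability, and
whole-trial non-responses occur with a probability decreasing in
skill — together these produce the floor-heavy words-passed
distributions typical of this population, while the feature-additive
phonemic score retains graded variability.

Sessions follow the mastery-driven protocol: a participant probes the
active word set weekly and advances when 3 of its 5 words are passed
in 2-of-3 attempts, or after 4 weeks, whichever comes first.

Ground truth (abilities, generating coefficients, target forms) is
retained for structure-recovery tests.  Helpers also generate a
two-rater ratings matrix for reliability studies and a plain linear
regression fixture with known standardized coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .inventory import FeatureInventory, default_inventory, default_word_list
from .probes import ProbeSession, TrialRecord, compute_session_metrics
from .scoring import ScoringConfig, score_attempt

#: Per-feature logit difficulty offsets: place is the hardest consonant
#: feature to approximate, rounding the easiest vowel feature.
DEFAULT_FEATURE_DIFFICULTY: dict[str, float] = {
    "voicing": 0.0,
    "place": 0.6,
    "manner": 0.2,
    "height": 0.3,
    "advancement": 0.3,
    "rounding": 0.0,
    "tenseness": 0.4,
}


class InvalidSpecError(ValueError):
    """A cohort specification fails validation."""


@dataclass(frozen=True)
class CohortSpec:
    """Study-design and generative parameters for a synthetic cohort.

    Defaults mirror the probe protocol (5 words x 3 presentations,
    advancement on mastery or after 4 weeks) and a cohort of 23
    participants.
    """

    n_participants: int = 23
    n_sets: int = 4
    words_per_set: int = 5
    trials_per_word: int = 3
    weeks_per_set_max: int = 4
    ability_mean: float = 0.0
    ability_sd: float = 1.0
    ability_slope: float = 1.0
    learning_rate: float = 0.1
    feature_intercept: float = 0.3
    feature_difficulty: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FEATURE_DIFFICULTY)
    )
    c2_omit_intercept: float = -0.3
    c2_omit_slope: float = 0.8
    no_attempt_intercept: float = -1.2
    no_attempt_slope: float = 0.8
    rater_noise: float = 0.02
    vineland_mean: float = 55.0
    vineland_sd: float = 9.4
    vineland_ability_r: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_participants, self.n_sets, self.words_per_set,
                  self.trials_per_word, self.weeks_per_set_max)
        if any(c < 1 for c in counts):
            raise InvalidSpecError("all design counts must be >= 1")
        for name in ("rater_noise",):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidSpecError(f"{name} must be a probability, got {v}")
        if self.ability_sd < 0 or self.vineland_sd < 0:
            raise InvalidSpecError("standard deviations must be non-negative")
        if not -1.0 <= self.vineland_ability_r <= 1.0:
            raise InvalidSpecError("vineland_ability_r must be a correlation")


@dataclass(frozen=True)
class SimTruth:
    """Generating quantities retained for recovery tests."""

    spec: CohortSpec
    abilities: dict[str, float]
    targets: dict[str, tuple[str, ...]]
    word_sets: dict[str, tuple[str, ...]]


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


class _PhonemeRealizer:
    """Maps a realized feature-agreement pattern to candidate phonemes.

    For a target phoneme and a desired 0/1 agreement vector over its
    features, candidates are inventory phonemes of the same class whose
    featurewise agreement with the target equals the vector; when no
    phoneme realizes the exact pattern (some combinations are
    phonotactically impossible), the candidates closest in Hamming
    distance to the desired pattern are used.
    """

    def __init__(self, inventory: FeatureInventory):
        self.inventory = inventory
        self._cache: dict[tuple[str, tuple[int, ...]], tuple[str, ...]] = {}

    def _agreement(self, target: str, other: str) -> tuple[int, ...]:
        if self.inventory.is_consonant(target):
            t = self.inventory.lookup_consonant(target).as_dict()
            o = self.inventory.lookup_consonant(other).as_dict()
        else:
            t = self.inventory.lookup_vowel(target).as_dict()
            o = self.inventory.lookup_vowel(other).as_dict()
        return tuple(int(t[k] == o[k]) for k in t)

    def candidates(self, target: str, pattern: tuple[int, ...]) -> tuple[str, ...]:
        key = (target, pattern)
        if key not in self._cache:
            pool = (self.inventory.consonants
                    if self.inventory.is_consonant(target) else self.inventory.vowels)
            by_distance: dict[int, list[str]] = {}
            for sym in pool:
                agr = self._agreement(target, sym)
                d = sum(x != y for x, y in zip(agr, pattern))
                by_distance.setdefault(d, []).append(sym)
            self._cache[key] = tuple(by_distance[min(by_distance)])
        return self._cache[key]


def _feature_names(inventory: FeatureInventory, symbol: str) -> tuple[str, ...]:
    if inventory.is_consonant(symbol):
        return tuple(inventory.lookup_consonant(symbol).as_dict())
    return tuple(inventory.lookup_vowel(symbol).as_dict())


def generate_cohort(
    spec: CohortSpec,
    inventory: Optional[FeatureInventory] = None,
    word_list: Optional[dict[str, tuple[str, ...]]] = None,
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Generate a cohort's trial file, covariate file, and ground truth.

    Returns ``(trials, covariates, truth)`` where ``trials`` has the
    standard trial-file columns (participant, week, word_set, word,
    trial_index, transcription, notation) and parses through the full
    scoring pipeline.
    """
    inventory = inventory or default_inventory()
    word_list = word_list or default_word_list()
    n_words_needed = spec.n_sets * spec.words_per_set
    if n_words_needed > len(word_list):
        raise InvalidSpecError(
            f"need {n_words_needed} words but the word list has {len(word_list)}"
        )
    words = list(word_list)[:n_words_needed]
    word_sets = {
        f"set{i + 1}": tuple(words[i * spec.words_per_set:(i + 1) * spec.words_per_set])
        for i in range(spec.n_sets)
    }
    rng = np.random.default_rng(spec.seed)
    realizer = _PhonemeRealizer(inventory)
    scoring_config = ScoringConfig()

    abilities: dict[str, float] = {}
    rows: list[dict] = []
    cov_rows: list[dict] = []
    for p in range(spec.n_participants):
        pid = f"P{p + 1:02d}"
        a = float(rng.normal(spec.ability_mean, spec.ability_sd))
        abilities[pid] = a
        a_std = (a - spec.ability_mean) / spec.ability_sd if spec.ability_sd else 0.0
        r = spec.vineland_ability_r
        vineland = spec.vineland_mean + spec.vineland_sd * (
            r * a_std + np.sqrt(1.0 - r * r) * rng.normal()
        )
        cov_rows.append({"participant": pid,
                         "vineland_composite": round(float(vineland), 1)})

        week = 1
        for set_id, set_words in word_sets.items():
            for _ in range(spec.weeks_per_set_max):
                skill = spec.ability_slope * a + spec.learning_rate * (week - 1)
                order = rng.permutation(
                    np.repeat(np.arange(len(set_words)), spec.trials_per_word)
                )
                session_records: list[TrialRecord] = []
                for trial_index, word_idx in enumerate(order, start=1):
                    word = set_words[word_idx]
                    target = word_list[word]
                    production = _generate_production(
                        target, skill, a, spec, inventory, realizer, rng
                    )
                    rows.append({
                        "participant": pid,
                        "week": week,
                        "word_set": set_id,
                        "word": word,
                        "trial_index": trial_index,
                        "transcription": " ".join(production),
                        "notation": "arpabet",
                    })
                    score = score_attempt(target, production, inventory, scoring_config)
                    session_records.append(TrialRecord(word, tuple(production), score))
                session = ProbeSession(pid, week, set_id, tuple(session_records))
                mastered = compute_session_metrics(session).set_mastered
                week += 1
                if mastered:
                    break

    trials = pd.DataFrame(rows)
    covariates = pd.DataFrame(cov_rows)
    truth = SimTruth(
        spec=spec,
        abilities=abilities,
        targets={w: word_list[w] for w in words},
        word_sets=word_sets,
    )
    return trials, covariates, truth


def _generate_production(
    target: Sequence[str],
    skill: float,
    ability: float,
    spec: CohortSpec,
    inventory: FeatureInventory,
    realizer: _PhonemeRealizer,
    rng: np.random.Generator,
) -> list[str]:
    """One trial's produced phoneme sequence (possibly empty)."""
    p_no_attempt = _sigmoid(spec.no_attempt_intercept - spec.no_attempt_slope * skill)
    if rng.random() < p_no_attempt:
        return []
    produced: list[str] = []
    p_omit_c2 = _sigmoid(spec.c2_omit_intercept - spec.c2_omit_slope * ability)
    for slot_index, symbol in enumerate(target):
        if slot_index == 2 and rng.random() < p_omit_c2:
            continue
        names = _feature_names(inventory, symbol)
        pattern = tuple(
            int(rng.random() < _sigmoid(
                spec.feature_intercept + skill - spec.feature_difficulty.get(n, 0.0)
            ))
            for n in names
        )
        candidates = realizer.candidates(symbol, pattern)
        produced.append(candidates[rng.integers(len(candidates))])
    return produced


def generate_rater_pair(
    scored_trials: pd.DataFrame,
    noise: float,
    seed: int,
) -> np.ndarray:
    """Two-rater ratings matrix from a per-trial score table.

    Rater 1 is the pipeline's raw totals; rater 2 re-totals the ten
    feature credits after flipping each independently with probability
    ``noise``.  Returns an (n_items, 2) array suitable for
    :func:`cvcscore.stats.icc_two_way_random`.
    """
    if not 0.0 <= noise <= 1.0:
        raise ValueError("noise must be a probability")
    credit_cols = [
        "c1_voicing", "c1_place", "c1_manner",
        "v_height", "v_advancement", "v_rounding", "v_tenseness",
        "c2_voicing", "c2_place", "c2_manner",
    ]
    credits = scored_trials[credit_cols].to_numpy(dtype=int)
    rng = np.random.default_rng(seed)
    flips = rng.random(credits.shape) < noise
    rater2 = np.where(flips, 1 - credits, credits).sum(axis=1)
    rater1 = scored_trials["raw_total"].to_numpy(dtype=int)
    return np.column_stack([rater1, rater2])


def generate_regression_fixture(
    n: int,
    coefficients: Sequence[float],
    noise_sd: float,
    seed: int,
    predictor_corr: Optional[np.ndarray] = None,
) -> tuple[pd.DataFrame, dict]:
    """Linear-model fixture with known coefficients.

    Predictors ``x1..xp`` are standard normal with correlation matrix
    ``predictor_corr`` (identity by default); the outcome is
    ``y = X @ coefficients + noise_sd * eps``.  The returned truth dict
    carries the raw coefficients and the implied *standardized*
    coefficients ``beta_j / sd(y)``.
    """
    beta = np.asarray(coefficients, dtype=float)
    p = len(beta)
    if n <= p + 1:
        raise ValueError("n must exceed the number of predictors + 1")
    corr = np.eye(p) if predictor_corr is None else np.asarray(predictor_corr, float)
    rng = np.random.default_rng(seed)
    X = rng.multivariate_normal(np.zeros(p), corr, size=n, method="cholesky")
    y = X @ beta + noise_sd * rng.normal(size=n)
    data = pd.DataFrame(X, columns=[f"x{i + 1}" for i in range(p)])
    data["y"] = y
    var_y = float(beta @ corr @ beta + noise_sd**2)
    truth = {
        "coefficients": beta,
        "noise_sd": noise_sd,
        "predictor_corr": corr,
        "standardized_coefficients": beta / np.sqrt(var_y),
        "r2": float(beta @ corr @ beta / var_y) if var_y > 0 else 1.0,
    }
    return data, truth
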