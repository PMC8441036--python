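"""Probe-session aggregation and per-participant derived variables.

A weekly probe presents each of the 5 target words in the active word
set 3 times in random order (15 trials).  A word is *passed* in a
session when at least 2 of its 3 attempts pass (for k attempts the
threshold generalizes to ceil(2k/3)); a set is *mastered* when at
least 3 of its 5 words are passed, which in the intervention protocol
triggers advancement to the next set (or after 4 weeks, whichever
comes first).

From scored sessions this module derives the five per-participant
variables used in the downstream analyses:

``ps_tw4``
    week-4 total phonemic score divided by the number of trials;
``wp_tw4``
    week-4 words passed divided by the number of trials;
``ps_ts2``
    best post-week-4 session of the outcome set, phonemic total per trial;
``wp_ts2``
    best post-week-4 session of the outcome set, words passed per trial;
``wp_wasw``
    total word passes across all post-week-4 sessions divided by the
    number of post-week-4 intervention weeks.

The words-passed-per-trial metrics admit two denominations.  The
primary definition divides the count of *distinct* words passed by the
number of trials (so a perfect 15-trial session scores 5/15 ≈ 0.33);
the alternate ``"trials"`` definition divides the count of passing
*trials* by the number of trials and is bounded by 1.0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .inventory import FeatureInventory, default_inventory, default_word_list
from .scoring import AttemptScore, ScoringConfig, score_attempt

logger = logging.getLogger(__name__)

CANONICAL_TRIALS = 15
CANONICAL_WORDS = 5
MASTERY_WORDS_REQUIRED = 3

#: Column order for the per-trial score table.
TRIAL_SCORE_COLUMNS = [
    "participant",
    "week",
    "word_set",
    "word",
    "trial_index",
    "c1_voicing",
    "c1_place",
    "c1_manner",
    "v_height",
    "v_advancement",
    "v_rounding",
    "v_tenseness",
    "c2_voicing",
    "c2_place",
    "c2_manner",
    "raw_total",
    "initial_consonant_correct",
    "passed",
]


class EmptySessionError(ValueError):
    """A probe session with no trials cannot be summarized."""


class MissingWeek4Error(ValueError):
    """No probe session at intervention week 4 for this participant."""


class NoOutcomeDataError(ValueError):
    """No post-week-4 probe sessions for this participant."""


@dataclass(frozen=True)
class TrialRecord:
    """One scored naming trial."""

    word: str
    production: tuple[str, ...]
    score: AttemptScore


@dataclass(frozen=True)
class ProbeSession:
    """One weekly probe: a participant's ordered trials for one word set."""

    participant: str
    week: int
    word_set: str
    trials: tuple[TrialRecord, ...]

    def __post_init__(self) -> None:
        if self.week < 1:
            raise ValueError("intervention week must be >= 1")
        n_words = len({t.word for t in self.trials})
        if self.trials and (len(self.trials) != CANONICAL_TRIALS or n_words != CANONICAL_WORDS):
            logger.warning(
                "protocol deviation: participant %s week %s set %s has %d trials over %d words "
                "(canonical design is %d trials over %d words)",
                self.participant, self.week, self.word_set,
                len(self.trials), n_words, CANONICAL_TRIALS, CANONICAL_WORDS,
            )

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def words(self) -> tuple[str, ...]:
        seen: list[str] = []
        for t in self.trials:
            if t.word not in seen:
                seen.append(t.word)
        return tuple(seen)


@dataclass(frozen=True)
class SessionMetrics:
    """Session-level totals and per-trial normalizations."""

    total_phonemic_score: int
    phonemic_score_per_trial: float
    words_passed: int
    words_passed_per_trial: float
    trials_passed: int
    trials_passed_per_trial: float
    set_mastered: bool
    n_trials: int
    n_words: int


@dataclass(frozen=True)
class DerivationConfig:
    """Options for deriving participant variables.

    ``words_passed_definition`` selects the numerator of the
    words-passed-per-trial metrics: ``"words"`` (distinct words passed,
    primary) or ``"trials"`` (passing trials, bounded by 1.0).
    ``total_weeks_after_4``, when given, replaces the count of observed
    post-week-4 probe weeks as the denominator of ``wp_wasw``.
    """

    words_passed_definition: str = "words"
    total_weeks_after_4: Optional[int] = None

    def __post_init__(self) -> None:
        if self.words_passed_definition not in ("words", "trials"):
            raise ValueError("words_passed_definition must be 'words' or 'trials'")


@dataclass(frozen=True)
class ParticipantDerived:
    """The five derived predictor/outcome variables plus the Vineland covariate."""

    participant: str
    ps_tw4: float
    wp_tw4: float
    ps_ts2: float
    wp_ts2: float
    wp_wasw: float
    vineland_composite: Optional[float] = None
    outcome_set: Optional[str] = None


def word_passed_in_session(trials_for_word: Sequence[AttemptScore]) -> bool:
    """True when the word passed in at least 2-of-3 of its attempts.

    For k attempts the threshold is ceil(2k/3), which reduces to 2 for
    the canonical 3 presentations.
    """
    if not trials_for_word:
        raise ValueError("word_passed_in_session requires at least one trial")
    k = len(trials_for_word)
    threshold = math.ceil(2 * k / 3)
    return sum(t.passed for t in trials_for_word) >= threshold


def compute_session_metrics(
    session: ProbeSession, definition: str = "words"
) -> SessionMetrics:
    """Summarize a probe session into totals and per-trial rates."""
    if session.n_trials == 0:
        raise EmptySessionError(
            f"participant {session.participant} week {session.week}: empty session"
        )
    if definition not in ("words", "trials"):
        raise ValueError("definition must be 'words' or 'trials'")
    total = sum(t.score.raw_total for t in session.trials)
    trials_passed = sum(t.score.passed for t in session.trials)
    by_word: dict[str, list[AttemptScore]] = {}
    for t in session.trials:
        by_word.setdefault(t.word, []).append(t.score)
    words_passed = sum(word_passed_in_session(scores) for scores in by_word.values())
    n = session.n_trials
    numerator = words_passed if definition == "words" else trials_passed
    return SessionMetrics(
        total_phonemic_score=total,
        phonemic_score_per_trial=total / n,
        words_passed=words_passed,
        words_passed_per_trial=numerator / n,
        trials_passed=trials_passed,
        trials_passed_per_trial=trials_passed / n,
        set_mastered=words_passed >= MASTERY_WORDS_REQUIRED,
        n_trials=n,
        n_words=len(by_word),
    )


def best_session_for_set(
    sessions: Sequence[ProbeSession],
    criterion: str = "phonemic_total",
    definition: str = "words",
) -> ProbeSession:
    """The session maximizing the named criterion; ties go to the earliest week.

    ``criterion`` is ``"phonemic_total"`` (total phonemic score) or
    ``"words_passed"`` (words passed under ``definition``).
    """
    if not sessions:
        raise ValueError("best_session_for_set requires at least one session")

    def key(s: ProbeSession) -> float:
        m = compute_session_metrics(s, definition)
        if criterion == "phonemic_total":
            return m.total_phonemic_score
        if criterion == "words_passed":
            return m.words_passed if definition == "words" else m.trials_passed
        raise ValueError(f"unknown criterion {criterion!r}")

    best = sessions[0]
    best_key = key(best)
    for s in sessions[1:]:
        k = key(s)
        if k > best_key or (k == best_key and s.week < best.week):
            best, best_key = s, k
    return best


def derive_participant_variables(
    all_sessions: Sequence[ProbeSession],
    vineland_composite: Optional[float] = None,
    config: DerivationConfig = DerivationConfig(),
) -> ParticipantDerived:
    """Compute the five predictor/outcome variables for one participant.

    Predictors come from the week-4 session; outcomes from the first
    word set probed after week 4 (the "outcome set") and from all
    post-week-4 word passes.  Raises if the week-4 session or the
    outcome window is missing.
    """
    if not all_sessions:
        raise ValueError("no sessions supplied")
    participant = all_sessions[0].participant
    week4 = [s for s in all_sessions if s.week == 4]
    if not week4:
        raise MissingWeek4Error(f"participant {participant}: no week-4 probe session")
    if len(week4) > 1:
        raise ValueError(f"participant {participant}: multiple week-4 sessions")
    wk4 = compute_session_metrics(week4[0], config.words_passed_definition)

    post = sorted(
        (s for s in all_sessions if s.week > 4), key=lambda s: (s.week, s.word_set)
    )
    if not post:
        raise NoOutcomeDataError(f"participant {participant}: no post-week-4 sessions")
    outcome_set = post[0].word_set
    if any(s.week <= 4 and s.word_set == outcome_set for s in all_sessions):
        logger.info(
            "participant %s: outcome set %s was already probed at or before week 4",
            participant, outcome_set,
        )
    set2 = [s for s in post if s.word_set == outcome_set]
    defn = config.words_passed_definition
    best_ps = compute_session_metrics(
        best_session_for_set(set2, "phonemic_total", defn), defn
    )
    best_wp = compute_session_metrics(
        best_session_for_set(set2, "words_passed", defn), defn
    )

    post_metrics = [compute_session_metrics(s, defn) for s in post]
    total_passes = sum(
        m.words_passed if defn == "words" else m.trials_passed for m in post_metrics
    )
    n_weeks = config.total_weeks_after_4 or len({s.week for s in post})
    return ParticipantDerived(
        participant=participant,
        ps_tw4=wk4.phonemic_score_per_trial,
        wp_tw4=wk4.words_passed_per_trial,
        ps_ts2=best_ps.phonemic_score_per_trial,
        wp_ts2=best_wp.words_passed_per_trial,
        wp_wasw=total_passes / n_weeks,
        vineland_composite=vineland_composite,
        outcome_set=outcome_set,
    )


# ---------------------------------------------------------------------------
# file-level pipeline (delimited text in, tables out)
# ---------------------------------------------------------------------------

def read_trials(path) -> pd.DataFrame:
    """Read a trial file: participant, week, word_set, word, trial_index,
    transcription, notation (TSV or CSV by extension)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype={"participant": str, "word_set": str},
                     keep_default_na=False)
    required = {"participant", "week", "word_set", "word", "trial_index", "transcription"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trial file missing columns: {sorted(missing)}")
    if "notation" not in df.columns:
        df["notation"] = "arpabet"
    return df


def read_covariates(path) -> pd.DataFrame:
    """Read a covariate file: participant, vineland_composite."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype={"participant": str})
    if not {"participant", "vineland_composite"} <= set(df.columns):
        raise ValueError("covariate file needs participant, vineland_composite columns")
    return df


def sessions_from_trials(
    trials: pd.DataFrame,
    inventory: Optional[FeatureInventory] = None,
    word_list: Optional[dict[str, tuple[str, ...]]] = None,
    config: ScoringConfig = ScoringConfig(),
) -> list[ProbeSession]:
    """Score every trial and group into probe sessions.

    Target transcriptions come from ``word_list`` (packaged CVC list by
    default); productions are parsed according to each row's notation tag.
    """
    inventory = inventory or default_inventory()
    word_list = word_list or default_word_list()
    sessions: list[ProbeSession] = []
    trials = trials.sort_values(["participant", "week", "word_set", "trial_index"],
                                kind="mergesort")
    for (participant, week, word_set), group in trials.groupby(
        ["participant", "week", "word_set"], sort=True
    ):
        records = []
        for row in group.itertuples(index=False):
            target = word_list.get(row.word)
            if target is None:
                raise KeyError(f"word {row.word!r} not in the target word list")
            production = inventory.parse_transcription(
                str(row.transcription), getattr(row, "notation", "arpabet")
            )
            score = score_attempt(target, production, inventory, config)
            records.append(TrialRecord(row.word, production.symbols, score))
        sessions.append(
            ProbeSession(str(participant), int(week), str(word_set), tuple(records))
        )
    return sessions


def trial_score_table(sessions: Iterable[ProbeSession]) -> pd.DataFrame:
    """Per-trial score rows with the ten feature-credit columns."""
    rows = []
    for s in sessions:
        for i, t in enumerate(s.trials, start=1):
            sc = t.score
            rows.append({
                "participant": s.participant,
                "week": s.week,
                "word_set": s.word_set,
                "word": t.word,
                "trial_index": i,
                "c1_voicing": sc.c1.credits["voicing"],
                "c1_place": sc.c1.credits["place"],
                "c1_manner": sc.c1.credits["manner"],
                "v_height": sc.v.credits["height"],
                "v_advancement": sc.v.credits["advancement"],
                "v_rounding": sc.v.credits["rounding"],
                "v_tenseness": sc.v.credits["tenseness"],
                "c2_voicing": sc.c2.credits["voicing"],
                "c2_place": sc.c2.credits["place"],
                "c2_manner": sc.c2.credits["manner"],
                "raw_total": sc.raw_total,
                "initial_consonant_correct": sc.initial_consonant_correct,
                "passed": sc.passed,
            })
    return pd.DataFrame(rows, columns=TRIAL_SCORE_COLUMNS)


def session_metrics_table(
    sessions: Iterable[ProbeSession], definition: str = "words"
) -> pd.DataFrame:
    """One row of SessionMetrics per probe session."""
    rows = []
    for s in sessions:
        m = compute_session_metrics(s, definition)
        rows.append({
            "participant": s.participant,
            "week": s.week,
            "word_set": s.word_set,
            "n_trials": m.n_trials,
            "n_words": m.n_words,
            "total_phonemic_score": m.total_phonemic_score,
            "phonemic_score_per_trial": m.phonemic_score_per_trial,
            "words_passed": m.words_passed,
            "words_passed_per_trial": m.words_passed_per_trial,
            "trials_passed": m.trials_passed,
            "trials_passed_per_trial": m.trials_passed_per_trial,
            "set_mastered": m.set_mastered,
        })
    return pd.DataFrame(rows)


def derive_table(
    sessions: Iterable[ProbeSession],
    covariates: Optional[pd.DataFrame] = None,
    config: DerivationConfig = DerivationConfig(),
) -> pd.DataFrame:
    """Derived-variable row per participant; participants without a week-4
    session or an outcome window are dropped with a log message."""
    by_participant: dict[str, list[ProbeSession]] = {}
    for s in sessions:
        by_participant.setdefault(s.participant, []).append(s)
    vineland = {}
    if covariates is not None:
        vineland = dict(zip(covariates["participant"].astype(str),
                            covariates["vineland_composite"]))
    rows = []
    for participant in sorted(by_participant):
        try:
            d = derive_participant_variables(
                by_participant[participant], vineland.get(participant), config
            )
        except (MissingWeek4Error, NoOutcomeDataError) as exc:
            logger.warning("dropping participant %s: %s", participant, exc)
            continue
        rows.append({
            "participant": d.participant,
            "ps_tw4": d.ps_tw4,
            "wp_tw4": d.wp_tw4,
            "ps_ts2": d.ps_ts2,
            "wp_ts2": d.wp_ts2,
            "wp_wasw": d.wp_wasw,
            "vineland_composite": d.vineland_composite,
            "outcome_set": d.outcome_set,
        })
    return pd.DataFrame(rows)


def descriptives(derived: pd.DataFrame) -> pd.DataFrame:
    """Min/max/mean/SD for each derived variable."""
    cols = [c for c in ("ps_tw4", "wp_tw4", "ps_ts2", "wp_ts2", "wp_wasw",
                        "vineland_composite") if c in derived.columns]
    stats = derived[cols].agg(["min", "max", "mean", "std"]).T
    stats.columns = ["minimum", "maximum", "mean", "sd"]
    return stats
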