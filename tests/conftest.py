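import pytest

from cvcscore import (
    ProbeSession,
    ScoringConfig,
    TrialRecord,
    default_inventory,
    default_word_list,
    score_attempt,
)


@pytest.fixture(scope="session")
def inventory():
    return default_inventory()


@pytest.fixture(scope="session")
def word_list():
    return default_word_list()


@pytest.fixture(scope="session")
def make_session(inventory, word_list):
    """Build a scored ProbeSession from word → list-of-productions.

    Each production is a tuple of phoneme symbols; () means no attempt.
    """

    def _make(productions_by_word, participant="P01", week=1, word_set="set1",
              config=ScoringConfig()):
        records = []
        for word, productions in productions_by_word.items():
            target = word_list[word]
            for production in productions:
                score = score_attempt(target, production, inventory, config)
                records.append(TrialRecord(word, tuple(production), score))
        return ProbeSession(participant, week, word_set, tuple(records))

    return _make
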