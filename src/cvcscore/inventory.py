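"""Articulatory feature inventory, transcription parsing, and CVC alignment.

The scoring system rests on a per-phoneme articulatory feature table:
consonants carry a (voicing, place, manner) triple and vowels a
(height, advancement, rounding, tenseness) quadruple.  The packaged
table covers a General-American inventory in a machine-friendly
ARPAbet-style notation, with an IPA mapping for each symbol; diphthongs
are assigned the features of their nucleus and affricates are single
phonemes with manner ``affricate``.  Users may override the table with
a TSV of the same layout.

Productions arrive as phonemic transcriptions.  :func:`parse_transcription`
tokenizes them (ARPAbet tokens or greedy IPA segmentation) and
:func:`align_to_cvc` maps the resulting phoneme sequence onto the three
scoring slots C1 (initial consonant), V (vowel nucleus), C2 (final
consonant): consonants before the first vowel fill C1 (first one wins),
the first vowel fills V, the first consonant after it fills C2, and
everything else is kept as unscored extras.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

CONSONANT_PLACES = frozenset(
    {"bilabial", "labio-dental", "dental", "alveolar", "palatal", "velar", "glottal"}
)
CONSONANT_MANNERS = frozenset(
    {"stop", "fricative", "affricate", "nasal", "liquid", "glide"}
)
VOICING_VALUES = frozenset({"voiced", "voiceless"})
VOWEL_HEIGHTS = frozenset({"low", "mid", "high"})
VOWEL_ADVANCEMENTS = frozenset({"front", "central", "back"})
ROUNDING_VALUES = frozenset({"rounded", "unrounded"})
TENSENESS_VALUES = frozenset({"tense", "lax"})

CONSONANT_FEATURE_NAMES = ("voicing", "place", "manner")
VOWEL_FEATURE_NAMES = ("height", "advancement", "rounding", "tenseness")

#: Sentinel transcription values meaning the child made no attempt.
NO_ATTEMPT_TOKENS = frozenset({"", "-", "NA", "NO_ATTEMPT"})


class InventoryError(KeyError):
    """A phoneme symbol does not resolve in the feature inventory."""


class WrongClassError(InventoryError):
    """A symbol resolves, but to the wrong phoneme class for the lookup."""


class ParseError(ValueError):
    """A transcription contains a token that cannot be segmented."""


@dataclass(frozen=True)
class ConsonantFeatures:
    """Feature triple for a consonant: voicing, place and manner of articulation."""

    voicing: str
    place: str
    manner: str

    def __post_init__(self) -> None:
        if self.voicing not in VOICING_VALUES:
            raise ValueError(f"invalid voicing {self.voicing!r}")
        if self.place not in CONSONANT_PLACES:
            raise ValueError(f"invalid place {self.place!r}")
        if self.manner not in CONSONANT_MANNERS:
            raise ValueError(f"invalid manner {self.manner!r}")

    def as_dict(self) -> dict[str, str]:
        return {"voicing": self.voicing, "place": self.place, "manner": self.manner}


@dataclass(frozen=True)
class VowelFeatures:
    """Feature quadruple for a vowel: height, advancement, rounding, tenseness."""

    height: str
    advancement: str
    rounding: str
    tenseness: str

    def __post_init__(self) -> None:
        if self.height not in VOWEL_HEIGHTS:
            raise ValueError(f"invalid height {self.height!r}")
        if self.advancement not in VOWEL_ADVANCEMENTS:
            raise ValueError(f"invalid advancement {self.advancement!r}")
        if self.rounding not in ROUNDING_VALUES:
            raise ValueError(f"invalid rounding {self.rounding!r}")
        if self.tenseness not in TENSENESS_VALUES:
            raise ValueError(f"invalid tenseness {self.tenseness!r}")

    def as_dict(self) -> dict[str, str]:
        return {
            "height": self.height,
            "advancement": self.advancement,
            "rounding": self.rounding,
            "tenseness": self.tenseness,
        }


@dataclass(frozen=True)
class PhonemeSequence:
    """An ordered sequence of inventory symbols plus the notation it came from."""

    symbols: tuple[str, ...]
    notation: str = "arpabet"

    def __len__(self) -> int:
        return len(self.symbols)

    def __iter__(self):
        return iter(self.symbols)


@dataclass(frozen=True)
class AlignedProduction:
    """A production mapped onto the C1 / V / C2 scoring slots.

    An empty slot means the corresponding sound was omitted and scores 0;
    ``extras`` holds inserted phonemes, which never earn or cost points.
    """

    c1: Optional[str]
    v: Optional[str]
    c2: Optional[str]
    extras: tuple[str, ...] = ()

    @property
    def n_aligned(self) -> int:
        return sum(s is not None for s in (self.c1, self.v, self.c2))


class FeatureInventory:
    """Phoneme → articulatory-feature lookup backed by a delimited table."""

    def __init__(
        self,
        consonants: dict[str, ConsonantFeatures],
        vowels: dict[str, VowelFeatures],
        ipa_map: dict[str, str],
    ):
        overlap = consonants.keys() & vowels.keys()
        if overlap:
            raise ValueError(f"symbols in both classes: {sorted(overlap)}")
        self._consonants = dict(consonants)
        self._vowels = dict(vowels)
        self._ipa_map = dict(ipa_map)

    @classmethod
    def from_table(cls, path: str | Path) -> "FeatureInventory":
        """Load an inventory from a TSV feature table (see packaged resource)."""
        consonants: dict[str, ConsonantFeatures] = {}
        vowels: dict[str, VowelFeatures] = {}
        ipa_map: dict[str, str] = {}
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            idx = {name: i for i, name in enumerate(header)}
            for lineno, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                row = line.rstrip("\n").split("\t")

                def cell(name: str) -> str:
                    i = idx[name]
                    return row[i].strip() if i < len(row) else ""

                symbol = cell("symbol")
                klass = cell("class")
                if symbol in consonants or symbol in vowels:
                    raise ValueError(f"duplicate symbol {symbol!r} at line {lineno}")
                if klass == "consonant":
                    consonants[symbol] = ConsonantFeatures(
                        cell("voicing"), cell("place"), cell("manner")
                    )
                elif klass == "vowel":
                    vowels[symbol] = VowelFeatures(
                        cell("height"), cell("advancement"), cell("rounding"), cell("tenseness")
                    )
                else:
                    raise ValueError(f"unknown class {klass!r} at line {lineno}")
                ipa = cell("ipa")
                if ipa:
                    ipa_map[ipa] = symbol
        return cls(consonants, vowels, ipa_map)

    # -- lookups ---------------------------------------------------------

    @property
    def consonants(self) -> tuple[str, ...]:
        return tuple(self._consonants)

    @property
    def vowels(self) -> tuple[str, ...]:
        return tuple(self._vowels)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._consonants or symbol in self._vowels

    def is_consonant(self, symbol: str) -> bool:
        return symbol in self._consonants

    def is_vowel(self, symbol: str) -> bool:
        return symbol in self._vowels

    def lookup_consonant(self, symbol: str) -> ConsonantFeatures:
        """Return the (voicing, place, manner) triple for a consonant symbol."""
        try:
            return self._consonants[symbol]
        except KeyError:
            if symbol in self._vowels:
                raise WrongClassError(
                    f"{symbol!r} is a vowel, not a consonant"
                ) from None
            raise InventoryError(f"unknown consonant symbol {symbol!r}") from None

    def lookup_vowel(self, symbol: str) -> VowelFeatures:
        """Return the (height, advancement, rounding, tenseness) quadruple for a vowel."""
        try:
            return self._vowels[symbol]
        except KeyError:
            if symbol in self._consonants:
                raise WrongClassError(
                    f"{symbol!r} is a consonant, not a vowel"
                ) from None
            raise InventoryError(f"unknown vowel symbol {symbol!r}") from None

    # -- parsing ---------------------------------------------------------

    def parse_transcription(self, text: str, notation: str = "arpabet") -> PhonemeSequence:
        """Tokenize a transcription into inventory symbols.

        ``notation="arpabet"`` splits on whitespace (case-insensitive tokens);
        ``notation="ipa"`` strips slashes and segments greedily, longest IPA
        string first.  A no-attempt marker (empty string, ``-``, ``NA``)
        yields an empty sequence.
        """
        stripped = text.strip()
        if stripped.upper() in NO_ATTEMPT_TOKENS:
            return PhonemeSequence((), notation)
        if notation == "arpabet":
            symbols = []
            for pos, token in enumerate(stripped.split()):
                sym = token.upper()
                if sym not in self:
                    raise ParseError(f"unknown symbol {token!r} at token {pos}")
                symbols.append(sym)
            return PhonemeSequence(tuple(symbols), notation)
        if notation == "ipa":
            return self._parse_ipa(stripped)
        raise ValueError(f"unknown notation {notation!r}")

    def _parse_ipa(self, text: str) -> PhonemeSequence:
        body = text.strip().strip("/").strip()
        keys = sorted(self._ipa_map, key=len, reverse=True)
        symbols: list[str] = []
        i = 0
        while i < len(body):
            if body[i].isspace():
                i += 1
                continue
            for key in keys:
                if body.startswith(key, i):
                    symbols.append(self._ipa_map[key])
                    i += len(key)
                    break
            else:
                raise ParseError(f"unparseable IPA at position {i}: {body[i:]!r}")
        return PhonemeSequence(tuple(symbols), "ipa")

    # -- alignment -------------------------------------------------------

    def align_to_cvc(self, production: PhonemeSequence | Iterable[str]) -> AlignedProduction:
        """Greedy first-match assignment of a production to C1/V/C2 slots."""
        symbols = tuple(production)
        c1 = v = c2 = None
        extras: list[str] = []
        for sym in symbols:
            if self.is_vowel(sym):
                if v is None:
                    v = sym
                else:
                    extras.append(sym)
            else:
                self.lookup_consonant(sym)  # raise on unknown symbol
                if v is None:
                    if c1 is None:
                        c1 = sym
                    else:
                        extras.append(sym)
                else:
                    if c2 is None:
                        c2 = sym
                    else:
                        extras.append(sym)
        return AlignedProduction(c1, v, c2, tuple(extras))


def _packaged(name: str) -> Path:
    return Path(resources.files("cvcscore").joinpath("data", name))  # type: ignore[arg-type]


def default_inventory() -> FeatureInventory:
    """The packaged General-American feature inventory."""
    return FeatureInventory.from_table(_packaged("feature_table.tsv"))


def default_word_list() -> dict[str, tuple[str, ...]]:
    """Packaged CVC probe words mapped to their canonical transcriptions."""
    words: dict[str, tuple[str, ...]] = {}
    with open(_packaged("word_list.tsv"), encoding="utf-8") as fh:
        fh.readline()
        for line in fh:
            if not line.strip():
                continue
            word, transcription = line.rstrip("\n").split("\t")
            words[word] = tuple(transcription.split())
    return words
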