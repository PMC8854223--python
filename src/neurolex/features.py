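"""Word-complexity parameters of spoken content words.

Four word-level measures are computed from a phonological decomposition and a
lemma-frequency lexicon:

* **NoS** — number of spoken syllables.
* **CVR** — consonant-to-vowel ratio: consonant count divided by vowel count.
* **EoA** — ease-of-articulation index: a linear penalty score over the
  metrical (stress) pattern, complex constrictions (consonant clusters) and
  the number of articulatory gestures.  Higher values mean easier words.
* **FRQ** — lemma frequency in a spoken-language corpus, disambiguated by
  part of speech so that homographs of a different category (e.g. the German
  verb "sein" vs. the possessive pronoun "sein") never pool their counts.

Content-word selection keeps full verbs (FV), normal nouns (NN) and the
adverb group (ADV, ADJD, PWAV, PAV), drops words longer than three syllables
(the EoA model is undefined beyond that) and keeps only the chronologically
first occurrence of each word form within its category.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Syllable",
    "WordType",
    "EoAWeights",
    "FrequencyLexicon",
    "CONTENT_POS",
    "ADV_GROUP",
    "pos_category",
    "count_syllables",
    "consonant_vowel_ratio",
    "default_gesture_count",
    "ease_of_articulation",
    "lookup_frequency",
    "select_content_words",
    "log_transform",
]

#: Part-of-speech tags analyzed (STTS content categories).
CONTENT_POS = frozenset({"FV", "NN", "ADV", "ADJD", "PWAV", "PAV"})

#: Tags pooled into the adverb category.
ADV_GROUP = frozenset({"ADV", "ADJD", "PWAV", "PAV"})

#: Maximum word length, in syllables, for which EoA is defined.
MAX_SYLLABLES = 3


def pos_category(pos: str) -> str:
    """Collapse a PoS tag to its analysis category (FV, NN or ADV)."""
    if pos in ADV_GROUP:
        return "ADV"
    if pos in ("FV", "NN"):
        return pos
    raise ValueError(f"not a content-word PoS tag: {pos!r}")


@dataclass(frozen=True)
class Syllable:
    """Abstract C*VC* syllable template: consonant/vowel counts only.

    Diphthongs count as a single nucleus vowel.
    """

    onset_consonants: int = 0
    nucleus_vowels: int = 1
    coda_consonants: int = 0

    def __post_init__(self) -> None:
        if self.nucleus_vowels < 1:
            raise ValueError("a syllable needs a vocalic nucleus (nucleus_vowels >= 1)")
        if self.onset_consonants < 0 or self.coda_consonants < 0:
            raise ValueError("consonant counts must be non-negative")

    @property
    def n_consonants(self) -> int:
        return self.onset_consonants + self.coda_consonants

    def as_template(self) -> str:
        """Render as a C/V string, e.g. ``CCVC``."""
        return (
            "C" * self.onset_consonants
            + "V" * self.nucleus_vowels
            + "C" * self.coda_consonants
        )

    @classmethod
    def from_template(cls, template: str) -> "Syllable":
        t = template.upper()
        if set(t) - {"C", "V"}:
            raise ValueError(f"syllable template may contain only C/V: {template!r}")
        i = 0
        while i < len(t) and t[i] == "C":
            i += 1
        j = i
        while j < len(t) and t[j] == "V":
            j += 1
        if "V" in t[j:]:
            raise ValueError(f"not a C*V*C* template: {template!r}")
        return cls(i, j - i, len(t) - j)


@dataclass(frozen=True)
class WordType:
    """A lexical entry with its phonological decomposition."""

    orthography: str
    lemma: str
    pos: str
    syllables: tuple[Syllable, ...]
    stress_index: int = 0
    gesture_count: int | None = None

    def __post_init__(self) -> None:
        if len(self.syllables) < 1:
            raise ValueError("a word has at least one syllable")
        if not 0 <= self.stress_index < len(self.syllables):
            raise ValueError("stress_index must address an existing syllable")
        if self.gesture_count is not None and self.gesture_count < len(self.syllables):
            raise ValueError("gesture_count cannot be below the syllable count")
        object.__setattr__(self, "syllables", tuple(self.syllables))

    @property
    def n_consonants(self) -> int:
        return sum(s.n_consonants for s in self.syllables)

    @property
    def n_vowels(self) -> int:
        return sum(s.nucleus_vowels for s in self.syllables)


def count_syllables(word: WordType) -> int:
    """Number of spoken syllables (NoS)."""
    return len(word.syllables)


def consonant_vowel_ratio(word: WordType) -> float:
    """Consonant-to-vowel ratio (CVR): consonant count / vowel count."""
    return word.n_consonants / word.n_vowels


def default_gesture_count(word: WordType) -> int:
    """Stand-in articulatory gesture count when none is annotated.

    One gesture per consonant, one per syllable nucleus, plus one word-level
    (glottal/velic) baseline gesture.  Overridable per word via
    :attr:`WordType.gesture_count`.
    """
    return word.n_consonants + count_syllables(word) + 1


@dataclass(frozen=True)
class EoAWeights:
    """Penalty weights of the linear ease-of-articulation surrogate.

    The score decreases with a non-word-initial stress pattern, with each
    complex constriction (onset or coda cluster of >= 2 consonants) and with
    each articulatory gesture.  Defaults produce the expected sign structure
    between EoA and frequency/length without asserting published magnitudes.
    """

    intercept: float = 10.0
    w_metric: float = 1.0
    w_cluster: float = 1.0
    w_gesture: float = 0.25

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "EoAWeights":
        return cls(**json.loads(Path(path).read_text()))


def _n_clusters(word: WordType) -> int:
    """Complex constrictions: onset/coda groups with >= 2 consonants."""
    n = 0
    for syl in word.syllables:
        if syl.onset_consonants >= 2:
            n += 1
        if syl.coda_consonants >= 2:
            n += 1
    return n


def ease_of_articulation(word: WordType, weights: EoAWeights = EoAWeights()) -> float:
    """Ease-of-articulation index (EoA). Higher = easier to articulate.

    Defined only for words of at most three syllables.
    """
    nos = count_syllables(word)
    if nos > MAX_SYLLABLES:
        raise ValueError(
            f"EoA undefined for words of more than {MAX_SYLLABLES} syllables "
            f"(got {nos})"
        )
    gestures = (
        word.gesture_count if word.gesture_count is not None else default_gesture_count(word)
    )
    return (
        weights.intercept
        - weights.w_metric * (word.stress_index != 0)
        - weights.w_cluster * _n_clusters(word)
        - weights.w_gesture * gestures
    )


# frequency lexicon ----------------------------------------------------------

_POS_CLASS = {
    "FV": "verb",
    "VVFIN": "verb",
    "VVINF": "verb",
    "NN": "noun",
    "ADV": "adv",
    "ADJD": "adv",
    "PWAV": "adv",
    "PAV": "adv",
}


def pos_class(pos: str) -> str:
    """Map a PoS tag to the coarse class used for frequency disambiguation."""
    return _POS_CLASS.get(pos, pos.lower())


class FrequencyLexicon:
    """(lemma, PoS class) -> corpus frequency, summing inflectional sub-entries.

    Lookups are PoS-disambiguated: homographs of a different class never mix.
    A missing pair yields NaN (a missing-value flag), never zero.
    """

    def __init__(self, entries: Mapping[tuple[str, str], float] | None = None):
        self._table: dict[tuple[str, str], float] = {}
        if entries:
            for (lemma, pos), freq in entries.items():
                self.add(lemma, pos, freq)

    def add(self, lemma: str, pos: str, frequency: float) -> None:
        if frequency < 0:
            raise ValueError("frequencies must be non-negative")
        key = (lemma, pos_class(pos))
        self._table[key] = self._table.get(key, 0.0) + float(frequency)

    def get(self, lemma: str, pos: str) -> float:
        return self._table.get((lemma, pos_class(pos)), math.nan)

    def __len__(self) -> int:
        return len(self._table)

    def __contains__(self, key: tuple[str, str]) -> bool:
        lemma, pos = key
        return (lemma, pos_class(pos)) in self._table

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"lemma": lemma, "pos": pos, "frequency": freq}
            for (lemma, pos), freq in sorted(self._table.items())
        ]
        return pd.DataFrame(rows, columns=["lemma", "pos", "frequency"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FrequencyLexicon":
        df = pd.read_csv(path, sep="\t", dtype={"lemma": str, "pos": str})
        lex = cls()
        for row in df.itertuples(index=False):
            lex.add(row.lemma, row.pos, row.frequency)
        return lex


def lookup_frequency(lemma: str, pos: str, lexicon: FrequencyLexicon) -> float:
    """Lemma frequency (FRQ) for the matching PoS class; NaN if unknown.

    Sub-entries of the same class (e.g. finite and non-finite verb forms) are
    summed at lexicon construction; classes never pool across each other.
    """
    return lexicon.get(lemma, pos)


# content-word selection -----------------------------------------------------

def select_content_words(tokens: Sequence) -> list:
    """Filter a stream of timed word tokens down to the analyzed set.

    Keeps content PoS only (FV, NN, and the adverb group), drops words longer
    than three syllables, and keeps only the chronologically first occurrence
    of each word form within its PoS category.  Tokens must carry ``word``
    (a :class:`WordType`) and ``onset`` attributes and be chronologically
    ordered within each category.  Idempotent.
    """
    last_onset: dict[str, float] = {}
    seen: dict[str, set[str]] = {}
    kept = []
    for tok in tokens:
        word: WordType = tok.word
        if word.pos not in CONTENT_POS:
            continue
        cat = pos_category(word.pos)
        if cat in last_onset and tok.onset < last_onset[cat]:
            raise ValueError(
                f"tokens not chronologically ordered within category {cat!r}"
            )
        last_onset[cat] = tok.onset
        if count_syllables(word) > MAX_SYLLABLES:
            continue
        forms = seen.setdefault(cat, set())
        if word.orthography in forms:
            continue
        forms.add(word.orthography)
        kept.append(tok)
    return kept


def log_transform(values, offset: float = 0.001) -> np.ndarray:
    """Natural log of ``values + offset`` elementwise.

    The small offset keeps exact zeros (e.g. an epoch-initial ss_ws of 0 ms)
    finite on the log scale.  Negative inputs are rejected; NaNs pass through
    as missing values.
    """
    arr = np.asarray(values, dtype=float)
    if np.any(arr < 0):
        raise ValueError("log_transform requires non-negative values")
    return np.log(arr + offset)
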