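"""Compute the four word-complexity parameters for a handful of words.

Builds abstract phonological decompositions (C/V syllable templates), looks
up PoS-disambiguated lemma frequencies, and prints NoS, CVR, EoA and FRQ.
"""

from neurolex import (
    FrequencyLexicon,
    Syllable,
    WordType,
    consonant_vowel_ratio,
    count_syllables,
    ease_of_articulation,
    lookup_frequency,
)

lexicon = FrequencyLexicon(
    {
        ("sein", "verb"): 120.0,  # finite + non-finite verb forms
        ("sein", "pronoun"): 80.0,  # the possessive homograph stays separate
        ("haus", "noun"): 40.0,
        ("strumpf", "noun"): 2.0,
    }
)

words = [
    WordType("sein", "sein", "FV", (Syllable.from_template("CVVC"),)),
    WordType("haus", "haus", "NN", (Syllable.from_template("CVVC"),)),
    WordType("strumpf", "strumpf", "NN", (Syllable.from_template("CCCVCCC"),)),
]

print(f"{'word':>10} {'NoS':>4} {'CVR':>6} {'EoA':>6} {'FRQ':>6}")
for w in words:
    print(
        f"{w.orthography:>10} {count_syllables(w):>4} "
        f"{consonant_vowel_ratio(w):>6.2f} {ease_of_articulation(w):>6.2f} "
        f"{lookup_frequency(w.lemma, w.pos, lexicon):>6.0f}"
    )

# NoS counts syllables; CVR divides consonants by vowels ("strumpf" has six
# consonants around one vowel -> 6.0); EoA drops with clusters and gestures,
# so the articulatorily heavy "strumpf" scores lowest; FRQ is the lemma
# frequency for the word's own PoS class only.
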