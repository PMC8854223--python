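import numpy as np
import pytest

from neurolex import features, synth
from neurolex.features import Syllable, WordType


def make_word(
    templates=("CV",),
    pos="NN",
    orthography="word",
    lemma=None,
    stress_index=0,
    gesture_count=None,
):
    """Build a WordType from C/V syllable templates like ("CCV", "CVC")."""
    return WordType(
        orthography=orthography,
        lemma=lemma if lemma is not None else orthography,
        pos=pos,
        syllables=tuple(Syllable.from_template(t) for t in templates),
        stress_index=stress_index,
        gesture_count=gesture_count,
    )


@pytest.fixture(scope="session")
def small_lexicon():
    return synth.generate_lexicon(1200, zipf_exponent=1.0, seed=7)


@pytest.fixture(scope="session")
def small_discourse(small_lexicon):
    cfg = synth.DiscourseConfig(seed=3, n_tokens={"FV": 60, "NN": 40, "ADV": 40})
    return synth.generate_discourse(small_lexicon, cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
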