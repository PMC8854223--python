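"""Neurocorrelation with confound removal: the package's central analysis.

Injects a neural effect coupled only to syllable count (NoS), together with
an ease-of-articulation covariate that is strongly anticorrelated with NoS.
Before residualization both parameters correlate with the effect; after
residualization only the truly coupled one survives.
"""

import numpy as np
import pandas as pd

from neurolex import (
    DiscourseConfig,
    EffectSpec,
    SpectralConfig,
    bonferroni_test,
    compute_trial_spectra,
    generate_discourse,
    generate_lexicon,
    log_transform,
    neurocorrelate,
    parameter_correlation_matrix,
    residualize,
    select_content_words,
    synthesize_recording,
)
from neurolex.effects import extract_effects, match_pre_post
from neurolex.features import count_syllables, ease_of_articulation

lexicon = generate_lexicon(1200, seed=11)
discourse = generate_discourse(
    lexicon, DiscourseConfig(seed=11, n_tokens={"FV": 90, "NN": 60, "ADV": 60})
)
effect = EffectSpec(channel=3, parameter="NoS", band=(70.0, 110.0), r=0.6)
recording = synthesize_recording(discourse, [effect], n_channels=8, seed=11)

tokens = select_content_words(discourse.tokens)
table = pd.DataFrame(
    {
        "NoS": log_transform([count_syllables(t.word) for t in tokens]),
        "EoA": log_transform([ease_of_articulation(t.word) for t in tokens]),
    }
)
corr = parameter_correlation_matrix(table)
print(f"r(NoS, EoA) = {corr.r.loc['NoS', 'EoA']:+.2f}  (the confound)")

spectra = compute_trial_spectra(
    recording, [t.onset for t in tokens], SpectralConfig(f_max=150.0)
)

effects = {}
for label, values in [
    ("NoS pre", table["NoS"]),
    ("EoA pre", table["EoA"]),
    ("NoS post", residualize(table, "NoS", corr=corr)[0]),
    ("EoA post", residualize(table, "EoA", corr=corr)[0]),
]:
    cmap = neurocorrelate(spectra, np.asarray(values), label)
    mask = bonferroni_test(cmap, q=0.05)
    effects[label] = extract_effects(mask, cmap)
    where = {(e.channel, e.band, e.sign) for e in effects[label]}
    print(f"{label:>9}: {len(effects[label])} effect cluster(s) {where or ''}")

matches = match_pre_post(effects["NoS pre"], effects["NoS post"])
print(f"NoS pre/post matches: {sum(m.matched for m in matches)}")

# Pre-residualization, EoA inherits a spurious gamma effect at the injected
# channel purely through its collinearity with NoS.  Residualization removes
# it while the genuine NoS effect persists in the same band with the same
# sign — the qualitative signature of parameter-specific coupling.
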