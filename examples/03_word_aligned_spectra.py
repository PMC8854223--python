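"""Word-aligned log RSM spectra and the baseline-change group test.

Synthesizes a small recording with one injected gamma effect, re-references
it, cuts word-aligned trials, computes multitaper log relative spectral
magnitudes and tests every bin against "no change from baseline".
"""

import numpy as np

from neurolex import (
    DiscourseConfig,
    EffectSpec,
    SpectralConfig,
    common_average_reference,
    compute_trial_spectra,
    generate_discourse,
    generate_lexicon,
    rsm_group_test,
    select_content_words,
    synthesize_recording,
)

lexicon = generate_lexicon(800, seed=5)
discourse = generate_discourse(
    lexicon, DiscourseConfig(seed=5, n_tokens={"FV": 40, "NN": 30, "ADV": 30})
)
effect = EffectSpec(channel=2, parameter="NoS", band=(70.0, 110.0), r=0.5)
recording = synthesize_recording(discourse, [effect], n_channels=4, seed=5)

rec = common_average_reference(recording)
tokens = select_content_words(discourse.tokens)
spectra = compute_trial_spectra(
    rec, [t.onset for t in tokens], SpectralConfig(f_max=150.0)
)
print(
    f"log RSM tensor: {spectra.log_rsm.shape} "
    "(trials x channels x frequency x time)"
)
print(f"frequency bins every {spectra.freqs[1] - spectra.freqs[0]:.2f} Hz")

p, mask = rsm_group_test(spectra, q=0.05)
for ch, name in enumerate(spectra.channel_names):
    sig = mask[ch]
    if sig.any():
        fi, ti = np.nonzero(sig)
        print(
            f"{name}: {sig.sum()} significant bins, "
            f"{spectra.freqs[fi.min()]:.0f}-{spectra.freqs[fi.max()]:.0f} Hz, "
            f"{spectra.times[ti.min()]:+.2f}..{spectra.times[ti.max()]:+.2f} s"
        )
    else:
        print(f"{name}: no significant RSM change")

# The injected channel shows a word-locked gamma-band power increase around
# word onset; the FDR-corrected Wilcoxon test flags those bins, while the
# background-only channels stay (almost) empty.
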