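"""Canned ground-truth study scenarios for validation and calibration runs.

Each scenario builds a complete synthetic study under fixed conditions,
runs the analysis exactly as the pipeline would, and reports what was
recovered.  They are the package's standard evidence that the method works:

* :func:`recovery_run` — one CVR-coupled gamma effect (target r = 0.5,
  70-110 Hz) on channel 12 of 16, 200 word trials; did Bonferroni testing
  flag the injected channel and band with the right sign, and how close is
  the realized coupling?
* :func:`confound_run` — a neural effect coupled *only* to syllable count
  (NoS), with an ease-of-articulation covariate strongly anticorrelated with
  NoS; residualization should keep the NoS effect and remove the spurious
  EoA effect.
* :func:`sign_structure_run` — does the default generator reproduce the
  documented collinearity sign structure of spontaneous speech?
* :func:`null_calibration_run` — false-positive calibration of the per-bin
  correlation test and of the FDR-corrected signed-rank RSM test.
"""

from __future__ import annotations

import math
from dataclasses import replace
from typing import Mapping

import numpy as np
import pandas as pd

from . import features, neurocorr, pipeline, spectral, synth

__all__ = [
    "recovery_run",
    "confound_run",
    "sign_structure_run",
    "null_calibration_run",
]

#: Token counts drawn so that ~200 unique content words survive selection.
_RUN_TOKENS = {"FV": 90, "NN": 60, "ADV": 60}


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s % 2**31) for s in np.random.SeedSequence(seed).generate_state(n)]


def _band_average(sp: spectral.TrialSpectra, channel: int, band, window) -> np.ndarray:
    fsel = (sp.freqs >= band[0]) & (sp.freqs <= band[1])
    tsel = (sp.times >= window[0]) & (sp.times <= window[1])
    return sp.log_rsm[:, channel][:, fsel][:, :, tsel].mean(axis=(1, 2))


def _mask_in_band(mask: np.ndarray, cmap: neurocorr.CorrelationMap, channel, band):
    fsel = (cmap.freqs >= band[0] - 5.0) & (cmap.freqs <= band[1] + 5.0)
    return mask[channel][fsel]


def recovery_run(seed: int, n_trials: int = 200, n_channels: int = 16) -> dict:
    """Inject one CVR-coupled gamma effect and try to recover it.

    Returns detection flags (injected channel/band significant under
    Bonferroni with positive sign; any other channel significant = false
    positive) and the realized band-averaged coupling ``r_hat``.
    """
    s_lex, s_disc, s_rec = _child_seeds(seed, 3)
    lexicon = synth.generate_lexicon(1200, seed=s_lex)
    discourse = synth.generate_discourse(
        lexicon, synth.DiscourseConfig(seed=s_disc, n_tokens=_RUN_TOKENS)
    )
    effect = synth.EffectSpec(channel=12, parameter="CVR", band=(70.0, 110.0), r=0.5)
    recording = synth.synthesize_recording(
        discourse, [effect], n_channels=n_channels, seed=s_rec
    )

    tokens = features.select_content_words(discourse.tokens)[:n_trials]
    values = features.log_transform(
        [features.consonant_vowel_ratio(t.word) for t in tokens]
    )
    sp = spectral.compute_trial_spectra(
        recording, [t.onset for t in tokens], spectral.SpectralConfig(f_max=150.0)
    )
    cmap = neurocorr.neurocorrelate(sp, values, "CVR")
    mask = neurocorr.bonferroni_test(cmap, q=0.05)

    in_band = _mask_in_band(mask, cmap, effect.channel, effect.band)
    sig_r = cmap.r[effect.channel][
        (cmap.freqs[:, None] >= effect.band[0] - 5.0)
        & (cmap.freqs[:, None] <= effect.band[1] + 5.0)
        & mask[effect.channel]
    ]
    other = [c for c in range(n_channels) if c != effect.channel]
    r_hat = float(
        np.corrcoef(
            _band_average(sp, effect.channel, effect.band, effect.probe_window), values
        )[0, 1]
    )
    return {
        "detected": bool(in_band.any()),
        "correct_sign": bool(in_band.any() and np.nanmean(sig_r) > 0),
        "false_positive": bool(mask[other].any()),
        "r_hat": r_hat,
        "n_trials": sp.n_trials,
    }


def confound_run(
    seed: int,
    n_trials: int = 200,
    n_channels: int = 8,
    confound_r: float = -0.75,
) -> dict:
    """NoS-coupled effect with an EoA covariate collinear with NoS.

    The neural effect is coupled only to the syllable count; the EoA column
    is constructed to anticorrelate with log NoS at ``confound_r``, the kind
    of collinearity the real parameters show.  Before residualization both
    parameters correlate with the effect bins; after residualization only
    NoS should.  Bonferroni at q = 0.05 decides "shows an effect".
    """
    s_lex, s_disc, s_rec, s_conf = _child_seeds(seed, 4)
    lexicon = synth.generate_lexicon(1200, seed=s_lex)
    discourse = synth.generate_discourse(
        lexicon, synth.DiscourseConfig(seed=s_disc, n_tokens=_RUN_TOKENS)
    )
    effect = synth.EffectSpec(channel=3, parameter="NoS", band=(70.0, 110.0), r=0.6)
    recording = synth.synthesize_recording(
        discourse, [effect], n_channels=n_channels, seed=s_rec
    )

    tokens = features.select_content_words(discourse.tokens)[:n_trials]
    nos_log = features.log_transform(
        [features.count_syllables(t.word) for t in tokens]
    )
    z = (nos_log - nos_log.mean()) / nos_log.std()
    rng = np.random.default_rng(s_conf)
    noise = rng.standard_normal(len(tokens))
    eoa_log = confound_r * z + math.sqrt(1 - confound_r**2) * noise
    table = pd.DataFrame({"NoS": nos_log, "EoA": eoa_log})

    sp = spectral.compute_trial_spectra(
        recording, [t.onset for t in tokens], spectral.SpectralConfig(f_max=150.0)
    )

    def significant(values: np.ndarray) -> bool:
        cmap = neurocorr.neurocorrelate(sp, values)
        mask = neurocorr.bonferroni_test(cmap, q=0.05)
        return bool(_mask_in_band(mask, cmap, effect.channel, effect.band).any())

    corr = neurocorr.parameter_correlation_matrix(table)
    resid_nos, _ = neurocorr.residualize(table, "NoS", corr=corr)
    resid_eoa, _ = neurocorr.residualize(table, "EoA", corr=corr)
    return {
        "confound_r": float(corr.r.loc["NoS", "EoA"]),
        "pre_nos": significant(table["NoS"].to_numpy()),
        "pre_eoa": significant(table["EoA"].to_numpy()),
        "post_nos": significant(resid_nos.to_numpy()),
        "post_eoa": significant(resid_eoa.to_numpy()),
    }


#: The five reproducible sign relations of the collinearity structure.
SIGN_EXPECTATIONS = {
    ("EoA", "FRQ"): 1,
    ("EoA", "NoS"): -1,
    ("FRQ", "NoS"): -1,
    ("CVR", "NoS"): -1,
    ("NoS", "ws_we"): 1,
}


def sign_structure_run(seed: int) -> dict:
    """Check the generated parameter table against the expected sign pattern."""
    s_lex, s_disc = _child_seeds(seed, 2)
    lexicon = synth.generate_lexicon(1200, seed=s_lex)
    discourse = synth.generate_discourse(lexicon, synth.DiscourseConfig(seed=s_disc))
    table = pipeline.parameter_table(discourse)
    corr = neurocorr.parameter_correlation_matrix(table)
    signs = {
        pair: int(np.sign(corr.r.loc[pair[0], pair[1]]))
        for pair in SIGN_EXPECTATIONS
    }
    return {
        "signs": signs,
        "all_match": all(signs[p] == s for p, s in SIGN_EXPECTATIONS.items()),
    }


def null_calibration_run(
    seed: int,
    n_permutations: int = 100,
    n_reps: int = 200,
    alpha: float = 0.05,
    q: float = 0.05,
) -> dict:
    """False-positive calibration under null data.

    Permutation null: a parameter permuted across trials should reach
    uncorrected p < alpha in about alpha of the bins.  Signed-rank null:
    log RSM drawn symmetric around zero should keep the FDR-corrected
    false-discovery proportion at or below q on average.
    """
    s_perm, s_wil, s_spec = _child_seeds(seed, 3)

    rng = np.random.default_rng(s_spec)
    sp = spectral.TrialSpectra(
        log_rsm=rng.standard_normal((80, 2, 12, 40)),
        freqs=5.0 * np.arange(1, 13),
        times=0.02 * np.arange(40),
        trial_ids=np.arange(80),
        channel_names=["a", "b"],
    )
    values = rng.standard_normal(80)
    perm_rng = np.random.default_rng(s_perm)
    fracs = []
    for _ in range(n_permutations):
        cmap = neurocorr.neurocorrelate(sp, perm_rng.permutation(values))
        fracs.append(float((cmap.p < alpha).mean()))
    perm_rate = float(np.mean(fracs))

    wil_rng = np.random.default_rng(s_wil)
    fdp = []
    for _ in range(n_reps):
        x = wil_rng.standard_normal((30, 1, 10, 40))
        _, mask = spectral.rsm_group_test(x, q=q)
        n_disc = int(mask.sum())
        fdp.append(0.0 if n_disc == 0 else 1.0)  # every discovery is false
    return {
        "perm_rate": perm_rate,
        "alpha": alpha,
        "fdp_mean": float(np.mean(fdp)),
        "q": q,
        "n_permutations": n_permutations,
        "n_reps": n_reps,
    }
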