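"""Synthetic spontaneous-speech corpora with ground-truth neural coupling.

No public corpus of word-annotated intracranial recordings of spontaneous
speech exists, so every downstream stage is exercised on generated data with
known ground truth.  Three generators emulate the statistical structure the
analysis assumes:

* :func:`generate_lexicon` — a Zipfian lexicon of abstract C*VC* words whose
  phonological make-up is coupled to frequency rank so that the documented
  collinearity signs emerge (frequent words have fewer syllables, fewer
  clusters and initial stress, hence a higher ease-of-articulation score).
* :func:`generate_discourse` — pause-delimited speech-production epochs of
  word tokens with durations increasing in syllable count and a tendency for
  longer, rarer words to occur later in an epoch.
* :func:`synthesize_recording` — multichannel 1/f background noise with
  band-limited bursts locked to word onsets on designated channels, whose
  amplitudes are modulated by a named linguistic parameter and calibrated so
  the realized correlation between band-averaged log relative spectral
  magnitude and the (log) parameter approximates a requested Pearson r.
  Channels named in no effect carry no word-locked coupling.

Everything is deterministic under a fixed seed.  German phonology is *not*
simulated: only counts and ratios enter the analysis, so syllables are
abstract consonant/vowel templates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import features, spectral, timeline
from .features import EoAWeights, FrequencyLexicon, Syllable, WordType
from .timeline import PAUSE_THRESHOLD, InvalidAnnotationError, TimedToken

__all__ = [
    "Lexicon",
    "DiscourseConfig",
    "AnnotatedDiscourse",
    "EffectSpec",
    "Covariates",
    "generate_lexicon",
    "generate_discourse",
    "synthesize_covariates",
    "synthesize_recording",
    "token_parameter_values",
]

_CONSONANTS = "bdfgklmnprstvz"
_VOWELS = "aeiou"

#: Corpus size the Zipfian frequencies are normalized to (counts per corpus).
CORPUS_SIZE = 1_000_000.0

#: PoS tag probabilities of generated lexical entries.
_POS_PROBS = {
    "FV": 0.30,
    "NN": 0.30,
    "ADV": 0.18,
    "ADJD": 0.10,
    "PWAV": 0.05,
    "PAV": 0.07,
}


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class Lexicon:
    """Generated lexical entries with their Zipfian frequencies."""

    entries: list[WordType]
    frequencies: dict[tuple[str, str], float]  # (lemma, pos) -> frequency
    zipf_exponent: float
    seed: int

    def __post_init__(self) -> None:
        if len({(w.lemma, w.pos) for w in self.entries}) != len(self.entries):
            raise ValueError("(lemma, PoS) pairs must be unique")
        if any(f <= 0 for f in self.frequencies.values()):
            raise ValueError("lemma frequencies must be strictly positive")

    def frequency_of(self, word: WordType) -> float:
        return self.frequencies[(word.lemma, word.pos)]

    def frequency_lexicon(self) -> FrequencyLexicon:
        """The (lemma, PoS class) frequency table used for FRQ lookups."""
        lex = FrequencyLexicon()
        for (lemma, pos), freq in self.frequencies.items():
            lex.add(lemma, pos, freq)
        return lex

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for w in self.entries:
            rows.append(
                {
                    "orthography": w.orthography,
                    "lemma": w.lemma,
                    "pos": w.pos,
                    "syllables": ".".join(s.as_template() for s in w.syllables),
                    "stress_index": w.stress_index,
                    "frequency": self.frequencies[(w.lemma, w.pos)],
                }
            )
        return pd.DataFrame(rows)


def _make_orthography(syllables: Sequence[Syllable], rng: np.random.Generator) -> str:
    out = []
    for s in syllables:
        out.append("".join(rng.choice(list(_CONSONANTS), s.onset_consonants)))
        out.append("".join(rng.choice(list(_VOWELS), s.nucleus_vowels)))
        out.append("".join(rng.choice(list(_CONSONANTS), s.coda_consonants)))
    return "".join(out)


def generate_lexicon(
    n_words: int, zipf_exponent: float = 1.0, seed: int = 0
) -> Lexicon:
    """Generate a Zipfian lexicon with frequency-coupled phonology.

    Frequencies follow rank^(-zipf_exponent), normalized to a corpus of
    1e6 tokens.  Syllable structure is sampled conditional on (log) rank:
    rarer words get more syllables, more consonant clusters and more
    non-initial stress, which yields the expected sign structure — NoS and
    FRQ negatively related, EoA positively related to FRQ.
    """
    if n_words < 1:
        raise ValueError("n_words must be >= 1")
    if zipf_exponent <= 0:
        raise ValueError("zipf_exponent must be positive")
    rng = np.random.default_rng(seed)
    ranks = np.arange(1, n_words + 1, dtype=float)
    raw = ranks**-zipf_exponent
    freqs = raw * (CORPUS_SIZE / raw.sum())

    logr = np.log(ranks)
    z = (logr - logr.mean()) / logr.std() if n_words > 1 else np.zeros(1)

    pos_tags = rng.choice(
        list(_POS_PROBS), size=n_words, p=list(_POS_PROBS.values())
    )

    entries: list[WordType] = []
    frequencies: dict[tuple[str, str], float] = {}
    seen: set[str] = set()
    for i in range(n_words):
        u = 0.9 * z[i] + rng.standard_normal()
        nos = 1 + int(u > -0.35) + int(u > 1.15) + int(u > 2.7)
        syls = []
        for _ in range(nos):
            p_on2 = _sigmoid(-1.4 + 0.25 * z[i] - 1.1 * (nos - 1))
            v = rng.random()
            onset = 2 if v < p_on2 else (1 if v < 0.95 - 0.08 * (nos - 1) else 0)
            p_co2 = _sigmoid(-2.0 + 0.25 * z[i] - 1.0 * (nos - 1))
            v = rng.random()
            coda = 2 if v < p_co2 else (1 if v < 0.55 - 0.15 * (nos - 1) else 0)
            syls.append(Syllable(onset, 1, coda))
        stress = 0
        if nos > 1 and rng.random() < _sigmoid(-0.6 + 0.4 * z[i]):
            stress = int(rng.integers(1, nos))
        orth = _make_orthography(syls, rng)
        while orth in seen:
            orth += rng.choice(list(_VOWELS))
        seen.add(orth)
        word = WordType(
            orthography=orth,
            lemma=orth,
            pos=str(pos_tags[i]),
            syllables=tuple(syls),
            stress_index=stress,
        )
        entries.append(word)
        frequencies[(word.lemma, word.pos)] = float(freqs[i])
    return Lexicon(
        entries=entries,
        frequencies=frequencies,
        zipf_exponent=zipf_exponent,
        seed=seed,
    )


@dataclass(frozen=True)
class DiscourseConfig:
    """Shape of the generated discourse.

    Token counts per PoS category default to mid-range per-subject counts of
    the kind of spontaneous-speech corpus this emulates.  Within-epoch gaps
    stay below the 200 ms pause threshold; between-epoch pauses stay at or
    above it.  Word duration grows linearly with syllable count, and the
    ``order_bias`` makes longer/rarer words occur later within their epoch.
    """

    n_tokens: Mapping[str, int] = field(
        default_factory=lambda: {"FV": 190, "NN": 120, "ADV": 110}
    )
    seed: int = 0
    words_per_epoch: float = 6.0  # mean epoch length in words
    gap_range: tuple[float, float] = (0.06, 0.16)  # s, within-epoch gaps
    pause_range: tuple[float, float] = (0.30, 1.20)  # s, between-epoch pauses
    dur_base: float = 0.16  # s, word-duration intercept
    dur_per_syllable: float = 0.12  # s per syllable
    dur_sd: float = 0.04  # s, word-duration noise
    dur_min: float = 0.08  # s, floor
    order_bias: float = 1.0  # strength of the late-position bias
    duplicate_rate: float = 0.05  # fraction of tokens repeating an earlier word
    lead_in: float = 6.0  # s of silence before the first onset
    clause_split_min: int = 5  # epochs with >= this many words get 2 clauses

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.n_tokens.values()):
            raise ValueError("token counts per category must be positive")
        if not self.gap_range[1] < PAUSE_THRESHOLD <= self.pause_range[0]:
            raise ValueError(
                "gaps must stay below and pauses at/above the 200 ms threshold"
            )


@dataclass
class AnnotatedDiscourse:
    """Timed word tokens grouped into clauses and speech-production epochs."""

    tokens: list[TimedToken]
    epochs: list[tuple[float, float]]  # (ss, se)
    clauses: list[tuple[float, float]]  # (cs, ce)
    clause_epoch: list[int]  # enclosing epoch of each clause

    def __post_init__(self) -> None:
        # epoch construction invariants: no internal pause, real pauses between
        for i, tok in enumerate(self.tokens[1:], start=1):
            prev = self.tokens[i - 1]
            gap = tok.onset - prev.offset
            if gap < 0:
                raise InvalidAnnotationError("tokens overlap")
            if tok.epoch_id == prev.epoch_id and gap >= PAUSE_THRESHOLD:
                raise InvalidAnnotationError("pause of >= 200 ms inside a speech epoch")
            if tok.epoch_id != prev.epoch_id and gap < PAUSE_THRESHOLD:
                raise InvalidAnnotationError("gap between epochs shorter than 200 ms")

    def onsets(self) -> np.ndarray:
        return np.array([t.onset for t in self.tokens])

    def epoch_of(self, token: TimedToken) -> tuple[float, float]:
        return self.epochs[token.epoch_id]

    def clause_of(self, token: TimedToken) -> tuple[float, float]:
        return self.clauses[token.clause_id]

    def duration_table(self) -> pd.DataFrame:
        """Per-token duration parameters (ms), from the stored tags."""
        rows = []
        for t in self.tokens:
            d = timeline.duration_parameters(
                (t.onset, t.offset), self.epoch_of(t), self.clause_of(t)
            )
            rows.append({"token_id": t.token_id, **d.__dict__})
        return pd.DataFrame(rows).set_index("token_id")


def generate_discourse(
    lexicon: Lexicon, config: DiscourseConfig = DiscourseConfig()
) -> AnnotatedDiscourse:
    """Lay out word tokens in pause-delimited epochs with realistic timing.

    Tokens are drawn per PoS category from the lexicon, weighted by
    frequency (mostly without replacement; a small fraction repeats earlier
    words).  Epoch membership is random, but within each epoch tokens are
    ordered by a noisy complexity score so that longer and rarer words tend
    to come later — reproducing the positive ss_ws-NoS and negative
    ss_ws-FRQ tendencies of spontaneous speech.
    """
    if not lexicon.entries:
        raise ValueError("lexicon must be non-empty")
    rng = np.random.default_rng(config.seed)

    by_cat: dict[str, list[WordType]] = {"FV": [], "NN": [], "ADV": []}
    for w in lexicon.entries:
        by_cat[features.pos_category(w.pos)].append(w)

    chosen: list[WordType] = []
    for cat, n in config.n_tokens.items():
        pool = by_cat.get(cat, [])
        if len(pool) < n:
            raise ValueError(
                f"lexicon has only {len(pool)} {cat} entries; {n} requested"
            )
        p = np.array([lexicon.frequency_of(w) for w in pool])
        idx = rng.choice(len(pool), size=n, replace=False, p=p / p.sum())
        chosen.extend(pool[i] for i in idx)
        n_dup = int(config.duplicate_rate * n)
        if n_dup:
            dups = rng.choice(idx, size=n_dup, replace=True)
            chosen.extend(pool[i] for i in dups)

    order = rng.permutation(len(chosen))
    chosen = [chosen[i] for i in order]

    # epoch membership, then a complexity-biased order within each epoch
    sizes: list[int] = []
    left = len(chosen)
    while left > 0:
        s = 1 + rng.poisson(max(config.words_per_epoch - 1.0, 0.0))
        sizes.append(min(s, left))
        left -= sizes[-1]

    nos = np.array([features.count_syllables(w) for w in chosen], dtype=float)
    rare = -np.log([lexicon.frequency_of(w) for w in chosen])
    z = lambda a: (a - a.mean()) / a.std() if a.std() > 0 else np.zeros_like(a)
    score = config.order_bias * (z(nos) + 0.5 * z(rare)) + rng.standard_normal(
        len(chosen)
    )

    tokens: list[TimedToken] = []
    epochs: list[tuple[float, float]] = []
    clauses: list[tuple[float, float]] = []
    clause_epoch: list[int] = []
    t = config.lead_in
    pos0 = 0
    tid = 0
    for size in sizes:
        members = np.arange(pos0, pos0 + size)
        members = members[np.argsort(score[members], kind="stable")]
        pos0 += size
        ep_id = len(epochs)
        ep_tokens: list[TimedToken] = []
        for k, i in enumerate(members):
            w = chosen[i]
            dur = max(
                config.dur_min,
                config.dur_base
                + config.dur_per_syllable * nos[i]
                + config.dur_sd * rng.standard_normal(),
            )
            ep_tokens.append(
                TimedToken(
                    token_id=tid,
                    word=w,
                    onset=round(t, 6),
                    offset=round(t + dur, 6),
                    epoch_id=ep_id,
                    clause_id=0,  # assigned below
                    frequency=lexicon.frequency_of(w),
                )
            )
            tid += 1
            t += dur
            if k < size - 1:
                t += rng.uniform(*config.gap_range)
        t += rng.uniform(*config.pause_range)
        epochs.append((ep_tokens[0].onset, ep_tokens[-1].offset))

        # clauses: long epochs split once at a random word boundary
        if size >= config.clause_split_min:
            cut = int(rng.integers(2, size - 1))
            groups = [ep_tokens[:cut], ep_tokens[cut:]]
        else:
            groups = [ep_tokens]
        for g in groups:
            cid = len(clauses)
            clauses.append((g[0].onset, g[-1].offset))
            clause_epoch.append(ep_id)
            for j, tok in enumerate(g):
                g[j] = TimedToken(
                    token_id=tok.token_id,
                    word=tok.word,
                    onset=tok.onset,
                    offset=tok.offset,
                    epoch_id=ep_id,
                    clause_id=cid,
                    frequency=tok.frequency,
                )
        tokens.extend(tok for g in groups for tok in g)

    return AnnotatedDiscourse(
        tokens=tokens, epochs=epochs, clauses=clauses, clause_epoch=clause_epoch
    )


def token_parameter_values(
    discourse: AnnotatedDiscourse,
    parameter: str,
    weights: EoAWeights = EoAWeights(),
) -> np.ndarray:
    """Raw (pre-log) per-token values of one linguistic parameter."""
    toks = discourse.tokens
    if parameter == "NoS":
        return np.array([features.count_syllables(t.word) for t in toks], float)
    if parameter == "CVR":
        return np.array([features.consonant_vowel_ratio(t.word) for t in toks])
    if parameter == "EoA":
        return np.array(
            [features.ease_of_articulation(t.word, weights) for t in toks]
        )
    if parameter == "FRQ":
        return np.array([t.frequency for t in toks])
    if parameter in ("ss_ws", "ws_we", "we_se"):
        out = []
        for t in toks:
            d = timeline.duration_parameters(
                (t.onset, t.offset), discourse.epoch_of(t), discourse.clause_of(t)
            )
            out.append(getattr(d, parameter))
        return np.array(out)
    raise ValueError(
        f"cannot derive parameter {parameter!r} from the discourse alone; "
        "pass its values explicitly"
    )


@dataclass(frozen=True)
class EffectSpec:
    """Ground truth for one injected word-locked neural effect.

    ``r`` is the target Pearson correlation, across words, between the
    band-and-window-averaged log relative spectral magnitude at ``channel``
    and the log-transformed parameter; ``sign`` sets its direction.  The
    modulation is applied over ``window`` but its target correlation is
    evaluated over the slightly wider ``probe_window`` of the analysis bins.
    """

    channel: int
    parameter: str
    band: tuple[float, float] = (70.0, 110.0)
    window: tuple[float, float] = (0.05, 0.35)  # s relative to word onset
    r: float = 0.5
    sign: int = 1

    @property
    def probe_window(self) -> tuple[float, float]:
        return (self.window[0] - 0.05, self.window[1] + 0.05)

    def __post_init__(self) -> None:
        if not 0 < self.band[0] < self.band[1] < 512:
            raise ValueError("effect band must lie within (0, 512) Hz")
        if not 0 < self.r < 1:
            raise ValueError("coupling strength must satisfy 0 < |r| < 1")
        if self.sign not in (-1, 1):
            raise ValueError("sign must be -1 or +1")
        if not -2.0 <= self.window[0] < self.window[1] <= 3.0:
            raise ValueError("effect window must lie within [-2, 3] s")


@dataclass
class Covariates:
    """Synthetic control covariates: per-token intensity and an EMG channel."""

    table: pd.DataFrame  # token_id, intensity_db
    emg: np.ndarray  # (n_emg_channels, samples)
    fs: float


def synthesize_covariates(
    discourse: AnnotatedDiscourse, seed: int = 0, fs: float = 1024.0
) -> Covariates:
    """Per-token acoustic intensity (dB) and a word-locked EMG channel.

    Intensity decreases with the word's distance from speech start (epoch-
    initial words are louder), emulating the declination of loudness over a
    speech epoch.  The EMG channel is broadband noise with mild 60-200 Hz
    bursts over each word.
    """
    if not discourse.tokens:
        raise ValueError("discourse must be non-empty")
    rng = np.random.default_rng(seed)
    ss_ws = np.array(
        [t.onset - discourse.epoch_of(t)[0] for t in discourse.tokens]
    )
    z = (ss_ws - ss_ws.mean()) / ss_ws.std() if ss_ws.std() > 0 else ss_ws * 0
    intensity = 66.0 - 1.2 * z + 1.8 * rng.standard_normal(len(ss_ws))
    intensity = np.clip(intensity, 40.0, None)
    table = pd.DataFrame(
        {
            "token_id": [t.token_id for t in discourse.tokens],
            "intensity_db": intensity,
        }
    )

    n = int(math.ceil((discourse.tokens[-1].offset + discourse.tokens[0].onset) * fs))
    emg = rng.standard_normal(n)
    burst_band = (60.0, 200.0)
    for t in discourse.tokens:
        i0, i1 = int(t.onset * fs), int(t.offset * fs)
        if i1 <= i0 or i1 > n:
            continue
        seg = _bandlimited_noise(i1 - i0, fs, burst_band, rng)
        emg[i0:i1] += (1.0 + 0.3 * rng.standard_normal()) * seg
    return Covariates(table=table, emg=emg[None, :], fs=fs)


# recording synthesis --------------------------------------------------------

def _one_over_f_noise(
    n: int, fs: float, exponent: float, rng: np.random.Generator
) -> np.ndarray:
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    shape = np.empty_like(f)
    shape[1:] = f[1:] ** (-exponent / 2.0)
    shape[0] = shape[1]
    x = np.fft.irfft(spec * shape, n)
    return x / x.std()


def _bandlimited_noise(
    m: int, fs: float, band: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance noise confined to a band, tapered at the edges."""
    seg = rng.standard_normal(m)
    spec = np.fft.rfft(seg)
    f = np.fft.rfftfreq(m, 1.0 / fs)
    spec[(f < band[0]) | (f > band[1])] = 0.0
    x = np.fft.irfft(spec, m)
    ramp = max(2, int(0.025 * fs))
    taper = np.ones(m)
    if 2 * ramp < m:
        edge = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
        taper[:ramp] = edge
        taper[-ramp:] = edge[::-1]
    x *= taper
    sd = x.std()
    return x / sd if sd > 0 else x


def _band_window_logrsm(
    sig: np.ndarray,
    fs: float,
    onsets: np.ndarray,
    band: tuple[float, float],
    window: tuple[float, float],
) -> np.ndarray:
    """Per-trial log RSM averaged over a band and a window (one channel)."""
    cfg = spectral.SpectralConfig(
        f_max=band[1] + 10.0, trial_window=(-2.0, window[1] + 0.3)
    )
    rec = spectral.Recording(sig[None, :], fs, [spectral.ChannelInfo("probe")])
    trials, kept = spectral.extract_trials(rec, onsets, cfg)
    if kept.size != onsets.size:
        raise ValueError("effect calibration needs all trials inside the recording")
    asm, freqs, times = spectral.multitaper_spectrogram(trials, fs, cfg)
    times = times + cfg.trial_window[0]
    log_rsm = spectral.baseline_correct(asm, times, cfg)
    fsel = (freqs >= band[0]) & (freqs <= band[1])
    tsel = (times >= window[0]) & (times <= window[1])
    return log_rsm[:, 0][:, fsel][:, :, tsel].mean(axis=(1, 2))


def _band_component(sig: np.ndarray, fs: float, band: tuple[float, float]) -> np.ndarray:
    """The signal's component inside a frequency band (FFT brick-wall)."""
    spec = np.fft.rfft(sig)
    f = np.fft.rfftfreq(sig.size, 1.0 / fs)
    return np.fft.irfft(np.where((f >= band[0]) & (f <= band[1]), spec, 0.0), sig.size)


def _window_taper(m: int, fs: float) -> np.ndarray:
    ramp = max(2, int(0.025 * fs))
    taper = np.ones(m)
    if 2 * ramp < m:
        edge = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
        taper[:ramp] = edge
        taper[-ramp:] = edge[::-1]
    return taper


def synthesize_recording(
    discourse: AnnotatedDiscourse,
    effects: Sequence[EffectSpec] = (),
    n_channels: int = 16,
    fs: float = 1024.0,
    seed: int = 0,
    noise_exponent: float = 1.0,
    effect_log_gain: float = 0.5,
    param_values: Mapping[str, Sequence[float]] | None = None,
    calibrate: bool = True,
    max_calibration_passes: int = 4,
) -> spectral.Recording:
    """Multichannel 1/f noise with parameter-coupled word-locked band gain.

    For each :class:`EffectSpec`, the background's own component inside the
    effect band is amplified (or suppressed) by a per-word gain over the
    effect window around each word onset.  The log amplitude gain is
    ``gain + beta * z`` with ``z`` the standardized, sign-flipped log
    parameter, so the word-wise band-averaged log relative spectral
    magnitude tracks the parameter linearly even into the heavy left tail
    the ``log(x + 0.001)`` transform produces for zero-valued parameters.
    ``beta`` is calibrated iteratively against the realized coupling: each
    pass measures the slope and residual noise of the band-averaged log RSM
    on the composite signal (which includes estimation noise and the
    baseline contamination by neighboring words in continuous speech) and
    rescales ``beta`` to the slope a correlation of ``r`` requires.  Channels
    not named in any effect carry no word-locked coupling.  Deterministic
    under ``seed``.
    """
    nyq = fs / 2.0
    for e in effects:
        if e.band[1] > nyq:
            raise ValueError(f"effect band {e.band} exceeds the Nyquist {nyq} Hz")
        if not 0 <= e.channel < n_channels:
            raise ValueError(f"effect channel {e.channel} outside 0..{n_channels - 1}")

    rng = np.random.default_rng(seed)
    onsets = discourse.onsets()
    n = int(math.ceil((discourse.tokens[-1].offset + discourse.tokens[0].onset) * fs))
    data = np.empty((n_channels, n))
    for ch in range(n_channels):
        data[ch] = _one_over_f_noise(n, fs, noise_exponent, rng)

    for e in effects:
        if param_values is not None and e.parameter in param_values:
            raw = np.asarray(param_values[e.parameter], dtype=float)
        else:
            raw = token_parameter_values(discourse, e.parameter)
        if raw.size != onsets.size:
            raise ValueError("parameter values must align with the tokens")
        logged = features.log_transform(raw)
        z = e.sign * (logged - logged.mean()) / logged.std()

        background = data[e.channel].copy()
        bandc = _band_component(background, fs, e.band)
        m = int(round((e.window[1] - e.window[0]) * fs))
        taper = _window_taper(m, fs)
        starts = np.round((onsets + e.window[0]) * fs).astype(int)

        def build(beta: float) -> np.ndarray:
            gain = np.exp(effect_log_gain + beta * z)
            composite = background.copy()
            for i, i0 in enumerate(starts):
                composite[i0 : i0 + m] += (gain[i] - 1.0) * taper * bandc[i0 : i0 + m]
            return composite

        target_ratio = e.r / math.sqrt(1.0 - e.r**2)
        sigma0 = float(
            np.std(_band_window_logrsm(background, fs, onsets, e.band, e.probe_window))
        )
        beta = sigma0 * target_ratio
        composite = build(beta)
        if calibrate:
            for _ in range(max_calibration_passes):
                L = _band_window_logrsm(composite, fs, onsets, e.band, e.probe_window)
                slope = float(np.polyfit(z, L, 1)[0])
                resid_sd = float(np.std(L - slope * z))
                r_hat = slope / math.hypot(slope, resid_sd)
                if abs(r_hat - e.r) < 0.015 or slope <= 0:
                    break
                beta *= resid_sd * target_ratio / slope
                composite = build(beta)
        data[e.channel] = composite

    channels = [spectral.ChannelInfo(name=f"ch{c:02d}") for c in range(n_channels)]
    return spectral.Recording(data=data, fs=fs, channels=channels)
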