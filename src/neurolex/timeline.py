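"""Speech timeline: tag model, epoch segmentation, duration covariates.

Every analyzed word token carries start/end tags (ws/we), and sits inside a
clause (cs/ce) and a pause-delimited speech-production epoch (ss/se).  A
speech-production epoch is a stretch of speech containing no pause of 200 ms
or longer.  Because epoch/clause tags were set manually in the original
annotation workflow, they may lag the word tags by a few milliseconds; the
post-hoc correction widens the enclosing unit so that ss <= cs <= ws < we <=
ce <= se always holds.

Duration parameters are reported in milliseconds (ss_ws, ws_we, we_se, cs_ce,
ss_cs, ce_se); covariates are the mean acoustic intensity in dB over the word
and the word-averaged log relative spectral magnitude of EMG activity in the
60-200 Hz band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .features import WordType

__all__ = [
    "InvalidAnnotationError",
    "TimedToken",
    "TagSet",
    "DurationSet",
    "PAUSE_THRESHOLD",
    "correct_tag_order",
    "segment_speech_epochs",
    "duration_parameters",
    "mean_intensity",
    "emg_band_rsm",
]

#: Pauses of at least this duration (s) end a speech-production epoch.
PAUSE_THRESHOLD = 0.2


class InvalidAnnotationError(ValueError):
    """Raised for annotation files or tag sets that violate the tag model."""


@dataclass(frozen=True)
class TimedToken:
    """A word token in the speech stream with its timing and lexical identity."""

    token_id: int
    word: WordType
    onset: float  # ws, s
    offset: float  # we, s
    clause_id: int = 0
    epoch_id: int = 0
    frequency: float = math.nan  # lemma frequency, carried from the lexicon

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise InvalidAnnotationError(
                f"token {self.token_id}: word end {self.offset} not after "
                f"word start {self.onset}"
            )

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass(frozen=True)
class TagSet:
    """One token's tags plus those of its enclosing clause and epoch (all s)."""

    ws: float
    we: float
    cs: float
    ce: float
    ss: float
    se: float


def correct_tag_order(tags: TagSet) -> TagSet:
    """Post-hoc correction of small manual tag-order inconsistencies.

    Word tags are trusted (they were set as precisely as possible); the
    enclosing clause and epoch are widened to contain them:
    ``cs := min(cs, ws)``, ``ce := max(ce, we)``, ``ss := min(ss, cs)``,
    ``se := max(se, ce)``.  Idempotent; consistent tags pass unchanged.
    """
    if tags.we <= tags.ws:
        raise InvalidAnnotationError("word end must lie after word start")
    cs = min(tags.cs, tags.ws)
    ce = max(tags.ce, tags.we)
    ss = min(tags.ss, cs)
    se = max(tags.se, ce)
    return replace(tags, cs=cs, ce=ce, ss=ss, se=se)


def segment_speech_epochs(
    tokens: Sequence[TimedToken] | Sequence[tuple[float, float]],
    pause_threshold: float = PAUSE_THRESHOLD,
) -> tuple[list[tuple[float, float]], list[int]]:
    """Group time-ordered tokens into pause-delimited speech epochs.

    A gap of ``pause_threshold`` (default 200 ms) **or more** between one
    token's offset and the next token's onset starts a new epoch.  Returns
    the epoch intervals (first onset, last offset) and the epoch index of
    every token.
    """
    ivals = [
        (t.onset, t.offset) if isinstance(t, TimedToken) else (float(t[0]), float(t[1]))
        for t in tokens
    ]
    if not ivals:
        return [], []
    epochs: list[tuple[float, float]] = []
    epoch_of: list[int] = []
    start, prev_end = ivals[0]
    epoch_of.append(0)
    for onset, offset in ivals[1:]:
        if onset < prev_end:
            raise InvalidAnnotationError(
                f"overlapping tokens: onset {onset} before previous offset {prev_end}"
            )
        # tolerance keeps a nominal 200 ms gap a pause despite float rounding
        if onset - prev_end >= pause_threshold - 1e-9:
            epochs.append((start, prev_end))
            start = onset
        epoch_of.append(len(epochs))
        prev_end = offset
    epochs.append((start, prev_end))
    return epochs, epoch_of


@dataclass(frozen=True)
class DurationSet:
    """Duration parameters of one token, in ms."""

    ss_ws: float
    ws_we: float
    we_se: float
    cs_ce: float
    ss_cs: float
    ce_se: float


def duration_parameters(
    token: tuple[float, float],
    epoch: tuple[float, float],
    clause: tuple[float, float] | None = None,
) -> DurationSet:
    """Compute the six duration parameters (ms) from corrected tags.

    ``token``/``epoch``/``clause`` are (start, end) intervals in s; a missing
    clause defaults to the epoch.
    """
    ws, we = token
    ss, se = epoch
    cs, ce = clause if clause is not None else epoch
    if not (ss <= ws and we <= se):
        raise InvalidAnnotationError(
            f"token [{ws}, {we}] outside its epoch [{ss}, {se}] — run "
            "correct_tag_order first"
        )
    return DurationSet(
        ss_ws=(ws - ss) * 1000.0,
        ws_we=(we - ws) * 1000.0,
        we_se=(se - we) * 1000.0,
        cs_ce=(ce - cs) * 1000.0,
        ss_cs=(cs - ss) * 1000.0,
        ce_se=(se - ce) * 1000.0,
    )


def mean_intensity(
    times: np.ndarray, values_db: np.ndarray, interval: tuple[float, float]
) -> float:
    """Mean acoustic intensity (dB) over a word interval.

    Arithmetic mean of the intensity-trace samples falling within
    [ws, we]; NaN (missing) if the interval does not overlap the trace.
    """
    times = np.asarray(times, dtype=float)
    values_db = np.asarray(values_db, dtype=float)
    lo, hi = interval
    sel = (times >= lo) & (times <= hi)
    if not np.any(sel):
        return math.nan
    return float(np.mean(values_db[sel]))


def emg_band_rsm(
    emg: np.ndarray,
    fs: float,
    interval: tuple[float, float],
    band: tuple[float, float] = (60.0, 200.0),
    cfg=None,
) -> float:
    """Word-averaged log relative spectral magnitude of an EMG channel.

    The EMG signal is analyzed exactly like the neural data: a trial is cut
    around the word onset, a multitaper spectrogram is computed, baseline
    correction uses the trial's own first 200 ms, and the resulting relative
    spectral magnitude is averaged over the band (default 60-200 Hz) and over
    the word interval [ws, we] before taking the natural log.  Returns NaN
    when the word is too close to the recording edge for a full trial.
    """
    from . import spectral

    if cfg is None:
        cfg = spectral.SpectralConfig(f_max=band[1] + 25.0)
    if band[1] > fs / 2:
        raise ValueError(f"EMG band {band} exceeds the Nyquist frequency {fs / 2}")
    ws, we = interval
    emg = np.asarray(emg, dtype=float)
    t0, t1 = cfg.trial_window
    i0 = int(round((ws + t0) * fs))
    i1 = i0 + cfg.trial_samples(fs)
    if i0 < 0 or i1 > emg.size:
        return math.nan
    trial = emg[None, i0:i1]
    asm, freqs, times = spectral.multitaper_spectrogram(trial, fs, cfg)
    log_rsm = spectral.baseline_correct(asm[None], times + t0, cfg)[0]
    fsel = (freqs >= band[0]) & (freqs <= band[1])
    tsel = (times + t0 + ws >= ws) & (times + t0 + ws <= we)
    if not fsel.any() or not tsel.any():
        return math.nan
    rsm = np.exp(log_rsm[0, fsel][:, tsel])
    return float(np.log(np.mean(rsm)))
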