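"""Significant time-frequency effects and their pre/post-residualization match.

A significance mask is reduced to *effect clusters*: 4-connected components
of significant bins within one channel's time-frequency plane.  Each cluster
carries its bounding time and frequency extents, the dominant sign of the
correlation inside it, and a band label — alpha (5-10 Hz), beta (15-30 Hz)
or gamma (above 35 Hz) by the midpoint of its frequency extent.

Two effects from the same subject count as "the same" when they sit on the
same channel, their time extents lie within 40 ms of each other, and they
share a frequency range — within 20 Hz of each other for gamma effects, or
inside the same alpha/beta band otherwise.  Extents are compared as
intervals (edge-to-edge gap, zero if overlapping), with inclusive bounds.
An effect found after residualization is confirmed when a pre-residualization
effect of the same parameter matches it under this rule with equal sign.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .neurocorr import CorrelationMap

logger = logging.getLogger(__name__)

__all__ = [
    "BANDS",
    "band_label",
    "EffectCluster",
    "EffectMatch",
    "extract_effects",
    "detect_overlap",
    "match_pre_post",
    "effects_to_frame",
]

#: Frequency bands used for the overlap rule (Hz).
BANDS = {"alpha": (5.0, 10.0), "beta": (15.0, 30.0), "gamma": (35.0, np.inf)}

#: Maximum edge-to-edge temporal distance between "the same" effects (s).
MAX_TIME_GAP = 0.040

#: Maximum edge-to-edge frequency distance within gamma (Hz).
MAX_GAMMA_FREQ_GAP = 20.0

_EPS = 1e-9


def band_label(freq: float) -> str | None:
    """Band containing a frequency, or None between/below the bands."""
    for name, (lo, hi) in BANDS.items():
        if lo <= freq <= hi:
            return name
    return None


@dataclass(frozen=True)
class EffectCluster:
    """One significant time-frequency region at one electrode."""

    channel: int
    t_start: float  # s, bin centers
    t_end: float
    f_low: float  # Hz, bin centers
    f_high: float
    sign: int  # sign of the mean r over the cluster
    band: str | None
    parameter: str = ""
    threshold: float | None = None  # most conservative threshold survived
    n_bins: int = 1
    bins: frozenset = field(default_factory=frozenset, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.sign not in (-1, 1):
            raise ValueError("cluster sign must be -1 or +1")
        if self.t_end < self.t_start or self.f_high < self.f_low:
            raise ValueError("cluster extents must be non-empty")


def extract_effects(
    mask: np.ndarray,
    cmap: CorrelationMap,
    min_bins: int = 1,
    threshold: float | None = None,
) -> list[EffectCluster]:
    """Connected components of significant bins, per channel.

    4-connectivity in the time x frequency plane (no diagonal adjacency).
    Each component becomes one cluster with bounding extents (bin centers),
    the sign of its mean r, and a band label from the midpoint of its
    frequency extent; components spanning a band boundary are labeled by
    that midpoint with a warning.
    """
    if mask.shape != cmap.r.shape:
        raise ValueError("mask and correlation map must share coordinates")
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    clusters: list[EffectCluster] = []
    for ch in range(mask.shape[0]):
        labels, n = ndimage.label(mask[ch], structure=structure)
        for lab in range(1, n + 1):
            fi, ti = np.nonzero(labels == lab)
            if fi.size < min_bins:
                continue
            f_low, f_high = cmap.freqs[fi.min()], cmap.freqs[fi.max()]
            mean_r = float(np.nanmean(cmap.r[ch, fi, ti]))
            band = band_label((f_low + f_high) / 2.0)
            if band_label(f_low) != band_label(f_high):
                logger.warning(
                    "cluster at channel %d spans a band boundary "
                    "(%g-%g Hz); labeled %r by its midpoint",
                    ch,
                    f_low,
                    f_high,
                    band,
                )
            clusters.append(
                EffectCluster(
                    channel=ch,
                    t_start=float(cmap.times[ti.min()]),
                    t_end=float(cmap.times[ti.max()]),
                    f_low=float(f_low),
                    f_high=float(f_high),
                    sign=1 if mean_r >= 0 else -1,
                    band=band,
                    parameter=cmap.parameter,
                    threshold=threshold,
                    n_bins=int(fi.size),
                    bins=frozenset(zip(fi.tolist(), ti.tolist())),
                )
            )
    return clusters


def _gap(a0: float, a1: float, b0: float, b1: float) -> float:
    """Edge-to-edge distance between two intervals; 0 if they overlap."""
    return max(0.0, max(a0, b0) - min(a1, b1))


def detect_overlap(a: EffectCluster, b: EffectCluster) -> bool:
    """Do two effects of one subject occupy "the same" time-frequency region?

    True iff same channel, time extents within 40 ms (inclusive), and either
    both gamma with frequency extents within 20 Hz, or both inside the same
    alpha/beta band.  Symmetric.
    """
    if a.channel != b.channel:
        return False
    if _gap(a.t_start, a.t_end, b.t_start, b.t_end) > MAX_TIME_GAP + _EPS:
        return False
    if a.band == "gamma" and b.band == "gamma":
        return _gap(a.f_low, a.f_high, b.f_low, b.f_high) <= MAX_GAMMA_FREQ_GAP + _EPS
    return a.band is not None and a.band == b.band


@dataclass(frozen=True)
class EffectMatch:
    """Pairing of a post-residualization effect with a pre-residualization one."""

    pre: EffectCluster | None
    post: EffectCluster | None
    matched: bool

    def __post_init__(self) -> None:
        if self.matched and (self.pre is None or self.post is None):
            raise ValueError("a match needs both effects")


def _canonical(effects: Sequence[EffectCluster]) -> list[EffectCluster]:
    return sorted(effects, key=lambda e: (e.channel, e.t_start, e.f_low, e.sign))


def match_pre_post(
    pre: Sequence[EffectCluster], post: Sequence[EffectCluster]
) -> list[EffectMatch]:
    """Match post-residualization effects against pre-residualization ones.

    A post effect is confirmed by the first (canonically ordered) unused pre
    effect that overlaps it (see :func:`detect_overlap`) with the same sign;
    each pre effect confirms at most one post effect.  Unmatched effects of
    either list are reported with ``matched=False``.  Output is sorted by
    channel and invariant to the input ordering.
    """
    pre_sorted = _canonical(pre)
    post_sorted = _canonical(post)
    used = [False] * len(pre_sorted)
    matches: list[EffectMatch] = []
    for po in post_sorted:
        hit = None
        for i, pr in enumerate(pre_sorted):
            if not used[i] and pr.sign == po.sign and detect_overlap(pr, po):
                hit = i
                break
        if hit is None:
            matches.append(EffectMatch(pre=None, post=po, matched=False))
        else:
            used[hit] = True
            matches.append(EffectMatch(pre=pre_sorted[hit], post=po, matched=True))
    for i, pr in enumerate(pre_sorted):
        if not used[i]:
            matches.append(EffectMatch(pre=pr, post=None, matched=False))
    return sorted(
        matches,
        key=lambda m: (
            (m.post or m.pre).channel,
            (m.post or m.pre).t_start,
            m.pre is None,
        ),
    )


def effects_to_frame(
    effects: Sequence[EffectCluster],
    subject: str = "",
    matched: Sequence[bool] | None = None,
) -> pd.DataFrame:
    """Tabulate effect clusters (the machine-readable effect report)."""
    rows = []
    for i, e in enumerate(effects):
        rows.append(
            {
                "subject": subject,
                "parameter": e.parameter,
                "channel": e.channel,
                "t_start": e.t_start,
                "t_end": e.t_end,
                "f_low": e.f_low,
                "f_high": e.f_high,
                "sign": e.sign,
                "band": e.band,
                "threshold": e.threshold,
                "n_bins": e.n_bins,
                "matched_pre_post": bool(matched[i]) if matched is not None else pd.NA,
            }
        )
    cols = [
        "subject",
        "parameter",
        "channel",
        "t_start",
        "t_end",
        "f_low",
        "f_high",
        "sign",
        "band",
        "threshold",
        "n_bins",
        "matched_pre_post",
    ]
    return pd.DataFrame(rows, columns=cols)
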