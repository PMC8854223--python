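"""Neurocorrelation: linguistic parameters vs. time-frequency neural power.

"Neurocorrelation" is the Pearson correlation, computed across trials (words)
separately for every channel and time-frequency bin, between the per-trial
log relative spectral magnitude and a per-trial linguistic parameter (both on
a natural-log scale).  Significance is controlled two ways:

* Bonferroni correction over all time-frequency bins and channels at
  q < 0.05 wherever it yields effects;
* otherwise a ladder of increasingly conservative uncorrected thresholds,
  capped at 5e-6: the most conservative threshold that still yields at least
  one significant bin is reported; uncorrected p-values above 5e-6 are never
  called significant.

Because complexity parameters of spontaneous speech are collinear, each
parameter can also be residualized: it is regressed (OLS with intercept) on
every parameter it is significantly correlated with, and the residuals —
orthogonal to those confounds — replace it in a second correlation pass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .spectral import TrialSpectra

logger = logging.getLogger(__name__)

__all__ = [
    "PARAMETERS",
    "CorrelationMap",
    "CorrelationMatrixResult",
    "ThresholdLadder",
    "parameter_correlation_matrix",
    "neurocorrelate",
    "bonferroni_test",
    "ladder_test",
    "residualize",
    "restrict_window",
]

#: Canonical parameter-table columns, in reporting order.
PARAMETERS = (
    "FRQ",
    "EoA",
    "CVR",
    "NoS",
    "ss_ws",
    "ws_we",
    "we_se",
    "intensity",
    "emg_rsm",
)

#: |r| above this is labeled a strong correlation.
STRONG_R = 0.4


@dataclass
class CorrelationMap:
    """Per-bin Pearson r and p of one parameter: channels x freq x time."""

    r: np.ndarray
    p: np.ndarray
    parameter: str
    n: int
    freqs: np.ndarray
    times: np.ndarray
    channel_names: list[str]

    def __post_init__(self) -> None:
        if self.r.shape != self.p.shape:
            raise ValueError("r and p must share a shape")


@dataclass
class CorrelationMatrixResult:
    """Pairwise Pearson structure of the linguistic parameters."""

    r: pd.DataFrame
    p: pd.DataFrame
    significant: pd.DataFrame  # p < alpha, uncorrected
    strong: pd.DataFrame  # |r| > 0.4
    n: pd.DataFrame  # complete cases per pair
    alpha: float


def parameter_correlation_matrix(
    table: pd.DataFrame, alpha: float = 0.05
) -> CorrelationMatrixResult:
    """Pairwise Pearson correlations over complete cases.

    Constant columns leave their pairs undefined (NaN, flagged
    non-significant); pairs with fewer than 3 complete rows likewise.
    Correlations with |r| > 0.4 are labeled strong.
    """
    cols = list(table.columns)
    k = len(cols)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    np.fill_diagonal(r, 1.0)
    np.fill_diagonal(p, 0.0)
    for i, j in combinations(range(k), 2):
        x = table[cols[i]].to_numpy(dtype=float)
        y = table[cols[j]].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        n[i, j] = n[j, i] = int(ok.sum())
        if ok.sum() < 3:
            continue
        if np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
            logger.warning(
                "constant column leaves r(%s, %s) undefined", cols[i], cols[j]
            )
            continue
        res = stats.pearsonr(x[ok], y[ok])
        r[i, j] = r[j, i] = res.statistic
        p[i, j] = p[j, i] = res.pvalue
    np.fill_diagonal(n, len(table))
    as_df = lambda a: pd.DataFrame(a, index=cols, columns=cols)
    with np.errstate(invalid="ignore"):
        sig = (p < alpha) & ~np.isnan(p)
        strong = (np.abs(r) > STRONG_R) & ~np.isnan(r)
    return CorrelationMatrixResult(
        r=as_df(r),
        p=as_df(p),
        significant=as_df(sig),
        strong=as_df(strong),
        n=as_df(n),
        alpha=alpha,
    )


def _pearson_map(x: np.ndarray, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r and two-sided p of ``values`` against the trial axis of x."""
    n = values.size
    z = values - values.mean()
    sz = np.sqrt((z**2).sum())
    xc = x - x.mean(axis=0)
    sx = np.sqrt((xc**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.einsum("t,t...->...", z, xc) / (sz * sx)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) == 1.0, 0.0, p)
    bad = sx == 0
    if np.any(bad):
        logger.warning("%d zero-variance bins flagged missing", int(bad.sum()))
        r = np.where(bad, np.nan, r)
        p = np.where(bad, np.nan, p)
    return r, p


def neurocorrelate(trials: TrialSpectra, values: Sequence[float], parameter: str = "") -> CorrelationMap:
    """Correlate a per-trial parameter with log RSM in every bin.

    ``values`` must align with the trial axis and already be on the natural
    log scale (see :func:`neurolex.features.log_transform`).  Trials with a
    missing parameter value are dropped pairwise.  Bins with zero variance
    across trials are flagged missing (NaN).
    """
    values = np.asarray(values, dtype=float)
    if values.size != trials.n_trials:
        raise ValueError(
            f"parameter length {values.size} != trial count {trials.n_trials}"
        )
    ok = np.isfinite(values)
    x = trials.log_rsm[ok]
    r, p = _pearson_map(x, values[ok])
    return CorrelationMap(
        r=r,
        p=p,
        parameter=parameter,
        n=int(ok.sum()),
        freqs=trials.freqs,
        times=trials.times,
        channel_names=trials.channel_names,
    )


def bonferroni_test(
    cmap: CorrelationMap, q: float = 0.05, m: int | None = None
) -> np.ndarray:
    """Bonferroni mask over all channels x frequency x time bins: p < q/m."""
    if m is None:
        m = cmap.p.size
    with np.errstate(invalid="ignore"):
        return cmap.p < q / m


@dataclass(frozen=True)
class ThresholdLadder:
    """Descending uncorrected significance thresholds, capped at 5e-6.

    The default descends geometrically from the 5e-6 cap; no uncorrected
    p-value above the cap is ever called significant.
    """

    thresholds: tuple[float, ...] = tuple(5e-6 * 0.1**k for k in range(12))
    cap: float = 5e-6

    def __post_init__(self) -> None:
        t = self.thresholds
        if not t or any(b >= a for a, b in zip(t, t[1:])):
            raise ValueError("thresholds must be strictly decreasing")
        if t[0] > self.cap:
            raise ValueError(f"thresholds must not exceed the cap {self.cap}")


def ladder_test(
    cmap: CorrelationMap, ladder: ThresholdLadder = ThresholdLadder()
) -> tuple[float | None, np.ndarray]:
    """Most conservative ladder threshold still yielding significant bins.

    Walks the thresholds from least to most conservative and returns the last
    (smallest) threshold at which at least one bin has p <= threshold,
    together with its mask.  If nothing passes even the 5e-6 cap, no effect
    is reported: ``(None, all-False mask)``.
    """
    reported: float | None = None
    mask = np.zeros(cmap.p.shape, dtype=bool)
    with np.errstate(invalid="ignore"):
        for thr in ladder.thresholds:
            m = cmap.p <= thr
            if not m.any():
                break
            reported, mask = thr, m
    return reported, mask


def residualize(
    table: pd.DataFrame,
    target: str,
    alpha: float = 0.05,
    corr: CorrelationMatrixResult | None = None,
) -> tuple[pd.Series, list[str]]:
    """Replace a parameter by the residuals of its regression on its confounds.

    The target column is regressed (OLS, with intercept) on every other
    column it is significantly correlated with (pairwise Pearson p < alpha,
    uncorrected).  Returns the residual series — orthogonal to all selected
    predictors — aligned to the table index (NaN for incomplete rows), and
    the predictor names used.  With no significant confounds the residual is
    the mean-centered target.  Rank-deficient predictor sets are pruned in
    column order, with a log message.
    """
    if target not in table.columns:
        raise KeyError(f"target {target!r} not in table")
    if corr is None:
        corr = parameter_correlation_matrix(table, alpha=alpha)
    predictors = [
        c for c in table.columns if c != target and bool(corr.significant.loc[target, c])
    ]
    y = table[target].to_numpy(dtype=float)
    X = table[predictors].to_numpy(dtype=float) if predictors else np.empty((len(table), 0))
    ok = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    if ok.sum() < len(predictors) + 2:
        raise ValueError("too few complete rows for the residualization model")
    # prune collinear predictors in column order
    kept_idx: list[int] = []
    for j in range(len(predictors)):
        trial_cols = kept_idx + [j]
        M = np.column_stack([np.ones(int(ok.sum()))] + [X[ok, c] for c in trial_cols])
        if np.linalg.matrix_rank(M) == M.shape[1]:
            kept_idx.append(j)
        else:
            logger.warning(
                "dropping collinear predictor %r from the %r model",
                predictors[j],
                target,
            )
    used = [predictors[j] for j in kept_idx]
    design = sm.add_constant(X[ok][:, kept_idx], has_constant="add")
    fit = sm.OLS(y[ok], design).fit()
    resid = pd.Series(np.nan, index=table.index, name=target)
    resid.iloc[np.flatnonzero(ok)] = fit.resid
    return resid, used


def restrict_window(
    trials: TrialSpectra,
    speech_bounds: tuple[Sequence[float], Sequence[float]] | tuple[float, float],
    margin: float = 0.5,
    f_max: float = 150.0,
) -> TrialSpectra:
    """Focalize spectra to the speech epoch and to frequencies <= f_max.

    ``speech_bounds`` gives the speech start and end relative to word onset —
    either per-trial sequences (averaged across trials, so every bin keeps
    the same trial count) or a single (ss, se) pair.  Time bins are kept in
    [mean ss - margin, mean se + margin], clipped to the trial window, and
    frequency bins above ``f_max`` are dropped.
    """
    if margin < 0:
        raise ValueError("margin must be non-negative")
    ss, se = speech_bounds
    lo = float(np.mean(ss)) - margin
    hi = float(np.mean(se)) + margin
    fsel = trials.freqs <= f_max + 1e-9
    tsel = (trials.times >= lo - 1e-9) & (trials.times <= hi + 1e-9)
    if not fsel.any() or not tsel.any():
        raise ValueError("window restriction leaves no bins")
    return TrialSpectra(
        log_rsm=trials.log_rsm[:, :, fsel][:, :, :, tsel],
        freqs=trials.freqs[fsel],
        times=trials.times[tsel],
        trial_ids=trials.trial_ids,
        channel_names=trials.channel_names,
    )
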