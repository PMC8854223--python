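"""End-to-end pipeline: synthesis -> features -> spectra -> correlation -> effects.

The pipeline reproduces the full analysis chain on synthetic data with known
ground truth: generate a lexicon and discourse, synthesize covariates and the
multichannel recording, select content words and build the log-transformed
parameter table, compute word-aligned log RSM spectra, test them against
baseline, correlate every parameter with every time-frequency bin before and
after residualization, reduce the significance masks to effect clusters and
match them across the two passes.  A fixed config and seed reproduce every
numeric output exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import effects as fx
from . import features, io, neurocorr, spectral, synth, timeline

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ResultsBundle", "parameter_table", "run_pipeline", "report"]


@dataclass(frozen=True)
class PipelineConfig:
    """Every knob of a synthetic end-to-end run, with analysis defaults.

    Analysis defaults follow the primary setting: 0.2 s / 0.02 s multitaper
    windows with 5 tapers, [-2, 3] s trials, [-2, -1.8] s baseline, FDR and
    Bonferroni at q = 0.05, Pearson alpha = 0.05, log offset 0.001, 200 ms
    pause rule, |r| > 0.4 strong-correlation cut, 5e-6 ladder cap.
    """

    seed: int = 0
    n_lexicon: int = 1200
    zipf_exponent: float = 1.0
    n_channels: int = 16
    fs: float = 1024.0
    discourse: synth.DiscourseConfig = field(default_factory=synth.DiscourseConfig)
    effects: tuple[synth.EffectSpec, ...] = ()
    spectral: spectral.SpectralConfig = field(default_factory=spectral.SpectralConfig)
    ladder: neurocorr.ThresholdLadder = field(default_factory=neurocorr.ThresholdLadder)
    eoa_weights: features.EoAWeights = field(default_factory=features.EoAWeights)
    alpha: float = 0.05
    q: float = 0.05
    focalize: bool = True  # restrict neurocorrelation to the speech window
    focal_margin: float = 0.5  # s around mean speech start/end
    focal_f_max: float = 150.0  # Hz
    parameters: tuple[str, ...] = neurocorr.PARAMETERS
    include_emg: bool = True

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _corrected_token_bounds(
    disc: synth.AnnotatedDiscourse,
) -> list[timeline.TagSet]:
    out = []
    for t in disc.tokens:
        cs, ce = disc.clause_of(t)
        ss, se = disc.epoch_of(t)
        out.append(
            timeline.correct_tag_order(
                timeline.TagSet(ws=t.onset, we=t.offset, cs=cs, ce=ce, ss=ss, se=se)
            )
        )
    return out


def parameter_table(
    discourse: synth.AnnotatedDiscourse,
    covariates: synth.Covariates | None = None,
    weights: features.EoAWeights = features.EoAWeights(),
    spectral_cfg: spectral.SpectralConfig | None = None,
    tokens: Sequence[timeline.TimedToken] | None = None,
) -> pd.DataFrame:
    """Per-token linguistic parameters, log-transformed, indexed by token id.

    Columns: FRQ, EoA, CVR, NoS, ss_ws, ws_we, we_se and — when covariates
    are given — intensity and emg_rsm.  All values pass through
    ``log(x + 0.001)``; EMG enters as the pre-log band-averaged relative
    spectral magnitude so that the shared transform applies to it as well.
    Tokens default to the content-word selection of the discourse.
    """
    if tokens is None:
        tokens = features.select_content_words(discourse.tokens)
    tags = {
        t.token_id: timeline.correct_tag_order(
            timeline.TagSet(
                ws=t.onset,
                we=t.offset,
                cs=discourse.clause_of(t)[0],
                ce=discourse.clause_of(t)[1],
                ss=discourse.epoch_of(t)[0],
                se=discourse.epoch_of(t)[1],
            )
        )
        for t in tokens
    }
    rows = {}
    for t in tokens:
        tg = tags[t.token_id]
        d = timeline.duration_parameters(
            (tg.ws, tg.we), (tg.ss, tg.se), (tg.cs, tg.ce)
        )
        rows[t.token_id] = {
            "FRQ": t.frequency,
            "EoA": features.ease_of_articulation(t.word, weights),
            "CVR": features.consonant_vowel_ratio(t.word),
            "NoS": features.count_syllables(t.word),
            "ss_ws": d.ss_ws,
            "ws_we": d.ws_we,
            "we_se": d.we_se,
        }
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()

    if covariates is not None:
        intensity = covariates.table.set_index("token_id")["intensity_db"]
        df["intensity"] = intensity.reindex(df.index)
        emg_cfg = spectral_cfg or spectral.SpectralConfig(f_max=225.0)
        emg_cfg = replace(emg_cfg, f_max=min(225.0, covariates.fs / 2))
        emg_vals = {}
        for t in tokens:
            v = timeline.emg_band_rsm(
                covariates.emg[0],
                covariates.fs,
                (t.onset, t.offset),
                cfg=emg_cfg,
            )
            emg_vals[t.token_id] = math.exp(v) if math.isfinite(v) else math.nan
        df["emg_rsm"] = pd.Series(emg_vals).reindex(df.index)

    logged = df.apply(lambda col: features.log_transform(col.to_numpy()), axis=0)
    logged.index.name = "token_id"
    return logged


@dataclass
class ResultsBundle:
    """Everything one pipeline run produces, traceable to its config hash."""

    config: PipelineConfig
    lexicon: synth.Lexicon
    discourse: synth.AnnotatedDiscourse
    covariates: synth.Covariates | None
    table: pd.DataFrame  # log-transformed parameters, selected tokens
    spectra: spectral.TrialSpectra  # focalized view used for neurocorrelation
    rsm_p: np.ndarray
    rsm_mask: np.ndarray
    corr_matrix: neurocorr.CorrelationMatrixResult
    maps_pre: dict[str, neurocorr.CorrelationMap]
    thresholds_pre: dict[str, float | None]
    effects_pre: dict[str, list[fx.EffectCluster]]
    residuals: pd.DataFrame
    residual_predictors: dict[str, list[str]]
    maps_post: dict[str, neurocorr.CorrelationMap]
    thresholds_post: dict[str, float | None]
    effects_post: dict[str, list[fx.EffectCluster]]
    matches: dict[str, list[fx.EffectMatch]]

    @property
    def config_hash(self) -> str:
        return self.config.config_hash()

    def effect_table(self) -> pd.DataFrame:
        frames = []
        for param, matches in self.matches.items():
            pre = self.effects_pre.get(param, [])
            matched_pre = {
                id(m.pre) for m in matches if m.matched and m.pre is not None
            }
            frames.append(
                fx.effects_to_frame(
                    pre, subject="synthetic", matched=[id(e) in matched_pre for e in pre]
                ).assign(pass_=("pre",) * len(pre))
            )
            post = self.effects_post.get(param, [])
            matched_post = [
                any(m.matched and m.post is e for m in matches) for e in post
            ]
            frames.append(
                fx.effects_to_frame(post, subject="synthetic", matched=matched_post)
                .assign(pass_=("post",) * len(post))
            )
        if not frames:
            return fx.effects_to_frame([]).assign(pass_=())
        return pd.concat(frames, ignore_index=True)

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        meta = {
            "config_hash": self.config_hash,
            "seed": self.config.seed,
            "n_trials": int(self.spectra.n_trials),
        }
        (out / "run.json").write_text(json.dumps(meta, indent=1) + "\n")
        io.write_lexicon(self.lexicon, out / "lexicon.tsv")
        io.write_annotations(self.discourse, out / "annotations.tsv", "tsv")
        self.table.to_csv(out / "parameters.tsv", sep="\t")
        self.residuals.to_csv(out / "residuals.tsv", sep="\t")
        self.corr_matrix.r.to_csv(out / "correlation_matrix.tsv", sep="\t")
        self.effect_table().to_csv(out / "effects.tsv", sep="\t", index=False)
        io.save_spectra(self.spectra, out / "spectra.npz")
        (out / "report.txt").write_text(report(self))


def _significance(
    cmap: neurocorr.CorrelationMap,
    q: float,
    ladder: neurocorr.ThresholdLadder,
) -> tuple[np.ndarray, float | None]:
    """Bonferroni mask where it yields effects, ladder mask otherwise."""
    bonf = neurocorr.bonferroni_test(cmap, q=q)
    if bonf.any():
        return bonf, q / cmap.p.size
    thr, mask = neurocorr.ladder_test(cmap, ladder)
    return mask, thr


def run_pipeline(config: PipelineConfig = PipelineConfig()) -> ResultsBundle:
    """Execute the whole synthetic analysis; deterministic under the config."""
    rng_seed = np.random.SeedSequence(config.seed).generate_state(4)
    s_lex, s_disc, s_cov, s_rec = (int(s % (2**31)) for s in rng_seed)

    lexicon = synth.generate_lexicon(
        config.n_lexicon, config.zipf_exponent, seed=s_lex
    )
    discourse = synth.generate_discourse(
        lexicon, replace(config.discourse, seed=s_disc)
    )
    covariates = (
        synth.synthesize_covariates(discourse, seed=s_cov, fs=config.fs)
        if config.include_emg
        else None
    )
    recording = synth.synthesize_recording(
        discourse,
        effects=config.effects,
        n_channels=config.n_channels,
        fs=config.fs,
        seed=s_rec,
    )

    tokens = features.select_content_words(discourse.tokens)
    table = parameter_table(
        discourse, covariates, weights=config.eoa_weights, tokens=tokens
    )
    keep = [p for p in config.parameters if p in table.columns]
    table = table[keep]

    rec = spectral.common_average_reference(recording)
    onsets = [t.onset for t in tokens]
    ids = [t.token_id for t in tokens]
    spectra = spectral.compute_trial_spectra(
        rec, onsets, config.spectral, trial_ids=ids
    )
    if spectra.n_trials != len(tokens):
        kept = set(spectra.trial_ids.tolist())
        table = table.loc[[i in kept for i in table.index]]

    rsm_p, rsm_mask = spectral.rsm_group_test(spectra, q=config.q)

    if config.focalize:
        by_id = {t.token_id: t for t in tokens}
        ss_rel = [
            discourse.epoch_of(by_id[i])[0] - by_id[i].onset for i in spectra.trial_ids
        ]
        se_rel = [
            discourse.epoch_of(by_id[i])[1] - by_id[i].onset for i in spectra.trial_ids
        ]
        spectra = neurocorr.restrict_window(
            spectra, (ss_rel, se_rel), config.focal_margin, config.focal_f_max
        )

    corr = neurocorr.parameter_correlation_matrix(table, alpha=config.alpha)

    maps_pre, thr_pre, eff_pre = {}, {}, {}
    for param in table.columns:
        cmap = neurocorr.neurocorrelate(spectra, table[param].to_numpy(), param)
        mask, thr = _significance(cmap, config.q, config.ladder)
        maps_pre[param] = cmap
        thr_pre[param] = thr
        eff_pre[param] = fx.extract_effects(mask, cmap, threshold=thr)

    residuals = pd.DataFrame(index=table.index)
    predictors: dict[str, list[str]] = {}
    maps_post, thr_post, eff_post, matches = {}, {}, {}, {}
    for param in table.columns:
        resid, used = neurocorr.residualize(table, param, config.alpha, corr)
        residuals[param] = resid
        predictors[param] = used
        cmap = neurocorr.neurocorrelate(spectra, resid.to_numpy(), param)
        mask, thr = _significance(cmap, config.q, config.ladder)
        maps_post[param] = cmap
        thr_post[param] = thr
        eff_post[param] = fx.extract_effects(mask, cmap, threshold=thr)
        matches[param] = fx.match_pre_post(eff_pre[param], eff_post[param])

    return ResultsBundle(
        config=config,
        lexicon=lexicon,
        discourse=discourse,
        covariates=covariates,
        table=table,
        spectra=spectra,
        rsm_p=rsm_p,
        rsm_mask=rsm_mask,
        corr_matrix=corr,
        maps_pre=maps_pre,
        thresholds_pre=thr_pre,
        effects_pre=eff_pre,
        residuals=residuals,
        residual_predictors=predictors,
        maps_post=maps_post,
        thresholds_post=thr_post,
        effects_post=eff_post,
        matches=matches,
    )


def report(bundle: ResultsBundle) -> str:
    """Human-readable run summary: collinearity, effects, pre/post matches."""
    lines = [
        "neurolex run summary",
        "====================",
        f"config hash : {bundle.config_hash}",
        f"seed        : {bundle.config.seed}",
        f"trials      : {bundle.spectra.n_trials}",
        f"channels    : {len(bundle.spectra.channel_names)}",
        "",
        "Parameter correlation matrix (Pearson r; * p<%.2g, S = strong |r|>0.4)"
        % bundle.corr_matrix.alpha,
    ]
    cols = list(bundle.corr_matrix.r.columns)
    lines.append("          " + "".join(f"{c:>10}" for c in cols))
    for a in cols:
        cells = []
        for b in cols:
            if a == b:
                cells.append(f"{'-':>10}")
                continue
            r = bundle.corr_matrix.r.loc[a, b]
            mark = "*" if bundle.corr_matrix.significant.loc[a, b] else " "
            strong = "S" if bundle.corr_matrix.strong.loc[a, b] else " "
            cells.append(f"{r:>8.2f}{mark}{strong}")
        lines.append(f"{a:>10}" + "".join(cells))
    lines.append("")
    total = 0
    for param in bundle.maps_pre:
        pre, post = bundle.effects_pre[param], bundle.effects_post[param]
        total += len(pre) + len(post)
        n_match = sum(m.matched for m in bundle.matches[param])
        lines.append(
            f"{param:>10}: {len(pre)} pre-residualization effect(s) "
            f"[threshold {bundle.thresholds_pre[param]}], "
            f"{len(post)} post [threshold {bundle.thresholds_post[param]}], "
            f"{n_match} matched"
        )
        for e in bundle.effects_pre[param]:
            lines.append(
                f"            pre  ch {e.channel:>2} {e.band or '?':>5} "
                f"{e.f_low:6.1f}-{e.f_high:6.1f} Hz "
                f"{e.t_start:+.3f}..{e.t_end:+.3f} s sign {e.sign:+d}"
            )
        for e in bundle.effects_post[param]:
            lines.append(
                f"            post ch {e.channel:>2} {e.band or '?':>5} "
                f"{e.f_low:6.1f}-{e.f_high:6.1f} Hz "
                f"{e.t_start:+.3f}..{e.t_end:+.3f} s sign {e.sign:+d}"
            )
    if total == 0:
        lines.append("no significant effects at any threshold (zero effects)")
    lines.append("")
    return "\n".join(lines)
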