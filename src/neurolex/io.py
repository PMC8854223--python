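"""Interchange formats: annotation TSV/TextGrid, lexicon TSV, array containers.

Two annotation dialects are supported and round-trip exactly:

* ``tsv`` — one row per token with columns ``token_id, orthography, lemma,
  pos, syllables, stress_index, frequency, onset_s, offset_s, clause_id,
  epoch_id, ss_s, se_s, cs_s, ce_s``.  ``syllables`` encodes the abstract
  phonological decomposition as dot-joined C/V templates (e.g. ``CCV.CVC``).
  Columns named ``onset_ms``/``offset_ms`` are accepted and converted to
  seconds on read.
* ``textgrid`` — a Praat-style long TextGrid with three interval tiers
  (``words``, ``clauses``, ``epochs``); word-interval texts carry the full
  token encoding so that reading a written file restores the discourse.

Continuous signals and trial spectra are stored in NPZ array containers with
explicit coordinate vectors and channel metadata.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .features import Syllable, WordType
from .spectral import ChannelInfo, Recording, TrialSpectra
from .synth import AnnotatedDiscourse, EffectSpec, Lexicon
from .timeline import InvalidAnnotationError, TimedToken

__all__ = [
    "write_annotations",
    "read_annotations",
    "write_lexicon",
    "read_lexicon",
    "save_recording",
    "load_recording",
    "save_spectra",
    "load_spectra",
    "write_effect_specs",
    "read_effect_specs",
]

_TOKEN_COLUMNS = [
    "token_id",
    "orthography",
    "lemma",
    "pos",
    "syllables",
    "stress_index",
    "frequency",
    "onset_s",
    "offset_s",
    "clause_id",
    "epoch_id",
    "ss_s",
    "se_s",
    "cs_s",
    "ce_s",
]


def _encode_syllables(word: WordType) -> str:
    return ".".join(s.as_template() for s in word.syllables)


def _decode_syllables(text: str) -> tuple[Syllable, ...]:
    return tuple(Syllable.from_template(t) for t in text.split("."))


def _discourse_frame(discourse: AnnotatedDiscourse) -> pd.DataFrame:
    rows = []
    for t in discourse.tokens:
        ss, se = discourse.epoch_of(t)
        cs, ce = discourse.clause_of(t)
        rows.append(
            {
                "token_id": t.token_id,
                "orthography": t.word.orthography,
                "lemma": t.word.lemma,
                "pos": t.word.pos,
                "syllables": _encode_syllables(t.word),
                "stress_index": t.word.stress_index,
                "frequency": t.frequency,
                "onset_s": t.onset,
                "offset_s": t.offset,
                "clause_id": t.clause_id,
                "epoch_id": t.epoch_id,
                "ss_s": ss,
                "se_s": se,
                "cs_s": cs,
                "ce_s": ce,
            }
        )
    return pd.DataFrame(rows, columns=_TOKEN_COLUMNS)


def _discourse_from_frame(df: pd.DataFrame) -> AnnotatedDiscourse:
    df = df.copy()
    for col in ("onset", "offset"):
        if f"{col}_ms" in df.columns and f"{col}_s" not in df.columns:
            df[f"{col}_s"] = df[f"{col}_ms"] / 1000.0
    missing = {"token_id", "orthography", "pos", "onset_s", "offset_s"} - set(df.columns)
    if missing:
        raise InvalidAnnotationError(f"annotation table lacks columns: {sorted(missing)}")
    df = df.sort_values("onset_s").reset_index(drop=True)
    prev_end = -np.inf
    tokens: list[TimedToken] = []
    epochs: dict[int, tuple[float, float]] = {}
    clauses: dict[int, tuple[float, float]] = {}
    clause_epoch: dict[int, int] = {}
    for i, row in df.iterrows():
        if row.onset_s < prev_end:
            raise InvalidAnnotationError(
                f"overlapping word intervals at token {row.token_id}"
            )
        prev_end = row.offset_s
        word = WordType(
            orthography=str(row.orthography),
            lemma=str(row.get("lemma", row.orthography)),
            pos=str(row.pos),
            syllables=_decode_syllables(str(row.get("syllables", "CV"))),
            stress_index=int(row.get("stress_index", 0)),
        )
        eid = int(row.get("epoch_id", 0))
        cid = int(row.get("clause_id", 0))
        tokens.append(
            TimedToken(
                token_id=int(row.token_id),
                word=word,
                onset=float(row.onset_s),
                offset=float(row.offset_s),
                clause_id=cid,
                epoch_id=eid,
                frequency=float(row.get("frequency", np.nan)),
            )
        )
        ss = float(row.get("ss_s", row.onset_s))
        se = float(row.get("se_s", row.offset_s))
        cs = float(row.get("cs_s", row.onset_s))
        ce = float(row.get("ce_s", row.offset_s))
        e0, e1 = epochs.get(eid, (ss, se))
        epochs[eid] = (min(e0, ss), max(e1, se))
        c0, c1 = clauses.get(cid, (cs, ce))
        clauses[cid] = (min(c0, cs), max(c1, ce))
        clause_epoch[cid] = eid
    ep_list = [epochs[k] for k in sorted(epochs)]
    cl_list = [clauses[k] for k in sorted(clauses)]
    return AnnotatedDiscourse(
        tokens=tokens,
        epochs=ep_list,
        clauses=cl_list,
        clause_epoch=[clause_epoch[k] for k in sorted(clauses)],
    )


# TextGrid -------------------------------------------------------------------

def _textgrid_escape(s: str) -> str:
    return s.replace('"', '""')


def _write_textgrid(discourse: AnnotatedDiscourse, path: Path) -> None:
    xmax = float(max(se for _, se in discourse.epochs) + 1.0)
    tiers: list[tuple[str, list[tuple[float, float, str]]]] = []

    word_ivals = [
        (
            float(t.onset),
            float(t.offset),
            "|".join(
                [
                    str(t.token_id),
                    t.word.orthography,
                    t.word.lemma,
                    t.word.pos,
                    _encode_syllables(t.word),
                    str(t.word.stress_index),
                    repr(float(t.frequency)),
                    str(t.clause_id),
                    str(t.epoch_id),
                ]
            ),
        )
        for t in discourse.tokens
    ]
    clause_ivals = [
        (float(cs), float(ce), f"clause {i}|epoch {discourse.clause_epoch[i]}")
        for i, (cs, ce) in enumerate(discourse.clauses)
    ]
    epoch_ivals = [
        (float(ss), float(se), f"epoch {i}")
        for i, (ss, se) in enumerate(discourse.epochs)
    ]
    tiers = [("words", word_ivals), ("clauses", clause_ivals), ("epochs", epoch_ivals)]

    lines = [
        'File type = "ooTextFile"',
        'Object class = "TextGrid"',
        "",
        "xmin = 0",
        f"xmax = {xmax!r}",
        "tiers? <exists>",
        f"size = {len(tiers)}",
        "item []:",
    ]
    for ti, (name, ivals) in enumerate(tiers, start=1):
        full: list[tuple[float, float, str]] = []
        cursor = 0.0
        for a, b, text in ivals:
            if a > cursor:
                full.append((cursor, a, ""))
            full.append((a, b, text))
            cursor = b
        if cursor < xmax:
            full.append((cursor, xmax, ""))
        lines += [
            f"    item [{ti}]:",
            '        class = "IntervalTier"',
            f'        name = "{name}"',
            "        xmin = 0",
            f"        xmax = {xmax!r}",
            f"        intervals: size = {len(full)}",
        ]
        for k, (a, b, text) in enumerate(full, start=1):
            lines += [
                f"        intervals [{k}]:",
                f"            xmin = {a!r}",
                f"            xmax = {b!r}",
                f'            text = "{_textgrid_escape(text)}"',
            ]
    path.write_text("\n".join(lines) + "\n")


def _parse_textgrid(path: Path) -> dict[str, list[tuple[float, float, str]]]:
    tiers: dict[str, list[tuple[float, float, str]]] = {}
    current: list[tuple[float, float, str]] | None = None
    xmin = xmax = None
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        try:
            if line.startswith("name ="):
                name = line.split("=", 1)[1].strip().strip('"')
                current = tiers.setdefault(name, [])
            elif line.startswith("xmin ="):
                xmin = float(line.split("=", 1)[1])
            elif line.startswith("xmax ="):
                xmax = float(line.split("=", 1)[1])
            elif line.startswith("text =") and current is not None:
                text = line.split("=", 1)[1].strip()
                if not (text.startswith('"') and text.endswith('"')):
                    raise ValueError("unterminated text field")
                text = text[1:-1].replace('""', '"')
                if xmin is None or xmax is None:
                    raise ValueError("interval without xmin/xmax")
                current.append((xmin, xmax, text))
        except ValueError as err:
            raise InvalidAnnotationError(
                f"{path.name}:{lineno}: malformed TextGrid line ({err}): {line!r}"
            ) from None
    return tiers


def _read_textgrid(path: Path) -> AnnotatedDiscourse:
    tiers = _parse_textgrid(path)
    if "words" not in tiers:
        raise InvalidAnnotationError(f"{path.name}: no 'words' tier")
    rows = []
    for a, b, text in tiers["words"]:
        if not text:
            continue
        parts = text.split("|")
        if len(parts) != 9:
            raise InvalidAnnotationError(
                f"{path.name}: word interval text has {len(parts)} fields, expected 9"
            )
        tid, orth, lemma, pos, syl, stress, freq, cid, eid = parts
        rows.append(
            {
                "token_id": int(tid),
                "orthography": orth,
                "lemma": lemma,
                "pos": pos,
                "syllables": syl,
                "stress_index": int(stress),
                "frequency": float(freq),
                "onset_s": a,
                "offset_s": b,
                "clause_id": int(cid),
                "epoch_id": int(eid),
            }
        )
    df = pd.DataFrame(rows)
    # clause/epoch extents from their own tiers
    ep = [(a, b) for a, b, t in tiers.get("epochs", []) if t]
    cl = [(a, b) for a, b, t in tiers.get("clauses", []) if t]
    disc = _discourse_from_frame(df)
    if len(ep) == len(disc.epochs):
        disc.epochs = ep
    if len(cl) == len(disc.clauses):
        disc.clauses = cl
    return disc


def write_annotations(
    discourse: AnnotatedDiscourse, path: str | Path, dialect: str = "tsv"
) -> None:
    """Write a discourse as TSV or as a Praat-style TextGrid."""
    path = Path(path)
    if dialect == "tsv":
        _discourse_frame(discourse).to_csv(path, sep="\t", index=False)
    elif dialect == "textgrid":
        _write_textgrid(discourse, path)
    else:
        raise ValueError(f"unknown annotation dialect: {dialect!r}")


def read_annotations(path: str | Path, dialect: str = "tsv") -> AnnotatedDiscourse:
    """Read a discourse written by :func:`write_annotations` (round-trips)."""
    path = Path(path)
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        return _discourse_from_frame(df)
    if dialect == "textgrid":
        return _read_textgrid(path)
    raise ValueError(f"unknown annotation dialect: {dialect!r}")


# lexicon --------------------------------------------------------------------

def write_lexicon(lexicon: Lexicon, path: str | Path) -> None:
    df = lexicon.to_frame()
    df.insert(0, "zipf_exponent", lexicon.zipf_exponent)
    df.insert(1, "seed", lexicon.seed)
    # repr keeps frequencies exact to the last bit across the round trip
    df.to_csv(path, sep="\t", index=False, float_format=lambda x: repr(float(x)))


def read_lexicon(path: str | Path) -> Lexicon:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    entries = []
    frequencies = {}
    for row in df.itertuples(index=False):
        w = WordType(
            orthography=str(row.orthography),
            lemma=str(row.lemma),
            pos=str(row.pos),
            syllables=_decode_syllables(str(row.syllables)),
            stress_index=int(row.stress_index),
        )
        entries.append(w)
        frequencies[(w.lemma, w.pos)] = float(row.frequency)
    return Lexicon(
        entries=entries,
        frequencies=frequencies,
        zipf_exponent=float(df["zipf_exponent"].iloc[0]),
        seed=int(df["seed"].iloc[0]),
    )


# array containers -----------------------------------------------------------

def save_recording(rec: Recording, path: str | Path) -> None:
    """Store a recording in an NPZ container with channel metadata."""
    np.savez(
        path,
        data=rec.data,
        fs=rec.fs,
        names=np.array([c.name for c in rec.channels]),
        labels=np.array([c.label for c in rec.channels]),
        status=np.array([c.status for c in rec.channels]),
    )


def load_recording(path: str | Path) -> Recording:
    with np.load(path, allow_pickle=False) as z:
        channels = [
            ChannelInfo(name=str(n), label=str(l), status=str(s))
            for n, l, s in zip(z["names"], z["labels"], z["status"])
        ]
        return Recording(data=z["data"], fs=float(z["fs"]), channels=channels)


def save_spectra(spectra: TrialSpectra, path: str | Path) -> None:
    np.savez(
        path,
        log_rsm=spectra.log_rsm,
        freqs=spectra.freqs,
        times=spectra.times,
        trial_ids=spectra.trial_ids,
        channel_names=np.array(spectra.channel_names),
    )


def load_spectra(path: str | Path) -> TrialSpectra:
    with np.load(path, allow_pickle=False) as z:
        return TrialSpectra(
            log_rsm=z["log_rsm"],
            freqs=z["freqs"],
            times=z["times"],
            trial_ids=z["trial_ids"],
            channel_names=[str(n) for n in z["channel_names"]],
        )


def write_effect_specs(effects: Sequence[EffectSpec], path: str | Path) -> None:
    payload = [
        {
            "channel": e.channel,
            "parameter": e.parameter,
            "band": list(e.band),
            "window": list(e.window),
            "r": e.r,
            "sign": e.sign,
        }
        for e in effects
    ]
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_effect_specs(path: str | Path) -> list[EffectSpec]:
    return [
        EffectSpec(
            channel=d["channel"],
            parameter=d["parameter"],
            band=tuple(d["band"]),
            window=tuple(d["window"]),
            r=d["r"],
            sign=d["sign"],
        )
        for d in json.loads(Path(path).read_text())
    ]
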