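"""Response-data filtering and surprisal alignment.

Implements the standard exclusion rules for naturalistic reading-time
corpora so that a downstream regression (out of scope here) can consume a
single modeling table:

* self-paced reading: drop sentence-initial and sentence-final words,
  subjects who answered fewer than four comprehension questions correctly,
  and reading times strictly below 100 ms or strictly above 3000 ms;
* eye-tracking: drop unfixated words, words following saccades strictly
  longer than four words, and words at starts/ends of sentences, screens,
  documents, and lines.

Boundary semantics are strict by default ("shorter than 100 ms" excludes
only durations < 100) and can be flipped to inclusive with ``closed=True``.
All criteria are row-local given the comprehension join, so the filters
are idempotent and order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, FormatError

SPR_COLUMNS = {
    "subject": "subject",
    "item": "item",
    "sentence_id": "sentence_id",
    "token_id": "token_id",
    "word": "word",
    "rt": "rt",
}

ET_BOUNDARY_COLUMNS = (
    "start_of_sentence",
    "end_of_sentence",
    "start_of_screen",
    "end_of_screen",
    "start_of_document",
    "end_of_document",
    "start_of_line",
    "end_of_line",
)


def _colmap(defaults: dict, colmap: dict | None) -> dict:
    out = dict(defaults)
    if colmap:
        out.update(colmap)
    return out


def _require(df: pd.DataFrame, cols, what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{what}: missing columns {missing}")


def filter_spr(
    observations: pd.DataFrame,
    comprehension: pd.DataFrame | None = None,
    min_ms: float = 100.0,
    max_ms: float = 3000.0,
    min_correct: int = 4,
    colmap: dict | None = None,
    closed: bool = False,
    log_transform: bool = False,
) -> pd.DataFrame:
    """Apply the self-paced-reading exclusions; row order is preserved.

    ``comprehension`` maps subjects (optionally subject x item) to the
    number of correctly answered comprehension questions; it may instead be
    a ``correct`` column already present in ``observations``.
    """
    cm = _colmap(SPR_COLUMNS, colmap)
    _require(
        observations,
        [cm["subject"], cm["sentence_id"], cm["token_id"], cm["rt"]],
        "self-paced reading table",
    )
    df = observations.copy()
    if "correct" not in df.columns:
        if comprehension is None:
            raise FormatError(
                "comprehension scores are neither joined (a 'correct' "
                "column) nor supplied as a table"
            )
        _require(comprehension, [cm["subject"], "correct"],
                 "comprehension table")
        join_cols = [cm["subject"]]
        if cm["item"] in comprehension.columns and cm["item"] in df.columns:
            join_cols.append(cm["item"])
        df = df.merge(comprehension[join_cols + ["correct"]], on=join_cols,
                      how="left", validate="many_to_one")
        if df["correct"].isna().any():
            bad = df.loc[df["correct"].isna(), cm["subject"]].unique()
            raise FormatError(
                f"comprehension join failed for subjects {sorted(bad)[:5]}"
            )
    if {"is_sentence_start", "is_sentence_end"} <= set(df.columns):
        # explicit flags (e.g. from a previous filtering pass): row-local,
        # which keeps the filter idempotent
        keep = ~(df["is_sentence_start"].astype(bool)
                 | df["is_sentence_end"].astype(bool))
    else:
        group_cols = [c for c in (cm["item"], cm["sentence_id"])
                      if c in df.columns]
        grp = df.groupby(group_cols)[cm["token_id"]]
        first = grp.transform("min")
        last = grp.transform("max")
        df["is_sentence_start"] = df[cm["token_id"]] == first
        df["is_sentence_end"] = df[cm["token_id"]] == last
        keep = ~(df["is_sentence_start"] | df["is_sentence_end"])
    keep &= df["correct"] >= min_correct
    rt = df[cm["rt"]]
    if closed:
        keep &= (rt > min_ms) & (rt < max_ms)
    else:
        keep &= (rt >= min_ms) & (rt <= max_ms)
    keep &= np.isfinite(rt)
    out = df.loc[keep].copy()
    if log_transform:
        out["log_rt"] = np.log(out[cm["rt"]])
    return out


def filter_eyetracking(
    observations: pd.DataFrame,
    max_saccade: int = 4,
    colmap: dict | None = None,
    closed: bool = False,
) -> pd.DataFrame:
    """Apply the eye-tracking exclusions; row order is preserved."""
    cm = _colmap({"fixated": "fixated", "saccade_len": "saccade_len"}, colmap)
    needed = [cm["fixated"], cm["saccade_len"], *ET_BOUNDARY_COLUMNS]
    missing = [c for c in needed if c not in observations.columns]
    if missing:
        raise FormatError(
            f"eye-tracking table: missing columns {missing}"
        )
    df = observations
    keep = df[cm["fixated"]].astype(bool)
    if closed:
        keep &= df[cm["saccade_len"]] < max_saccade
    else:
        keep &= df[cm["saccade_len"]] <= max_saccade
    for col in ET_BOUNDARY_COLUMNS:
        keep &= ~df[col].astype(bool)
    return df.loc[keep].copy()


@dataclass
class AlignmentReport:
    n_observations: int
    n_matched: int
    unmatched: list = field(default_factory=list)  # (sentence_id, token_id, word)
    detokenized: int = 0

    @property
    def rate(self) -> float:
        return self.n_matched / self.n_observations if self.n_observations else 1.0


def align_surprisal(
    observations: pd.DataFrame,
    surprisal: pd.DataFrame,
    detok_map: dict | None = None,
    min_rate: float = 0.95,
    colmap: dict | None = None,
) -> tuple[pd.DataFrame, AlignmentReport]:
    """Join filtered observations with a surprisal table.

    Alignment is by (sentence_id, token_id) with the word form checked;
    mismatching words are first sent through ``detok_map`` (raw form ->
    model tokenization).  Unmatched tokens are reported, never silently
    dropped; an alignment rate below ``min_rate`` raises
    :class:`AlignmentError` with a diff sample.

    The modeling table adds the surprisal columns and baseline predictors:
    word length in characters and position within the sentence.
    """
    cm = _colmap(SPR_COLUMNS, colmap)
    _require(observations, [cm["sentence_id"], cm["token_id"], cm["word"]],
             "observation table")
    _require(surprisal,
             ["sentence_id", "token_id", "word", "surprisal_nats"],
             "surprisal table")
    detok_map = detok_map or {}
    surp = surprisal.set_index(["sentence_id", "token_id"])
    report = AlignmentReport(len(observations), 0)
    rows = []
    for _, row in observations.iterrows():
        key = (row[cm["sentence_id"]], row[cm["token_id"]])
        word = row[cm["word"]]
        if key not in surp.index:
            report.unmatched.append((*key, word))
            continue
        srow = surp.loc[key]
        target = srow["word"]
        if word != target:
            mapped = detok_map.get(word)
            if mapped != target:
                report.unmatched.append((*key, word))
                continue
            report.detokenized += 1
        report.n_matched += 1
        merged = dict(row)
        merged["surprisal_nats"] = srow["surprisal_nats"]
        if "surprisal_bits" in srow:
            merged["surprisal_bits"] = srow["surprisal_bits"]
        if "prefix_logprob_nats" in srow:
            merged["prefix_logprob_nats"] = srow["prefix_logprob_nats"]
        merged["word_length"] = len(word)
        merged["sentence_position"] = row[cm["token_id"]]
        rows.append(merged)
    if report.rate < min_rate:
        sample = report.unmatched[:10]
        raise AlignmentError(
            f"alignment rate {report.rate:.3f} < {min_rate}; first "
            f"mismatches: {sample}"
        )
    return pd.DataFrame(rows), report


def read_spr_table(path, colmap: dict | None = None) -> pd.DataFrame:
    """Generic column-mapped reader for tab-separated per-word responses."""
    df = pd.read_csv(path, sep="\t")
    if colmap:
        df = df.rename(columns={v: k for k, v in colmap.items()})
    return df
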