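"""Prefix probabilities, surprisal, and perplexity.

The forward pass maintains a distribution over hypotheses (store state,
Z stack, log forward probability).  ``exact_forward`` keeps every reachable
hypothesis and is the oracle for small models; ``beam_forward`` retains the
top ``beam_size`` hypotheses by forward probability after merging
duplicates, so its prefix probabilities are lower bounds that are
monotonically non-decreasing in the beam size.

Prefix-probability convention: at word t < T the prefix log probability is
the mass of all live (continuable) hypotheses; at the final word it is the
sentence-termination mass, so the last word's surprisal includes the
end-of-sentence decision and per-sentence surprisals telescope to the
negative full-sentence log probability.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.special import logsumexp

from .errors import NumericalConsistencyError, StateSpaceError
from .state import EMPTY_STORE, EMPTY_Z
from .transition import TransitionModel

NEG_INF = -np.inf
MONOTONE_TOL = 1e-9


class BeamElement(NamedTuple):
    store: tuple
    z: tuple
    log_forward: float


@dataclass(frozen=True)
class SurprisalRecord:
    sentence_index: int
    token_index: int
    word: str
    prefix_logprob: float  # nats
    surprisal_nats: float
    surprisal_bits: float
    parse_failed: bool = False


@dataclass
class ForwardResult:
    prefix_logprobs: list[float]  # one per word; final entry includes termination
    parse_failed: bool
    top_decisions: list | None  # [(LexicalDecision, word, GrammaticalDecision)]
    n_states: list[int]


def _as_model(model_or_params) -> TransitionModel:
    if isinstance(model_or_params, TransitionModel):
        return model_or_params
    return TransitionModel(model_or_params)


class _Hyp:
    __slots__ = ("logp", "best_logp", "back", "decisions")

    def __init__(self, logp=NEG_INF, best_logp=NEG_INF, back=None,
                 decisions=None):
        self.logp = logp
        self.best_logp = best_logp
        self.back = back
        self.decisions = decisions


def _expand(model: TransitionModel, states: dict, word: str):
    """One forward step; returns (new_states, completed_hyp)."""
    new: dict = {}
    completed = _Hyp()
    for key, hyp in states.items():
        succ, comp = model.step_distribution(key[0], key[1], word)
        for skey, outcome in succ.items():
            tgt = new.get(skey)
            if tgt is None:
                tgt = new[skey] = _Hyp()
            tgt.logp = np.logaddexp(tgt.logp, hyp.logp + outcome.logp)
            cand = hyp.best_logp + outcome.best_logp
            if cand > tgt.best_logp:
                tgt.best_logp = cand
                tgt.back = (key, hyp)
                tgt.decisions = outcome.best_decisions
        if comp.logp > NEG_INF:
            completed.logp = np.logaddexp(
                completed.logp, hyp.logp + comp.logp
            )
            cand = hyp.best_logp + comp.best_logp
            if cand > completed.best_logp:
                completed.best_logp = cand
                completed.back = (key, hyp)
                completed.decisions = comp.best_decisions
    return new, completed


def _live_mass(states: dict) -> float:
    if not states:
        return NEG_INF
    return float(logsumexp([h.logp for h in states.values()]))


def _trace_decisions(final_hyp: _Hyp, words) -> list | None:
    steps = []
    hyp = final_hyp
    while hyp is not None and hyp.decisions is not None:
        steps.append(hyp.decisions)
        hyp = hyp.back[1] if hyp.back is not None else None
    steps.reverse()
    if len(steps) != len(words):
        return None
    return [(lex, w, g) for (lex, g), w in zip(steps, words)]


def _forward(model, words, beam_size: int | None, max_states: int,
             keep_parse: bool) -> ForwardResult:
    init = _Hyp(0.0, 0.0, None, None)
    states = {(EMPTY_STORE, EMPTY_Z): init}
    prefixes: list[float] = []
    n_states: list[int] = []
    failed = False
    final_completed = None
    T = len(words)
    for t, word in enumerate(words):
        states, completed = _expand(model, states, word)
        if beam_size is None:
            if len(states) > max_states:
                raise StateSpaceError(
                    f"{len(states)} live states exceed the exact-enumeration "
                    f"budget of {max_states} at word {t + 1}"
                )
        elif len(states) > beam_size:
            ranked = sorted(
                states.items(), key=lambda kv: (-kv[1].logp, kv[0])
            )
            states = dict(ranked[:beam_size])
        n_states.append(len(states))
        if t < T - 1:
            prefixes.append(_live_mass(states))
        else:
            prefixes.append(completed.logp)
            final_completed = completed
        if not states and t < T - 1:
            failed = True
            prefixes.extend([NEG_INF] * (T - 1 - t))
            n_states.extend([0] * (T - 1 - t))
            break
    if prefixes and prefixes[-1] == NEG_INF:
        failed = True
    top = None
    if keep_parse and final_completed is not None and not failed:
        top = _trace_decisions(final_completed, words)
    return ForwardResult(prefixes, failed, top, n_states)


def exact_forward(words, model_or_params, max_states: int = 200_000
                  ) -> ForwardResult:
    """Prefix log probabilities by exhaustive enumeration of hypotheses.

    Raises :class:`StateSpaceError` rather than truncating when the state
    space outgrows ``max_states``.
    """
    return _forward(_as_model(model_or_params), list(words), None, max_states,
                    keep_parse=True)


def beam_forward(words, model_or_params, beam_size: int = 5000,
                 keep_parse: bool = True) -> ForwardResult:
    """Beam-search prefix log probabilities (default beam width 5000).

    Duplicate hypotheses are merged by summing probability before pruning;
    ties at the beam boundary break on the canonical state key.  Prefix
    values lower-bound the exact ones and are non-decreasing in beam size.
    """
    if beam_size < 1:
        raise ValueError("beam_size must be >= 1")
    return _forward(_as_model(model_or_params), list(words), beam_size, 0,
                    keep_parse=keep_parse)


LOG2 = math.log(2.0)


def surprisal_series(prefix_logprobs, words, sentence_index: int = 0,
                     parse_failed: bool = False,
                     floor_nats: float = 25.0) -> list[SurprisalRecord]:
    """Per-word surprisal from a non-increasing prefix log-prob sequence.

    S(w_t) = log P(w_1..t-1) - log P(w_1..t) in nats (t = 1 uses log 1 = 0).
    On a parse failure (prefix mass -inf) the affected words receive the
    configured floor surprisal and are flagged.
    """
    if len(prefix_logprobs) != len(words):
        raise ValueError("prefix/word length mismatch")
    records = []
    prev = 0.0
    for t, (lp, w) in enumerate(zip(prefix_logprobs, words)):
        if lp == NEG_INF or prev == NEG_INF:
            records.append(
                SurprisalRecord(sentence_index, t, w, float(lp), floor_nats,
                                floor_nats / LOG2, True)
            )
            prev = lp
            continue
        if lp > prev + MONOTONE_TOL:
            raise NumericalConsistencyError(
                f"prefix log-probability increased at token {t}: "
                f"{prev} -> {lp}"
            )
        s = max(prev - lp, 0.0)
        records.append(
            SurprisalRecord(sentence_index, t, w, float(lp), float(s),
                            float(s / LOG2), parse_failed)
        )
        prev = lp
    return records


def score_sentences(sentences, model_or_params, beam_size: int | None = 5000,
                    floor_nats: float = 25.0) -> list[SurprisalRecord]:
    """Surprisal records for tokenized sentences (lists of words).

    ``beam_size=None`` uses exact enumeration.
    """
    model = _as_model(model_or_params)
    records = []
    for i, words in enumerate(sentences):
        if beam_size is None:
            res = exact_forward(words, model)
        else:
            res = beam_forward(words, model, beam_size, keep_parse=False)
        if res.parse_failed:
            warnings.warn(f"parse failure in sentence {i}; floor surprisal")
        records.extend(
            surprisal_series(res.prefix_logprobs, words, i, res.parse_failed,
                             floor_nats)
        )
    return records


def corpus_perplexity(records, policy: str = "drop") -> tuple[float, int]:
    """exp(mean per-token surprisal in nats); returns (ppl, n_excluded).

    ``policy='drop'`` excludes non-finite surprisals (reporting the count);
    ``policy='error'`` raises on the first one.
    """
    if not records:
        raise ValueError("empty record set")
    vals = []
    excluded = 0
    for r in records:
        if np.isfinite(r.surprisal_nats) and not r.parse_failed:
            vals.append(r.surprisal_nats)
        else:
            excluded += 1
            if policy == "error":
                raise NumericalConsistencyError(
                    f"non-finite surprisal at sentence {r.sentence_index} "
                    f"token {r.token_index}"
                )
    if not vals:
        raise ValueError("no finite surprisals")
    return float(np.exp(np.mean(vals))), excluded


def enumerate_language(model_or_params, word_support, max_len: int,
                       mass_floor: float = 1e-12) -> dict[tuple, float]:
    """All sentences up to ``max_len`` with probability above the floor.

    Only practical for tabular toy parameterizations with a finite word
    support.  Returns sentence -> probability; the total is the covered
    mass (1 minus truncation/pruning losses).
    """
    model = _as_model(model_or_params)
    log_floor = math.log(mass_floor)
    out: dict[tuple, float] = {}

    def rec(prefix, states):
        if len(prefix) >= max_len:
            return
        for w in word_support:
            new, completed = _expand(model, states, w)
            if completed.logp > NEG_INF:
                out[prefix + (w,)] = float(np.exp(completed.logp))
            if new and _live_mass(new) > log_floor:
                rec(prefix + (w,), new)

    rec((), {(EMPTY_STORE, EMPTY_Z): _Hyp(0.0, 0.0)})
    return out


def accepted_mass(model_or_params, word_support, max_len: int) -> float:
    """log of the total probability of completing within ``max_len`` words.

    Aggregated exact forward pass marginalizing over the word support at
    every step (state-level dynamic programming, so it stays polynomial
    where sentence-level enumeration is exponential).  1 - exp(result) is
    the mass lost to depth-bound pruning plus the overlength tail: the
    normalizer of the generator's length-bounded language.
    """
    model = _as_model(model_or_params)
    states = {(EMPTY_STORE, EMPTY_Z): _Hyp(0.0, 0.0)}
    log_z = NEG_INF
    for _ in range(max_len):
        new: dict = {}
        for w in word_support:
            nw, comp = _expand(model, states, w)
            if comp.logp > NEG_INF:
                log_z = np.logaddexp(log_z, comp.logp)
            for k, h in nw.items():
                tgt = new.get(k)
                if tgt is None:
                    tgt = new[k] = _Hyp()
                tgt.logp = np.logaddexp(tgt.logp, h.logp)
        states = new
        if not states:
            break
    return float(log_z)


def per_token_perplexity_of_language(language: dict[tuple, float]) -> float:
    """exp of the per-token entropy of an enumerated sentence distribution.

    Probabilities are renormalized over the enumerated set, so truncation
    to a high-coverage set perturbs the result only marginally.
    """
    total = sum(language.values())
    num = 0.0
    den = 0.0
    for sent, p in language.items():
        p /= total
        num += -p * math.log(p)
        den += p * len(sent)
    return math.exp(num / den)
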