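"""Morphological word generation: P(w | q, lex) as a sum over analyses.

A word's probability marginalizes over all <lemma, rule> pairs that
deterministically generate it: P(w) = sum_x,r P(x | .) P(r | ., x) with the
rule applied to the lemma required to yield exactly w.  The identity rule
guarantees at least one analysis for every word, which is how the model
assigns finite probability to out-of-vocabulary forms.

The -morph ablation replaces this with a relative-frequency table over the
training vocabulary conditioned on the preterminal category (additive
smoothing with a reserved unknown-word cell, which supplies the floor
probability for novel forms).
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

from .morph import RuleInventory

UNK_WORD = "\x00UNK\x00"


def candidate_analyses(word: str, rules: RuleInventory) -> list[tuple[str, int]]:
    """All <lemma, rule_id> pairs whose application regenerates ``word``.

    Always contains ``(word, 0)`` via the identity rule.  Canonically
    ordered by (lemma, rule id).
    """
    if not word:
        raise ValueError("word must be nonempty")
    out = set()
    for rid, rule in enumerate(rules):
        for lemma in rule.invert(word):
            if rule.apply(lemma) == word:
                out.add((lemma, rid))
    return sorted(out)


def word_logprob(params, word: str, pret_cat: int, h_l: bytes) -> float:
    """log P(word | preterminal) under the full model or the -morph table."""
    if params.word_table is not None:
        table = params.word_table.get(pret_cat)
        if table is None:
            table = params.word_table.get(-1)  # global fallback column
        if table is None:
            return -np.inf
        return table.get(word, table[UNK_WORD])
    terms = [
        params.lemma_logprob(lemma, pret_cat, h_l)
        + params.rule_logprob(rid, lemma, pret_cat, h_l)
        for lemma, rid in candidate_analyses(word, params.inv.rules)
    ]
    return float(logsumexp(terms)) if terms else -np.inf


def sample_word(params, pret_cat: int, h_l: bytes, rng,
                max_tries: int = 64) -> tuple[str, str, int]:
    """Sample (word, lemma, rule_id); resamples when the rule is inapplicable."""
    for _ in range(max_tries):
        lemma, rid = params.sample_lemma_rule(pret_cat, h_l, rng)
        word = params.inv.rules[rid].apply(lemma)
        if word is not None:
            return word, lemma, rid
    raise RuntimeError("could not sample an applicable <lemma, rule> pair")


def build_word_table(examples, alpha: float = 1.0) -> dict:
    """Relative-frequency word table for the -morph ablation.

    ``examples`` yields (pret_cat, word) training pairs.  Additive smoothing
    with pseudo-count ``alpha`` over the training vocabulary plus one
    unknown cell; each per-category column is a normalized distribution.
    """
    vocab: set[str] = set()
    counts: dict[int, dict[str, int]] = {}
    for cat, word in examples:
        vocab.add(word)
        counts.setdefault(cat, {})
        counts[cat][word] = counts[cat].get(word, 0) + 1
    vocab_list = sorted(vocab) + [UNK_WORD]
    table: dict[int, dict[str, float]] = {}
    global_counts: dict[str, int] = {}
    for cat, wc in counts.items():
        total = sum(wc.values()) + alpha * len(vocab_list)
        table[cat] = {
            w: float(np.log((wc.get(w, 0) + alpha) / total)) for w in vocab_list
        }
        for w, c in wc.items():
            global_counts[w] = global_counts.get(w, 0) + c
    total = sum(global_counts.values()) + alpha * len(vocab_list)
    table[-1] = {
        w: float(np.log((global_counts.get(w, 0) + alpha) / total))
        for w in vocab_list
    }
    return table


def truncated_word_mass(params, pret_cat: int, h_l: bytes, alphabet: str,
                        max_len: int) -> float:
    """Total P(w) over all words of length <= max_len from ``alphabet``.

    Diagnostic for the (sub)normalization of the word model: the result is
    a lower bound on total word mass and non-decreasing in ``max_len``.
    """
    total = 0.0
    words = [""]
    for _ in range(max_len):
        words = [w + ch for w in words for ch in alphabet]
        for w in words:
            total += np.exp(word_logprob(params, w, pret_cat, h_l))
    return float(total)
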