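"""Prefix probabilities, surprisal arithmetic, beam/exact agreement."""

import math

import numpy as np
import pytest

from lcsurp import (
    beam_forward,
    corpus_perplexity,
    enumerate_language,
    exact_forward,
    generate_grammar,
    sample_treebank,
    surprisal_series,
    to_parameters,
)
from lcsurp.errors import NumericalConsistencyError, StateSpaceError
from lcsurp.inference import SurprisalRecord, per_token_perplexity_of_language
from lcsurp.synth import word_support
from lcsurp.transition import TransitionModel


def test_surprisal_from_prefix_probs():
    # prefix probabilities (1.0, 0.25) -> second word carries 2 bits
    recs = surprisal_series([0.0, math.log(0.25)], ["a", "b"])
    assert recs[0].surprisal_bits == pytest.approx(0.0)
    assert recs[1].surprisal_bits == pytest.approx(2.0)
    assert recs[1].surprisal_nats == pytest.approx(math.log(4.0))


def test_surprisal_telescopes_to_final_prefix():
    lps = [-0.5, -1.25, -3.0]
    recs = surprisal_series(lps, list("abc"))
    assert sum(r.surprisal_nats for r in recs) == pytest.approx(3.0, abs=1e-12)


def test_increasing_prefix_probability_is_an_error():
    with pytest.raises(NumericalConsistencyError):
        surprisal_series([-1.0, -0.5], ["a", "b"])


def test_parse_failure_emits_floor_surprisal():
    recs = surprisal_series([-1.0, -np.inf], ["a", "b"], floor_nats=30.0)
    assert recs[1].parse_failed and recs[1].surprisal_nats == 30.0


def test_corpus_perplexity_identities():
    recs = [
        SurprisalRecord(0, i, "w", 0.0, math.log(2.0), 1.0) for i in range(10)
    ]
    ppl, excl = corpus_perplexity(recs)
    assert ppl == pytest.approx(2.0) and excl == 0
    # non-finite records are excluded and counted
    recs.append(SurprisalRecord(0, 10, "w", -np.inf, np.inf, np.inf))
    ppl, excl = corpus_perplexity(recs)
    assert ppl == pytest.approx(2.0) and excl == 1


def test_perplexity_matches_summed_logprob_recomputation(toy_teacher,
                                                         toy_sample):
    """exp(mean surprisal) equals exp(-sum prefix logprob / n tokens)."""
    _, sents, _ = toy_sample
    tm = TransitionModel(toy_teacher)
    from lcsurp.inference import score_sentences

    recs = score_sentences(sents[:50], tm, beam_size=None)
    ppl, _ = corpus_perplexity(recs)
    total_lp = 0.0
    n_tok = 0
    for s in sents[:50]:
        res = exact_forward(s, tm)
        total_lp += res.prefix_logprobs[-1]
        n_tok += len(s)
    assert ppl == pytest.approx(math.exp(-total_lp / n_tok), rel=1e-9)


def test_saturating_beam_equals_exact(toy_teacher, toy_sample):
    _, sents, _ = toy_sample
    tm = TransitionModel(toy_teacher)
    for s in sents[:30]:
        exact = exact_forward(s, tm)
        beam = beam_forward(s, tm, beam_size=10**6)
        assert np.allclose(exact.prefix_logprobs, beam.prefix_logprobs,
                           atol=1e-10)


def test_beam_monotone_in_beam_size(toy_teacher, toy_sample):
    _, sents, _ = toy_sample
    tm = TransitionModel(toy_teacher)
    for s in [x for x in sents if len(x) >= 3][:10]:
        prev = None
        for b in (1, 2, 5, 50, 10**6):
            res = beam_forward(s, tm, beam_size=b)
            lps = np.array(res.prefix_logprobs)
            if prev is not None:
                assert (prev <= lps + 1e-12).all()
            prev = lps


def test_prefix_logprobs_non_increasing(toy_teacher, toy_sample):
    _, sents, _ = toy_sample
    tm = TransitionModel(toy_teacher)
    for s in sents[:30]:
        res = exact_forward(s, tm)
        lps = res.prefix_logprobs
        assert all(b <= a + 1e-9 for a, b in zip(lps, lps[1:]))
        recs = surprisal_series(lps, s)
        assert all(r.surprisal_nats >= -1e-9 for r in recs)


def test_exact_forward_raises_on_state_explosion(toy_teacher, toy_sample):
    _, sents, _ = toy_sample
    long_sent = max(sents, key=len)
    if len(long_sent) < 3:
        pytest.skip("sample contains no multiword sentence")
    with pytest.raises(StateSpaceError):
        exact_forward(long_sent, TransitionModel(toy_teacher), max_states=1)


def test_single_sentence_grammar_has_zero_surprisal():
    """A grammar generating exactly one sentence gives every prefix
    probability 1 and all-zero surprisals."""
    g = generate_grammar(5, n_categories=1, n_predicates=1, n_rules=1,
                         max_valence=0, n_morph_rules=0,
                         lemmas_per_category=1, branch_mass=0.0)
    # suppress everything but immediate termination of a single word
    g.term_bias = 1e9
    g.zero_ctx_weight = 0.0
    g.morph_weights = [1.0, 0.0]
    params = to_parameters(g)
    lang = enumerate_language(params, word_support(params), max_len=3)
    top = max(lang.values())
    assert top > 1 - 1e-6  # one sentence carries essentially all mass
    sent = list(max(lang, key=lang.get))
    res = exact_forward(sent, params)
    recs = surprisal_series(res.prefix_logprobs, sent)
    for r in recs:
        assert r.surprisal_nats == pytest.approx(0.0, abs=1e-5)


def test_prefix_probability_equals_enumerated_continuation_mass(
        unambiguous_teacher):
    """The prefix probability at word t equals the total probability of
    all enumerated sentences consistent with the prefix (with the live
    mass at t additionally covering unfinished continuations)."""
    params = unambiguous_teacher
    lang = enumerate_language(params, word_support(params), max_len=12,
                              mass_floor=1e-12)
    total = sum(lang.values())
    assert total > 0.95
    tm = TransitionModel(params)
    # most probable multiword sentence and its shared 1-word prefix
    sent = max((s for s in lang if len(s) >= 2), key=lang.get)
    res = exact_forward(list(sent), tm)
    # final prefix = this sentence's own probability (complete parses)
    assert res.prefix_logprobs[-1] == pytest.approx(math.log(lang[sent]),
                                                    abs=1e-9)
    # live prefix mass after word 1 brackets the enumerated continuations:
    # it contains them all, plus at most the unenumerated remainder
    cont = sum(p for s, p in lang.items()
               if len(s) > 1 and s[0] == sent[0])
    live = math.exp(res.prefix_logprobs[0])
    assert cont - 1e-9 <= live <= cont + (1.0 - total) + 1e-9


def test_enumerated_language_sums_to_one():
    # a tiny termination-heavy grammar keeps the language effectively finite
    g = generate_grammar(9, n_categories=1, n_predicates=1, n_rules=1,
                         lemmas_per_category=1, n_morph_rules=1,
                         branch_mass=0.3)
    g.term_bias = 3.0
    g.zero_ctx_weight = 0.0
    params = to_parameters(g)
    lang = enumerate_language(params, word_support(params), max_len=7,
                              mass_floor=1e-7)
    total = sum(lang.values())
    assert 0.95 < total <= 1.0 + 1e-9
    ppl = per_token_perplexity_of_language(lang)
    assert ppl > 1.0
    # the renormalized language matches the exact aggregated normalizer
    from lcsurp import accepted_mass

    z = math.exp(accepted_mass(params, word_support(params), max_len=7))
    assert total == pytest.approx(z, abs=1e-3)


def test_top_parse_replays_to_the_scored_sentence(toy_teacher, toy_sample):
    from lcsurp.training import decisions_to_tree

    _, sents, _ = toy_sample
    tm = TransitionModel(toy_teacher)
    s = max(sents, key=len)
    res = beam_forward(s, tm, beam_size=10**6, keep_parse=True)
    assert res.top_decisions is not None
    steps = []
    from lcsurp.training import DecisionStep

    for (lex, word, g) in res.top_decisions:
        h_l = toy_teacher.inv.lex_contexts[lex.h_index]
        steps.append(
            DecisionStep(lex.match, lex.cat, h_l, word, "", 0, g.match, g.op,
                         g.parent_cat, g.base_cat, g.is_termination)
        )
    # the decision trace must replay into a tree whose leaves are the words
    tree = decisions_to_tree(steps, toy_teacher)
    assert [lf.word for lf in tree.leaves()] == list(s)
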