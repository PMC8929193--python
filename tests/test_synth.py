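"""Synthetic grammars and treebanks: determinism, validity, consistency."""

import math

import numpy as np
import pytest
from scipy import stats

from lcsurp import exact_forward, generate_grammar, sample_treebank, \
    to_parameters
from lcsurp.errors import GenerationError
from lcsurp.morph import MorphRule
from lcsurp.synth import LexEntry, sample_decisions, word_support
from lcsurp.transition import TransitionModel
from lcsurp.treebank import branch_counts, format_tree, read_treebank, \
    write_treebank
from lcsurp.training import left_corner_depth


def test_same_seed_same_grammar():
    a = generate_grammar(7).to_json()
    b = generate_grammar(7).to_json()
    assert a == b
    c = generate_grammar(8).to_json()
    assert c != a


def test_same_seed_same_treebank(toy_grammar):
    t1, s1, _ = sample_treebank(toy_grammar, 25, seed=3)
    t2, s2, _ = sample_treebank(toy_grammar, 25, seed=3)
    assert s1 == s2
    assert [format_tree(t) for t in t1] == [format_tree(t) for t in t2]


def test_infeasible_sizes_raise():
    with pytest.raises(GenerationError):
        generate_grammar(1, n_categories=0)
    g = generate_grammar(1)
    g.lexicon = [e for e in g.lexicon if e.cat != g.categories[0].label]
    with pytest.raises(GenerationError):
        g.validate()


def test_sampled_trees_validate_and_round_trip(toy_sample, tmp_path):
    trees, sents, info = toy_sample
    for tree, sent in zip(trees, sents):
        u, b = branch_counts(tree)
        assert u == len(sent) and b == len(sent) - 1
    path = tmp_path / "tb.txt"
    write_treebank(trees, path, info["header"])
    back, header, errors = read_treebank(path, info["params"].inv.rules)
    assert not errors
    assert [format_tree(t) for t in back] == [format_tree(t) for t in trees]
    assert header.V == 1 and header.D == 2


def test_sampled_trees_respect_depth_bound(toy_grammar, toy_sample):
    trees, _, _ = toy_sample
    assert all(left_corner_depth(t) <= toy_grammar.D for t in trees)


def test_sampled_words_are_rule_applications(toy_teacher, toy_sample):
    trees, _, _ = toy_sample
    rules = toy_teacher.inv.rules
    for tree in trees:
        for leaf in tree.leaves():
            assert rules[leaf.rule_id].apply(leaf.lemma) == leaf.word


def test_sampled_logprob_matches_exact_forward_when_unambiguous(
        unambiguous_teacher):
    """When every sentence has a unique derivation, the forward algorithm
    must assign exactly the sampled decision log probability."""
    params = unambiguous_teacher
    rng = np.random.default_rng(5)
    tm = TransitionModel(params)
    checked = 0
    for _ in range(25):
        steps, logp, _ = sample_decisions(params, rng, max_len=8)
        words = [s.word for s in steps]
        res = exact_forward(words, tm)
        assert res.prefix_logprobs[-1] == pytest.approx(logp, abs=1e-9)
        checked += 1
    assert checked == 25


def test_sampled_logprob_lower_bounds_forward_mass(toy_teacher, toy_sample):
    # with ambiguity the sampled derivation is one of possibly many
    _, sents, info = toy_sample
    tm = TransitionModel(info["params"])
    for words, logp in list(zip(sents, info["logps"]))[:25]:
        res = exact_forward(words, tm)
        assert res.prefix_logprobs[-1] >= logp - 1e-9


def test_production_frequencies_match_rule_probabilities(toy_grammar):
    """Decisions drawn through the sampler follow the renormalized
    rewrite-rule weights of the grammatical decision table (chi-square,
    p > 0.001).

    Sampling draws are taken directly at a fixed conditioning state, which
    sidesteps the survivorship conditioning that whole-sentence rejection
    (length cap, depth bound) would otherwise introduce."""
    params = to_parameters(toy_grammar)
    tm = TransitionModel(params)
    from lcsurp.state import Fragment, Node

    zero = params.inv.space.zero_bytes()
    # conditioning state: one open fragment, no-match lexical phase
    q = (Fragment(Node(2, zero), Node(2, zero)),)
    apex = Node(3, zero)
    dist = tm.grammatical_distribution(q, 0, apex)
    probs = np.exp([lp for _, lp in dist])
    probs = probs / probs.sum()
    rng = np.random.default_rng(17)
    n = 4000
    draws = rng.choice(len(dist), size=n, p=probs)
    obs = np.bincount(draws, minlength=len(dist)).astype(float)
    f_exp = n * probs
    keep = f_exp > 1e-9
    chi, p = stats.chisquare(obs[keep], f_exp[keep])
    assert p > 0.001
    # and the table itself reflects the rewrite-rule weights: for no-match
    # decisions the operator/category mass is proportional to rule weight
    by_rule: dict = {}
    for (gd, lp) in dist:
        if gd.match == 0:
            key = (gd.op, gd.parent_cat, gd.base_cat)
            by_rule[key] = by_rule.get(key, 0.0) + math.exp(lp)
    label = {params.inv.cat_id(c.label): c.label
             for c in toy_grammar.categories}
    apex_label = label[3]
    wanted = {
        (r.op, params.inv.cat_id(r.parent), params.inv.cat_id(r.right)):
            r.weight
        for r in toy_grammar.rewrite_rules if r.left == apex_label
    }
    total_w = sum(wanted.values())
    total_p = sum(by_rule.get(k, 0.0) for k in wanted)
    for k, w in wanted.items():
        assert by_rule.get(k, 0.0) / total_p == pytest.approx(
            w / total_w, abs=1e-9
        )


def test_word_support_regenerates_under_scoring(toy_teacher):
    # every supported word is scorable from at least one preterminal
    from lcsurp.wordmodel import word_logprob

    zero = toy_teacher.inv.space.zero_bytes()
    for w in word_support(toy_teacher):
        best = max(
            word_logprob(toy_teacher, w, cat, zero)
            for cat in toy_teacher.inv.real_cat_ids()
        )
        assert best > -np.inf


def test_rejection_counts_are_reported(toy_grammar):
    _, _, info = sample_treebank(toy_grammar, 50, seed=2, max_len=4)
    assert info["n_rejected"] >= 0
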