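"""Decision distributions: normalization, closed forms, support masks."""

import numpy as np
import pytest
from scipy.special import logsumexp

from lcsurp.categories import START_CAT
from lcsurp.contexts import to_bytes
from lcsurp.neural import NeuralConfig, NeuralParameters
from lcsurp.state import EMPTY_STORE, EMPTY_Z, Fragment, Node, h_vec
from lcsurp.transition import TransitionModel

TOL = 1e-9


@pytest.fixture(scope="module")
def neural_tm(tiny_inventories_module):
    inv = tiny_inventories_module
    params = NeuralParameters(
        inv, NeuralConfig(e_lex=6, e_gram=6, e_word=6, mlp_hidden=8,
                          rnn_hidden=8), seed=3
    )
    # non-trivial output layers so the distributions are not uniform
    rng = np.random.default_rng(0)
    for k in ("WX", "bX", "WR", "bR"):
        params.P[k] = rng.normal(0, 0.5, size=params.P[k].shape)
    return TransitionModel(params)


@pytest.fixture(scope="module")
def tiny_inventories_module():
    from lcsurp.categories import make_inventories
    from lcsurp.contexts import ContextSpace
    from lcsurp.morph import MorphRule, RuleInventory

    rules = RuleInventory([MorphRule("%a", "%ba")])
    inv = make_inventories(
        categories=[("N", 0, 0), ("V", 1, 0)],
        predicates=["P0", "P1"],
        V=1,
        E=0,
        rules=rules,
        charset="ab",
        D=3,
    )
    inv.add_lex_context(to_bytes(inv.space.own_onehot("P0")))
    inv.add_lex_context(to_bytes(inv.space.own_onehot("P1")))
    return inv


def store_of(inv, *cats):
    zero = inv.space.zero_bytes()
    q = tuple(Fragment(Node(c, zero), Node(c, zero)) for c in cats)
    H = inv.space.H
    z = tuple(to_bytes(np.eye(H, dtype=np.uint8)) for _ in cats)
    return q, z


@pytest.mark.parametrize("depth_cats", [(), (2,), (2, 3), (3, 2, 3)])
def test_lexical_distribution_normalizes(neural_tm, tiny_inventories_module,
                                         depth_cats):
    q, _ = store_of(tiny_inventories_module, *depth_cats)
    dist = neural_tm.lexical_distribution(q)
    assert abs(np.exp(logsumexp([lp for _, lp in dist])) - 1.0) < TOL


@pytest.mark.parametrize("m_l", [0, 1])
@pytest.mark.parametrize("depth_cats", [(2,), (2, 3)])
def test_grammatical_distribution_normalizes(neural_tm,
                                             tiny_inventories_module,
                                             depth_cats, m_l):
    inv = tiny_inventories_module
    q, _ = store_of(inv, *depth_cats)
    apex = Node(3, to_bytes(inv.space.own_onehot("P0")))
    dist = neural_tm.grammatical_distribution(q, m_l, apex)
    assert abs(np.exp(logsumexp([lp for _, lp in dist])) - 1.0) < TOL


def test_lexical_match_unavailable_at_depth_zero(neural_tm):
    dist = neural_tm.lexical_distribution(EMPTY_STORE)
    assert all(lex.match == 0 for lex, _ in dist)


def test_termination_is_the_only_match_at_the_axiom(neural_tm,
                                                    tiny_inventories_module):
    inv = tiny_inventories_module
    apex = Node(2, inv.space.zero_bytes())
    dist = neural_tm.grammatical_distribution(EMPTY_STORE, 0, apex)
    matches = [g for g, _ in dist if g.match == 1]
    assert matches and all(g.is_termination for g in matches)
    assert len(matches) == 1  # collapsed onto a single termination outcome


def test_zero_logit_scorers_give_uniform_joint_outcomes(
        tiny_inventories_module):
    """With all feedforward weights at zero every (m, h) and (m, o) outcome
    in the support is equiprobable (zero-logit softmax closed form)."""
    inv = tiny_inventories_module
    params = NeuralParameters(
        inv, NeuralConfig(e_lex=4, e_gram=4, e_word=4, mlp_hidden=4,
                          rnn_hidden=4), seed=0
    )
    for k in params.P:
        params.P[k] = np.zeros_like(params.P[k])
    tm = TransitionModel(params)
    q, _ = store_of(inv, 2)
    dist = tm.lexical_distribution(q)
    # joint P(m, h) should be uniform over 2 * n_h outcomes; category factor
    # is uniform as well, so group by (m, h)
    joint = {}
    for lex, lp in dist:
        joint[(lex.match, lex.h_index)] = np.logaddexp(
            joint.get((lex.match, lex.h_index), -np.inf), lp
        )
    vals = np.exp(list(joint.values()))
    assert np.allclose(vals, 1.0 / (2 * inv.n_lex_contexts), atol=TOL)
    apex = Node(2, inv.space.zero_bytes())
    gdist = tm.grammatical_distribution(q, 0, apex)
    gjoint = {}
    for g, lp in gdist:
        gjoint[(g.match, g.op)] = np.logaddexp(
            gjoint.get((g.match, g.op), -np.inf), lp
        )
    gvals = np.exp(list(gjoint.values()))
    n_ops = len(params.operators)
    assert np.allclose(gvals, 1.0 / (2 * n_ops), atol=TOL)


def test_step_distribution_mass_bounded_by_one(neural_tm,
                                               tiny_inventories_module):
    """Summing step mass over the word support never exceeds 1 (equality
    minus depth-pruning and unsupported-word mass)."""
    inv = tiny_inventories_module
    q, z = store_of(inv, 2)
    words = [a + b for a in "ab" for b in "ab"] + list("ab")
    total = -np.inf
    for w in words:
        succ, comp = neural_tm.step_distribution(q, z, w)
        for out in succ.values():
            total = np.logaddexp(total, out.logp)
        if comp.logp > -np.inf:
            total = np.logaddexp(total, comp.logp)
    assert np.exp(total) <= 1.0 + TOL


def test_tabular_teacher_distributions_normalize(toy_teacher):
    tm = TransitionModel(toy_teacher)
    inv = toy_teacher.inv
    dist = tm.lexical_distribution(EMPTY_STORE)
    assert abs(np.exp(logsumexp([lp for _, lp in dist])) - 1.0) < TOL
    zero = inv.space.zero_bytes()
    q = (Fragment(Node(2, zero), Node(2, zero)),)
    dist = tm.lexical_distribution(q)
    assert abs(np.exp(logsumexp([lp for _, lp in dist])) - 1.0) < TOL
    apex = Node(2, zero)
    for m_l, store in ((0, q), (1, q), (0, EMPTY_STORE)):
        if m_l > len(store):
            continue
        g = tm.grammatical_distribution(store, m_l, apex)
        assert abs(np.exp(logsumexp([lp for _, lp in g])) - 1.0) < TOL


def test_distributions_cached_by_conditioning_state(neural_tm,
                                                    tiny_inventories_module):
    q, _ = store_of(tiny_inventories_module, 2)
    d1 = neural_tm.lexical_distribution(q)
    d2 = neural_tm.lexical_distribution(tuple(q))
    assert d1 is d2
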