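"""Left-corner oracle round trips and maximum-likelihood fitting."""

import numpy as np
import pytest

from lcsurp import generate_grammar, sample_treebank, fit_model
from lcsurp.errors import DepthBoundError, StateError
from lcsurp.neural import NeuralConfig
from lcsurp.training import (
    DecisionStep,
    TrainConfig,
    decisions_to_tree,
    left_corner_depth,
    resolve_tree,
    sequence_to_examples,
    tree_to_decisions,
    unresolve_tree,
    _InvProbe,
)
from lcsurp.treebank import format_tree

SMALL_CFG = TrainConfig(
    epochs=3,
    lr=0.02,
    batch_size=16,
    neural=NeuralConfig(e_lex=8, e_gram=8, e_word=8, mlp_hidden=12,
                        rnn_hidden=12),
)


def test_tree_decision_tree_round_trip(toy_teacher, toy_sample):
    """tree -> decisions -> tree is the identity on sampled treebanks."""
    trees, _, _ = toy_sample
    inv = toy_teacher.inv
    for tree in trees:
        rnode = resolve_tree(tree, inv)
        steps = tree_to_decisions(rnode, toy_teacher)
        rebuilt = unresolve_tree(decisions_to_tree(steps, toy_teacher), inv)
        assert format_tree(rebuilt) == format_tree(tree)


def test_decision_sequence_round_trip_is_idempotent(toy_teacher, toy_sample):
    """Extraction of a rebuilt tree reproduces the extracted sequence."""
    trees, _, _ = toy_sample
    inv = toy_teacher.inv
    for tree in trees[:40]:
        steps = tree_to_decisions(resolve_tree(tree, inv), toy_teacher)
        again = tree_to_decisions(decisions_to_tree(steps, toy_teacher),
                                  toy_teacher)
        assert again == steps


def test_decision_counts_match_sentence_length(toy_teacher, toy_sample):
    # one lexical and one grammatical decision per input word
    trees, sents, _ = toy_sample
    inv = toy_teacher.inv
    for tree, sent in zip(trees, sents):
        steps = tree_to_decisions(resolve_tree(tree, inv), toy_teacher)
        assert len(steps) == len(sent)
        assert steps[-1].terminate
        assert not any(s.terminate for s in steps[:-1])


def test_branching_direction_changes_match_bits(toy_teacher):
    """Left- and right-branching 3-word trees produce different (m_l, m_g)
    traces, each verified by replay through the tree oracle."""
    import numpy as np

    from lcsurp.training import RNode
    from lcsurp.treebank import format_tree

    inv = toy_teacher.inv
    zero = inv.space.zero()

    def leaf(w):
        return RNode(2, zero, w, w, 0)

    def binop(l, r):
        n = RNode(2, zero)
        n.attach(l, r)
        return n

    left_tree = binop(binop(leaf("w1"), leaf("w2")), leaf("w3"))
    right_tree = binop(leaf("w1"), binop(leaf("w2"), leaf("w3")))
    patterns = {}
    for name, tree in (("left", left_tree), ("right", right_tree)):
        steps = tree_to_decisions(tree, toy_teacher)
        patterns[name] = tuple((s.m_l, s.m_g) for s in steps)
        # replay-equivalence: the rebuilt tree has the same shape and words
        rebuilt = decisions_to_tree(steps, toy_teacher)
        assert format_tree(unresolve_tree(rebuilt, inv)) == format_tree(
            unresolve_tree(tree, inv)
        )
    assert patterns["left"] == ((0, 0), (1, 0), (1, 1))
    assert patterns["right"] == ((0, 0), (0, 1), (1, 1))


def test_left_corner_depth_matches_replay_bound(toy_teacher, toy_sample):
    trees, _, _ = toy_sample
    inv = toy_teacher.inv
    for tree in trees[:40]:
        d = left_corner_depth(tree)
        assert 0 <= d <= toy_teacher.D
        # replay succeeds exactly because the bound holds
        tree_to_decisions(resolve_tree(tree, inv), toy_teacher)


def test_depth_bound_violation_raises(toy_teacher, toy_sample):
    trees, _, _ = toy_sample
    deep = [t for t in trees if left_corner_depth(t) == 2]
    if not deep:
        pytest.skip("no depth-2 tree sampled")
    inv = toy_teacher.inv

    class Shallow:
        def __init__(self, base):
            self.inv = base.inv
            self.operators = base.operators
            self.H = base.H
            self.D = 1

    with pytest.raises(DepthBoundError):
        tree_to_decisions(resolve_tree(deep[0], inv), Shallow(toy_teacher))


def test_invalid_match_above_store_top_raises(toy_teacher):
    # a grammatical match at depth 1 with no higher fragment is invalid
    inv = toy_teacher.inv
    h = inv.space.zero_bytes()
    bad = [
        DecisionStep(0, 2, h, "w", "w", 0, 1, 0, 2, 2, False),
        DecisionStep(0, 2, h, "w", "w", 0, 1, 0, -1, -1, True),
    ]
    with pytest.raises(StateError):
        decisions_to_tree(bad, toy_teacher)


def test_fit_is_deterministic_given_seed(toy_sample, toy_teacher):
    _, _, info = toy_sample
    seqs = info["sequences"][:40]
    inv = toy_teacher.inv
    m1, h1 = fit_model(seqs, inv, SMALL_CFG, seed=3)
    m2, h2 = fit_model(seqs, inv, SMALL_CFG, seed=3)
    assert h1.epoch_nll == h2.epoch_nll
    for k in m1.P:
        assert (m1.P[k] == m2.P[k]).all()


def test_training_likelihood_decreases(toy_sample, toy_teacher):
    _, _, info = toy_sample
    m, hist = fit_model(info["sequences"], toy_teacher.inv, SMALL_CFG, seed=0)
    assert hist.epoch_nll[-1] < hist.epoch_nll[0]


def test_model_archive_round_trip(tmp_path, toy_sample, toy_teacher):
    from lcsurp.neural import NeuralParameters

    _, _, info = toy_sample
    m, _ = fit_model(info["sequences"][:30], toy_teacher.inv, SMALL_CFG,
                     seed=1)
    path = tmp_path / "model.npz"
    m.save(path)
    back = NeuralParameters.load(path)
    assert back.inv.to_json() == m.inv.to_json()
    for k in m.P:
        assert (back.P[k] == m.P[k]).all()


def test_model_archive_version_check(tmp_path, toy_sample, toy_teacher):
    import json

    import numpy as np

    from lcsurp.errors import ConfigError
    from lcsurp.neural import NeuralParameters

    _, _, info = toy_sample
    m, _ = fit_model(info["sequences"][:10], toy_teacher.inv, SMALL_CFG,
                     seed=1)
    path = tmp_path / "model.npz"
    m.save(path)
    with np.load(path) as data:
        header = json.loads(bytes(data["__header__"]).decode())
        arrays = {k: data[k] for k in data.files if k != "__header__"}
    header["version"] = 999
    with open(path, "wb") as fh:
        np.savez(fh, __header__=np.frombuffer(
            json.dumps(header).encode(), np.uint8), **arrays)
    with pytest.raises(ConfigError):
        NeuralParameters.load(path)


def test_cat_ablation_invariant_to_category_embedding_rows(toy_sample,
                                                           toy_teacher):
    """With -cat, decision scores do not change when the category rows of
    the conditioning embeddings are permuted."""
    from lcsurp.state import Node

    _, _, info = toy_sample
    cfg = TrainConfig(epochs=1, lr=0.02, batch_size=16,
                      neural=SMALL_CFG.neural, ablate_cat=True)
    m, _ = fit_model(info["sequences"][:30], toy_teacher.inv, cfg, seed=2)
    inv = m.inv
    base = Node(2, inv.space.zero_bytes())
    before_lex = m.lex_logits(1, base).copy()
    before_gram = m.gram_logits(1, base, Node(3, inv.space.zero_bytes())).copy()
    rng = np.random.default_rng(0)
    for table in ("E_L", "E_G"):
        m.P[table][: inv.n_cats] = rng.normal(
            size=m.P[table][: inv.n_cats].shape
        )
    assert np.allclose(m.lex_logits(1, base), before_lex)
    assert np.allclose(
        m.gram_logits(1, base, Node(3, inv.space.zero_bytes())), before_gram
    )


def test_morph_ablation_table_is_category_conditioned(toy_sample,
                                                      toy_teacher):
    _, _, info = toy_sample
    cfg = TrainConfig(epochs=1, lr=0.02, batch_size=16,
                      neural=SMALL_CFG.neural, ablate_morph=True)
    m, _ = fit_model(info["sequences"], toy_teacher.inv, cfg, seed=2)
    assert m.word_table is not None
    import math

    for cat, col in m.word_table.items():
        assert abs(sum(math.exp(v) for v in col.values()) - 1.0) < 1e-9


def test_sequence_examples_record_conditioning_state(toy_teacher, toy_sample):
    _, _, info = toy_sample
    probe = _InvProbe(toy_teacher.inv)
    for steps in info["sequences"][:20]:
        exs = sequence_to_examples(steps, probe)
        assert len(exs) == len(steps)
        assert exs[0].depth == 0
        for ex, s in zip(exs, steps):
            assert ex.word == s.word and ex.m_l == s.m_l
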