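"""Left-corner oracle and maximum-likelihood training.

``tree_to_decisions`` performs the left-corner transform: it turns an
annotated CNF tree into the unique sequence of (lexical decision, word,
grammatical decision) triples whose replay reconstructs the tree; one
lexical and one grammatical decision per word.  ``decisions_to_tree`` is
the inverse replay.  Match bits and categories are structurally determined;
the composition operator of each binary branch is recovered by inverting
the annotated context vectors against the operator inventory (the treebank
dialect does not store operator ids), with depth-first backtracking and
canonical (lowest-id) tie-breaking where several operators explain the
same annotations.

Annotation conventions (shared with the synthetic generator): preterminal
nodes store the lexical increment vector h_l; internal nodes store their
creation-time vector (the satisfied prediction for grammatical matches).
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from . import nn
from .categories import Category, Inventories, make_inventories
from .contexts import to_bytes
from .errors import DepthBoundError, FormatError, StateError
from .neural import NeuralConfig, NeuralParameters
from .state import (
    EMPTY_STORE,
    EMPTY_Z,
    GrammaticalDecision,
    Node,
    PRUNED,
    TERMINATION,
    apply_grammatical,
    apply_lexical,
    conditioning_base,
    h_vec,
    update_store,
    update_z,
)
from .transition import gram_support_mask, lex_support_mask
from .treebank import TreeNode, TreebankHeader
from .wordmodel import build_word_table


class RNode:
    """Mutable id-resolved tree node used by the oracle."""

    __slots__ = ("cat", "h", "children", "parent", "word", "lemma", "rule_id")

    def __init__(self, cat, h, word=None, lemma=None, rule_id=None):
        self.cat = cat
        self.h = np.asarray(h, dtype=np.uint8)
        self.children: list["RNode"] = []
        self.parent: "RNode | None" = None
        self.word, self.lemma, self.rule_id = word, lemma, rule_id

    @property
    def is_leaf(self):
        return self.word is not None

    def attach(self, left: "RNode", right: "RNode"):
        self.children = [left, right]
        left.parent = self
        right.parent = self

    def leaves(self):
        if self.is_leaf:
            return [self]
        return [lf for ch in self.children for lf in ch.leaves()]


def resolve_tree(tree: TreeNode, inv: Inventories) -> RNode:
    node = RNode(
        inv.cat_id(tree.label),
        inv.space.vec_from_tokens(tree.ctx_tokens),
        tree.word,
        tree.lemma,
        tree.rule_id,
    )
    if not tree.is_leaf:
        left, right = (resolve_tree(c, inv) for c in tree.children)
        node.attach(left, right)
    return node


def unresolve_tree(node: RNode, inv: Inventories) -> TreeNode:
    label = inv.categories[node.cat].label
    tokens = tuple(inv.space.tokens_from_vec(node.h))
    if node.is_leaf:
        return TreeNode(label, tokens, (), node.word, node.lemma, node.rule_id)
    return TreeNode(
        label, tokens, tuple(unresolve_tree(c, inv) for c in node.children)
    )


class DecisionStep(NamedTuple):
    m_l: int
    c_l: int  # preterminal category (inherited from the base on a match)
    h_l: bytes  # lexical context increment
    word: str
    lemma: str
    rule_id: int
    m_g: int
    op: int
    c_g: int  # parent category; -1 on termination
    c_gp: int  # new base category; -1 on termination
    terminate: bool


def left_corner_depth(root: TreeNode | RNode) -> int:
    """Maximum number of simultaneously open derivation fragments.

    Structure-only simulation of the left-corner transform (match bits are
    determined by the tree shape alone).
    """
    leaves = root.leaves()
    parent: dict[int, object] = {}

    def index(node):
        if not node.is_leaf:
            for ch in node.children:
                parent[id(ch)] = node
                index(ch)

    index(root)
    store: list = []  # fragments as (apex node, predicted base node)
    max_depth = 0
    for p in leaves:
        if store and store[-1][1] is p:
            a = store.pop()[0]  # lexical match completes the fragment
        else:
            a = p
        if a is root:
            continue  # termination (final leaf)
        par = parent[id(a)]
        if store and store[-1][1] is par:
            apex = store.pop()[0]  # grammatical match extends the fragment
            store.append((apex, par.children[1]))
        else:
            store.append((par, par.children[1]))
        max_depth = max(max_depth, len(store))
    return max_depth


def tree_to_decisions(root: RNode, params_like, strict_ops: bool = True
                      ) -> list[DecisionStep]:
    """Left-corner transform of an annotated tree into decision triples.

    ``params_like`` provides ``inv``, ``operators``, ``H`` and ``D``.
    Raises :class:`DepthBoundError` when the tree needs more than D
    fragments, :class:`FormatError` when no operator assignment is
    consistent with the annotations.
    """
    inv, operators = params_like.inv, params_like.operators
    H, D = params_like.H, params_like.D
    leaves = root.leaves()
    n = len(leaves)
    sys.setrecursionlimit(max(sys.getrecursionlimit(), 50 * n + 1000))

    def step_candidates(t, q, z, tstore):
        """Yield (step, q2, z2, tstore2) for consistent operator choices."""
        p_node = leaves[t]
        m_l = 1 if tstore and tstore[-1][1] is p_node else 0
        if m_l and not q:
            raise StateError("oracle match with empty store")
        h_l = to_bytes(p_node.h)
        c_l = p_node.cat
        if m_l and q[-1].base.cat != c_l:
            raise FormatError(
                f"leaf {p_node.word!r} category disagrees with its prediction"
            )
        p, apex = apply_lexical(q, z, m_l, c_l, p_node.h)
        tstore_l = tstore[:-1] if m_l else tstore
        a_node = tstore[-1][0] if m_l else p_node
        if a_node is root:
            if tstore_l or t != n - 1:
                raise FormatError("root completed before the final word")
            step = DecisionStep(m_l, c_l, h_l, p_node.word, p_node.lemma,
                                p_node.rule_id, 1, 0, -1, -1, True)
            yield step, "DONE", EMPTY_Z, ()
            return
        par = a_node.parent
        if par is None or par.children[0] is not a_node:
            raise FormatError("completed subtree is not a left corner")
        sibling = par.children[1]
        m_g = 1 if tstore_l and tstore_l[-1][1] is par else 0
        j = len(q) - m_l
        if m_g and j < 1:
            raise StateError("grammatical match above the store top")
        ha = h_vec(apex.h)
        for op_id, op in enumerate(operators):
            if m_g:
                cond_h = h_vec(q[j - 1].base.h)
                pred_base = (op.B @ np.concatenate([cond_h, ha]) > 0).astype(
                    np.uint8
                )
                if not np.array_equal(h_vec(to_bytes(par.h)), cond_h):
                    # the realized prediction must carry the predicted vector
                    if strict_ops:
                        continue
                c_g = q[j - 1].base.cat
            else:
                pred_par = (op.AT @ ha > 0).astype(np.uint8)
                if not np.array_equal(pred_par, par.h):
                    continue
                zeros = np.zeros(H, dtype=np.uint8)
                pred_base = (op.B @ np.concatenate([zeros, ha]) > 0).astype(
                    np.uint8
                )
                c_g = par.cat
            if not sibling.is_leaf and not np.array_equal(pred_base, sibling.h):
                continue
            g = GrammaticalDecision(m_g, op_id, c_g, sibling.cat)
            nodes = apply_grammatical(q, z, m_l, apex, g, op, H)
            new_apex, new_base = nodes
            q2 = update_store(q, m_l, m_g, new_apex, new_base, D)
            if q2 is PRUNED:
                raise DepthBoundError(
                    f"word {t + 1} ({p_node.word!r}) requires depth > D={D}"
                )
            z2 = update_z(z, m_l, g, op, H)
            if m_g:
                frag = tstore_l[-1]
                tstore2 = tstore_l[:-1] + ((frag[0], sibling),)
            else:
                tstore2 = tstore_l + ((par, sibling),)
            step = DecisionStep(m_l, c_l, h_l, p_node.word, p_node.lemma,
                                p_node.rule_id, m_g, op_id, c_g, sibling.cat,
                                False)
            yield step, q2, z2, tstore2

    def search(t, q, z, tstore):
        for step, q2, z2, tstore2 in step_candidates(t, q, z, tstore):
            if q2 == "DONE":
                return [step] if t == n - 1 else None
            rest = search(t + 1, q2, z2, tstore2)
            if rest is not None:
                return [step] + rest
        return None

    result = search(0, EMPTY_STORE, EMPTY_Z, ())
    if result is None:
        raise FormatError(
            "no operator assignment is consistent with the tree annotations"
        )
    return result


def decisions_to_tree(steps: list[DecisionStep], params_like) -> RNode:
    """Replay a decision sequence into the annotated tree it encodes."""
    inv, operators = params_like.inv, params_like.operators
    H, D = params_like.H, params_like.D
    q, z = EMPTY_STORE, EMPTY_Z
    tstore: list[tuple[RNode, RNode]] = []
    root = None
    for t, s in enumerate(steps):
        h_lv = h_vec(s.h_l)
        p, apex = apply_lexical(q, z, s.m_l, s.c_l, h_lv)
        if s.m_l:
            if not tstore:
                raise StateError(f"step {t}: match with empty store")
            frag = tstore.pop()
            p_node = frag[1]
            p_node.word, p_node.lemma, p_node.rule_id = (
                s.word, s.lemma, s.rule_id,
            )
            p_node.h = np.asarray(h_lv, dtype=np.uint8)  # convention: h_l
            if p_node.children:
                raise StateError(f"step {t}: prediction already realized")
            a_node = frag[0]
        else:
            p_node = RNode(s.c_l, h_lv, s.word, s.lemma, s.rule_id)
            a_node = p_node
        if s.terminate:
            if tstore or t != len(steps) - 1:
                raise StateError(f"step {t}: premature termination")
            g = TERMINATION
            apply_grammatical(q, z, s.m_l, apex, g, operators[0], H)
            root = a_node
            q, z = EMPTY_STORE, EMPTY_Z
            continue
        g = GrammaticalDecision(s.m_g, s.op, s.c_g, s.c_gp)
        op = operators[s.op]
        new_apex, new_base = apply_grammatical(q, z, s.m_l, apex, g, op, H)
        q2 = update_store(q, s.m_l, s.m_g, new_apex, new_base, D)
        if q2 is PRUNED:
            raise DepthBoundError(f"step {t}: replay exceeds depth bound D={D}")
        z = update_z(z, s.m_l, g, op, H)
        sib = RNode(s.c_gp, h_vec(new_base.h))
        if s.m_g:
            frag = tstore.pop()
            par = frag[1]
            par.attach(a_node, sib)
            tstore.append((frag[0], sib))
        else:
            par = RNode(s.c_g, h_vec(new_apex.h))
            par.attach(a_node, sib)
            tstore.append((par, sib))
        q = q2
    if root is None:
        raise StateError("decision sequence did not terminate")
    return root


# ---------------------------------------------------------------------------
# training examples and fitting


class WordExample(NamedTuple):
    depth: int
    base: Node
    m_l: int
    h_idx: int
    c_l: int
    pret_cat: int
    h_l: bytes
    lemma: str
    rule_id: int
    word: str
    cond: Node
    apex: Node
    m_g: int
    op: int
    c_g: int
    c_gp: int
    terminate: bool


def sequence_to_examples(steps, params_like, add_contexts: bool = False
                         ) -> list[WordExample]:
    """Replay one decision sequence, recording the conditioning state of
    every decision.  With ``add_contexts`` unseen h_l vectors are added to
    the lexical-context inventory (training-time behaviour)."""
    inv = params_like.inv
    H, D = params_like.H, params_like.D
    q, z = EMPTY_STORE, EMPTY_Z
    out = []
    for t, s in enumerate(steps):
        depth = len(q)
        base = conditioning_base(q, H)
        if add_contexts:
            h_idx = inv.add_lex_context(s.h_l)
        else:
            h_idx = inv.lex_context_id(s.h_l)
            if h_idx is None:
                h_idx = 0
        p, apex = apply_lexical(q, z, s.m_l, s.c_l, h_vec(s.h_l))
        cond = conditioning_base(q, H, back=s.m_l)
        out.append(
            WordExample(depth, base, s.m_l, h_idx, s.c_l, p.cat, s.h_l,
                        s.lemma, s.rule_id, s.word, cond, apex, s.m_g, s.op,
                        s.c_g, s.c_gp, s.terminate)
        )
        g = (TERMINATION if s.terminate
             else GrammaticalDecision(s.m_g, s.op, s.c_g, s.c_gp))
        op = params_like.operators[s.op]
        nodes = apply_grammatical(q, z, s.m_l, apex, g, op, H)
        if nodes is None:
            q, z = EMPTY_STORE, EMPTY_Z
            continue
        q2 = update_store(q, s.m_l, s.m_g, *nodes, D)
        if q2 is PRUNED:
            raise DepthBoundError(f"step {t}: replay exceeds depth bound")
        z = update_z(z, s.m_l, g, op, H)
        q = q2
    return out


def build_inventories_from_trees(trees, header: TreebankHeader, rules,
                                 D: int | None = None) -> Inventories:
    """Freeze category/predicate/character inventories from a treebank."""
    cats = {c.label: c for c in header.categories}
    preds = list(dict.fromkeys(header.predicates))
    chars: set[str] = set()
    for tree in trees:
        for leaf in tree.leaves():
            chars.update(leaf.lemma)
            chars.update(leaf.word)

        def walk(node):
            if node.label not in cats:
                cats[node.label] = Category(node.label)
            for tok in node.ctx_tokens:
                pred = tok.split("_")[0]
                if pred not in preds:
                    preds.append(pred)
            for ch in node.children:
                walk(ch)

        walk(tree)
    return make_inventories(
        categories=list(cats.values()),
        predicates=preds,
        V=header.V,
        E=header.E,
        rules=rules,
        charset="".join(sorted(chars)),
        D=D if D is not None else header.D,
    )


@dataclass
class TrainConfig:
    epochs: int = 10
    lr: float = 0.01
    batch_size: int = 16
    neural: NeuralConfig = field(default_factory=NeuralConfig)
    ablate_cat: bool = False
    ablate_morph: bool = False
    log_every: int = 0  # epochs between log lines; 0 silences


@dataclass
class TrainingHistory:
    epoch_nll: list[float] = field(default_factory=list)
    n_examples: int = 0


def _example_loss(model: NeuralParameters, G, ex: WordExample,
                  train_word: bool) -> float:
    n_h = model.inv.n_lex_contexts
    loss = model.lex_loss(G, ex.depth, ex.base, ex.m_l, ex.h_idx,
                          lex_support_mask(ex.depth, n_h))
    if ex.m_l == 0:
        loss += model.lexcat_loss(G, ex.depth, ex.base, 0, ex.h_idx, ex.c_l)
    if train_word:
        loss += model.word_loss(G, ex.lemma, ex.rule_id, ex.pret_cat, ex.h_l)
    j = ex.depth - ex.m_l
    loss += model.gram_loss(G, ex.depth, ex.cond, ex.apex, ex.m_g, ex.op,
                            gram_support_mask(j, model.n_ops))
    if not ex.terminate:
        if ex.m_g == 0:
            loss += model.gramcat_loss(G, ex.depth, ex.cond, ex.apex, 0,
                                       ex.op, ex.c_g)
        loss += model.grambase_loss(G, ex.depth, ex.cond, ex.apex, ex.m_g,
                                    ex.op, ex.c_g, ex.c_gp)
    return loss


def fit_model(data, inv: Inventories, config: TrainConfig | None = None,
              seed: int = 0) -> tuple[NeuralParameters, TrainingHistory]:
    """Maximum-likelihood fit of the neural parameters.

    ``data`` is a list of decision sequences (lists of
    :class:`DecisionStep`); use :func:`tree_to_decisions` to obtain them
    from an annotated treebank.  Deterministic given ``seed``.
    """
    config = config or TrainConfig()
    examples: list[WordExample] = []
    probe = _InvProbe(inv)
    for steps in data:
        examples.extend(sequence_to_examples(steps, probe, add_contexts=True))
    if not examples:
        raise ValueError("empty training data")
    model = NeuralParameters(inv, config.neural, seed=seed,
                             ablate_cat=config.ablate_cat)
    opt = nn.Adam(model.P, lr=config.lr)
    rng = np.random.default_rng(seed + 1)
    history = TrainingHistory(n_examples=len(examples))
    order = np.arange(len(examples))
    train_word = not config.ablate_morph
    for epoch in range(config.epochs):
        rng.shuffle(order)
        total = 0.0
        G = nn.zeros_like_params(model.P)
        pending = 0
        for idx in order:
            total += _example_loss(model, G, examples[idx], train_word)
            pending += 1
            if pending == config.batch_size:
                for k in G:
                    G[k] /= pending
                opt.step(model.P, G)
                G = nn.zeros_like_params(model.P)
                pending = 0
        if pending:
            for k in G:
                G[k] /= pending
            opt.step(model.P, G)
        nll = total / len(examples)
        history.epoch_nll.append(nll)
        if not np.isfinite(nll):
            raise FloatingPointError(
                f"non-finite training loss at epoch {epoch}"
            )
        if config.log_every and (epoch + 1) % config.log_every == 0:
            print(f"epoch {epoch + 1}: mean NLL {nll:.4f}")
    if config.ablate_morph:
        model.word_table = build_word_table(
            (ex.pret_cat, ex.word) for ex in examples
        )
    model.clear_caches()
    return model, history


class _InvProbe:
    """Adapter exposing inventories/operators for the replay helpers."""

    def __init__(self, inv: Inventories):
        from .operators import build_operators

        self.inv = inv
        self.operators = build_operators(inv.space)
        self.H = inv.space.H
        self.D = inv.D


def make_ablation(which: str, data, inv: Inventories,
                  config: TrainConfig | None = None, seed: int = 0
                  ) -> tuple[NeuralParameters, TrainingHistory]:
    """Retrain an ablated variant from scratch on the same data.

    ``which='cat'`` zeroes the category embeddings in the lexical and
    grammatical conditioning features; ``which='morph'`` replaces the
    character-based word model with a relative-frequency table.
    """
    config = config or TrainConfig()
    if which == "cat":
        cfg = TrainConfig(config.epochs, config.lr, config.batch_size,
                          config.neural, ablate_cat=True,
                          ablate_morph=config.ablate_morph,
                          log_every=config.log_every)
    elif which == "morph":
        cfg = TrainConfig(config.epochs, config.lr, config.batch_size,
                          config.neural, ablate_cat=config.ablate_cat,
                          ablate_morph=True, log_every=config.log_every)
    else:
        from .errors import ConfigError

        raise ConfigError(f"unknown ablation {which!r}")
    return fit_model(data, inv, cfg, seed=seed)
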