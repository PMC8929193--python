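"""Store states and the left-corner transition (node construction, store
update, Z propagation).

A store state is the parser's working memory: a bounded stack of nested
derivation fragments, each an (apex, base) pair of nodes.  Only the
non-null prefix is stored; ``depth(q) = len(q)``.  The sentence-initial
store is empty, with an implicit axiom fragment at depth 0 whose base is
the reserved START node: the lexical decision at depth 0 conditions on it,
and the grammatical match against it is the sentence-termination event.

Every update here is a pure function; nodes and fragments are immutable
tuples so that store states can serve as beam merge keys.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from .categories import START_CAT
from .contexts import binarize, to_bytes
from .errors import StateError
from .operators import CompositionOperator


class Node(NamedTuple):
    cat: int
    h: bytes  # binary context vector, H bytes (one byte per entry)


class Fragment(NamedTuple):
    apex: Node
    base: Node


StoreState = tuple[Fragment, ...]
ZState = tuple[bytes, ...]  # one binarized H x H matrix per fragment (deepest last)

EMPTY_STORE: StoreState = ()
EMPTY_Z: ZState = ()

# sentinel results of update_store
PRUNED = "PRUNED"
COMPLETE = "COMPLETE"


def h_vec(h: bytes) -> np.ndarray:
    return np.frombuffer(h, dtype=np.uint8)


def z_mat(z: bytes, H: int) -> np.ndarray:
    return np.frombuffer(z, dtype=np.uint8).reshape(H, H)


def start_node(H: int) -> Node:
    return Node(START_CAT, bytes(H))


def depth(q: StoreState) -> int:
    return len(q)


def or_bytes(a: bytes, b: bytes) -> bytes:
    return to_bytes(h_vec(a) | h_vec(b))


class LexicalDecision(NamedTuple):
    match: int  # m_l
    cat: int  # c_l; on a match this is the inherited base category
    h_index: int  # index into the lexical-context support inventory


class GrammaticalDecision(NamedTuple):
    match: int  # m_g
    op: int  # composition operator id (0 on termination)
    parent_cat: int  # c_g; inherited prediction on a match, -1 on termination
    base_cat: int  # c'_g; -1 on termination

    @property
    def is_termination(self) -> bool:
        return self.match == 1 and self.base_cat == -1


TERMINATION = GrammaticalDecision(1, 0, -1, -1)


def conditioning_base(q: StoreState, H: int, back: int = 0) -> Node:
    """Base node at depth ``len(q) - back``; the axiom START node at depth 0."""
    j = len(q) - back
    if j < 0:
        raise StateError("conditioning index below the axiom")
    if j == 0:
        return start_node(H)
    return q[j - 1].base


def apply_lexical(
    q: StoreState, z: ZState, match: int, cat: int, h_l: np.ndarray
) -> tuple[Node, Node]:
    """Construct the preterminal and the lexical-phase apex node.

    No-match: both are the fresh node (c_l, h_l).  Match: the preterminal
    completes the deepest base (category inherited, contexts OR-ed in) and
    the apex is the deepest fragment's apex with the preterminal's contexts
    propagated up through that fragment's Z matrix.
    """
    H = len(h_l)
    hb = to_bytes(h_l)
    if not match:
        p = Node(cat, hb)
        return p, p
    if not q:
        raise StateError("lexical match with an empty store")
    frag = q[-1]
    p = Node(frag.base.cat, or_bytes(frag.base.h, hb))
    Z = z_mat(z[-1], H)
    up = binarize(Z @ h_vec(p.h))
    apex = Node(frag.apex.cat, to_bytes(h_vec(frag.apex.h) | up))
    return p, apex


def apply_grammatical(
    q: StoreState,
    z: ZState,
    m_l: int,
    apex: Node,
    g: GrammaticalDecision,
    op: CompositionOperator,
    H: int,
) -> tuple[Node, Node] | None:
    """Construct the new fragment's apex and base; None on termination."""
    j = len(q) - m_l
    if g.is_termination:
        if j != 0:
            raise StateError("termination with fragments still open")
        return None
    ha = h_vec(apex.h)
    if g.match:
        if j < 1:
            raise StateError("grammatical match above the store top")
        frag = q[j - 1]
        zl = z[:-1] if m_l else z
        Z = z_mat(zl[-1], H)
        up = binarize(Z @ binarize(op.AT @ ha))
        new_apex = Node(frag.apex.cat, to_bytes(h_vec(frag.apex.h) | up))
        hb = h_vec(frag.base.h)
        new_base = Node(
            g.base_cat, to_bytes(binarize(op.B @ np.concatenate([hb, ha])))
        )
    else:
        new_apex = Node(g.parent_cat, to_bytes(binarize(op.AT @ ha)))
        zeros = np.zeros(H, dtype=np.uint8)
        new_base = Node(
            g.base_cat, to_bytes(binarize(op.B @ np.concatenate([zeros, ha])))
        )
    return new_apex, new_base


def update_z(
    z: ZState, m_l: int, g: GrammaticalDecision, op: CompositionOperator, H: int
) -> ZState:
    """Advance the per-fragment Z stack.

    A lexical match pops the completed fragment's matrix; a grammatical
    no-match pushes [0,I]B^T for the new fragment; a grammatical match
    right-multiplies the enclosing fragment's matrix by [0,I]B^T.  Matrices
    are binarized after every product: only sat(Z h) is ever consumed, so
    this loses nothing and keeps merge keys canonical.
    """
    zl = z[:-1] if m_l else z
    if g.is_termination:
        if zl:
            raise StateError("termination with a non-empty Z stack")
        return EMPTY_Z
    step = op.Z_step  # [0, I] B^T
    if g.match:
        if not zl:
            raise StateError("Z update for a match with an empty stack")
        top = z_mat(zl[-1], H)
        return zl[:-1] + (to_bytes(binarize(top @ step)),)
    return zl + (to_bytes(binarize(step)),)


def update_store(
    q: StoreState,
    m_l: int,
    m_g: int,
    new_apex: Node | None,
    new_base: Node | None,
    D: int,
):
    """Store update: fragments above d carried forward, fragment d replaced,
    deeper fragments nulled, with d = depth(q) + 1 - m_l - m_g.

    Returns the new store, or PRUNED when d would exceed the depth bound D,
    or COMPLETE when d = 0 (termination).
    """
    d = len(q) + 1 - m_l - m_g
    if d < 0:
        raise StateError(f"store update with d={d}")
    if d == 0:
        return COMPLETE
    if d > D:
        return PRUNED
    if new_apex is None or new_base is None:
        raise StateError("missing fragment nodes for a non-terminating update")
    return q[: d - 1] + (Fragment(new_apex, new_base),)


def step_state(
    q: StoreState,
    z: ZState,
    lex: LexicalDecision,
    g: GrammaticalDecision,
    op: CompositionOperator,
    H: int,
    D: int,
    h_l: np.ndarray,
):
    """Apply one full word transition; returns (q', z', preterminal) or the
    PRUNED / COMPLETE sentinel in place of q'."""
    p, apex = apply_lexical(q, z, lex.match, lex.cat, h_l)
    nodes = apply_grammatical(q, z, lex.match, apex, g, op, H)
    if nodes is None:
        new_apex = new_base = None
    else:
        new_apex, new_base = nodes
    q2 = update_store(q, lex.match, g.match, new_apex, new_base, D)
    if q2 is PRUNED:
        return PRUNED, None, p
    if q2 is COMPLETE:
        return COMPLETE, EMPTY_Z, p
    z2 = update_z(z, lex.match, g, op, H)
    return q2, z2, p
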