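"""Store-state updates, Z propagation, and context-vector algebra."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lcsurp.categories import START_CAT
from lcsurp.contexts import ContextSpace, to_bytes
from lcsurp.errors import StateError
from lcsurp.operators import build_operators
from lcsurp.state import (
    COMPLETE,
    EMPTY_Z,
    Fragment,
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

SPACE = ContextSpace.build(["EAT", "PASTA"], V=1, E=0)
H = SPACE.H
OPS = build_operators(SPACE)


def node(cat, vec=None):
    v = SPACE.zero() if vec is None else vec
    return Node(cat, to_bytes(v))


def frag(cat=2):
    return Fragment(node(cat), node(cat))


# ---------------------------------------------------------------------------
# store update: Eq-5 bookkeeping against a naive reference over null-padded
# stores of exactly D slots


def naive_update(q, m_l, m_g, new_frag, D):
    padded = list(q) + [None] * (D - len(q))
    d = len(q) + 1 - m_l - m_g
    if d == 0:
        return COMPLETE
    if d > D:
        return PRUNED
    out = []
    for i in range(D):
        if i + 1 < d:
            out.append(padded[i])
        elif i + 1 == d:
            out.append(new_frag)
        else:
            out.append(None)
    while out and out[-1] is None:
        out.pop()
    assert all(f is not None for f in out), "contiguity violated"
    return tuple(out)


@pytest.mark.parametrize("m_l,m_g", [(0, 0), (0, 1), (1, 0), (1, 1)])
@pytest.mark.parametrize("depth", [1, 2, 3])
def test_update_store_matches_naive_reference(m_l, m_g, depth):
    D = 3
    q = tuple(frag(2 + (i % 2)) for i in range(depth))
    nf = Fragment(node(3), node(2))
    got = update_store(q, m_l, m_g, nf.apex, nf.base, D)
    want = naive_update(q, m_l, m_g, nf, D)
    assert got == want


def test_update_store_pushes_and_prunes_at_depth_bound():
    D = 4
    q = tuple(frag() for _ in range(2))
    nf = frag(3)
    assert len(update_store(q, 0, 0, nf.apex, nf.base, D)) == 3
    q4 = tuple(frag() for _ in range(D))
    assert update_store(q4, 0, 0, nf.apex, nf.base, D) is PRUNED


def test_update_store_join_reduces_depth():
    q = tuple(frag() for _ in range(2))
    nf = frag(3)
    assert len(update_store(q, 1, 1, nf.apex, nf.base, 4)) == 1


@settings(max_examples=100, deadline=None)
@given(
    depth=st.integers(0, 4),
    m_l=st.integers(0, 1),
    m_g=st.integers(0, 1),
)
def test_store_contiguity_invariant(depth, m_l, m_g):
    D = 4
    q = tuple(frag() for _ in range(depth))
    d = depth + 1 - m_l - m_g
    if d < 0:
        return
    nf = frag(3)
    got = update_store(q, m_l, m_g, nf.apex, nf.base, D)
    if got in (PRUNED, COMPLETE):
        return
    assert got == naive_update(q, m_l, m_g, nf, D)
    assert all(f is not None for f in got)  # non-null contiguous prefix


# ---------------------------------------------------------------------------
# lexical node construction (preterminal and apex)


def test_lexical_no_match_builds_fresh_preterminal():
    h_l = SPACE.own_onehot("EAT")
    p, apex = apply_lexical((), EMPTY_Z, 0, 5, h_l)
    assert p == Node(5, to_bytes(h_l))
    assert apex == p


def test_lexical_match_inherits_category_and_ors_contexts():
    h_b = SPACE.own_onehot("PASTA")
    base = node(3, h_b)
    q = (Fragment(node(2), base),)
    z = (to_bytes(np.zeros((H, H), dtype=np.uint8)),)
    h_l = SPACE.own_onehot("EAT")
    p, apex = apply_lexical(q, z, 1, 99, h_l)
    assert p.cat == 3  # inherited from the base, not the decision
    assert (h_vec(p.h) == (h_b | h_l)).all()


def test_lexical_match_zero_increment_keeps_base_contexts():
    h_b = SPACE.own_onehot("PASTA")
    q = (Fragment(node(2), node(3, h_b)),)
    z = (to_bytes(np.zeros((H, H), dtype=np.uint8)),)
    p, _ = apply_lexical(q, z, 1, 0, SPACE.zero())
    assert p.h == to_bytes(h_b)


def test_lexical_match_identity_z_propagates_preterminal_to_apex():
    h_b = SPACE.own_onehot("PASTA")
    q = (Fragment(node(2), node(3, h_b)),)
    z = (to_bytes(np.eye(H, dtype=np.uint8)),)
    _, apex = apply_lexical(q, z, 1, 0, SPACE.zero())
    assert apex.h == to_bytes(h_b)  # apex had zero contexts; gets Z @ h_p


def test_lexical_match_on_empty_store_is_an_error():
    with pytest.raises(StateError):
        apply_lexical((), EMPTY_Z, 1, 0, SPACE.zero())


# ---------------------------------------------------------------------------
# grammatical node construction


def op_by_name(name):
    return next(o for o in OPS if o.name == name)


def test_no_match_identity_operator_copies_apex_contexts():
    apex = node(4, SPACE.own_onehot("EAT"))
    g = GrammaticalDecision(0, 0, 5, 6)
    new_apex, new_base = apply_grammatical((), EMPTY_Z, 0, apex, g, OPS[0], H)
    assert new_apex == Node(5, apex.h)  # A = I
    assert h_vec(new_base.h).sum() == 0  # B = [I | 0]: base half zeroed


def test_no_match_base_ignores_outer_prediction():
    # the base-parent block is zeroed on a no-match, so the new base depends
    # only on the apex contexts even for operators with a nonzero left half
    apex = node(4, SPACE.own_onehot("EAT"))
    conj = op_by_name("conjunction_carry")
    g = GrammaticalDecision(0, conj.op_id, 5, 6)
    q = (Fragment(node(2), node(3, SPACE.own_onehot("PASTA"))),)
    z = (to_bytes(np.zeros((H, H), np.uint8)),)
    _, new_base = apply_grammatical(q, z, 0, apex, g, conj, H)
    assert new_base.h == apex.h


def test_match_with_carry_operator_keeps_base_contexts():
    # B = [I | 0] (identity carry): the new base repeats the prediction
    h_b = SPACE.own_onehot("PASTA")
    q = (Fragment(node(2, SPACE.zero()), node(3, h_b)),)
    z = (to_bytes(np.zeros((H, H), np.uint8)),)
    apex = node(4, SPACE.own_onehot("EAT"))
    g = GrammaticalDecision(1, 0, 3, 6)
    new_apex, new_base = apply_grammatical(q, z, 0, apex, g, OPS[0], H)
    assert new_base.h == to_bytes(h_b)
    assert new_apex.cat == 2  # apex of the extended fragment is kept


def test_termination_requires_empty_effective_store():
    apex = node(4)
    assert apply_grammatical((), EMPTY_Z, 0, apex, TERMINATION, OPS[0], H) is None
    q = (frag(),)
    z = (to_bytes(np.zeros((H, H), np.uint8)),)
    with pytest.raises(StateError):
        apply_grammatical(q, z, 0, apex, TERMINATION, OPS[0], H)


# ---------------------------------------------------------------------------
# Z stack


def test_z_push_is_transposed_apex_half_of_B():
    conj = op_by_name("conjunction_carry")  # B = [I | I] => [0,I]B^T = I
    g = GrammaticalDecision(0, conj.op_id, 5, 6)
    z = update_z(EMPTY_Z, 0, g, conj, H)
    assert len(z) == 1
    assert (np.frombuffer(z[0], np.uint8).reshape(H, H) == np.eye(H)).all()


def test_z_match_multiplies_top():
    conj = op_by_name("conjunction_carry")
    g0 = GrammaticalDecision(0, conj.op_id, 5, 6)
    z = update_z(EMPTY_Z, 0, g0, conj, H)
    arg = op_by_name("arg_1")
    g1 = GrammaticalDecision(1, arg.op_id, 5, 6)
    z2 = update_z(z, 0, g1, arg, H)
    step = (arg.Z_step > 0).astype(np.uint8)
    top = np.frombuffer(z2[0], np.uint8).reshape(H, H)
    assert (top == ((np.eye(H, dtype=np.uint8) @ step) > 0).astype(np.uint8)).all()
    # applying the same match again squares the step factor
    z3 = update_z(z2, 0, g1, arg, H)
    top3 = np.frombuffer(z3[0], np.uint8).reshape(H, H)
    assert (top3 == ((top @ step) > 0).astype(np.uint8)).all()


def test_z_stack_height_tracks_store_depth():
    conj = op_by_name("conjunction_carry")
    g0 = GrammaticalDecision(0, conj.op_id, 5, 6)
    z1 = update_z(EMPTY_Z, 0, g0, conj, H)
    z2 = update_z(z1, 0, g0, conj, H)
    assert len(z2) == 2
    # lexical match pops before the grammatical update
    z1b = update_z(z2, 1, g0, conj, H)
    assert len(z1b) == 2  # pop then push


def test_conditioning_base_is_axiom_at_depth_zero():
    assert conditioning_base((), H) == Node(START_CAT, bytes(H))
    q = (frag(7),)
    assert conditioning_base(q, H).cat == 7
    assert conditioning_base(q, H, back=1).cat == START_CAT
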