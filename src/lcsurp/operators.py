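"""Predicate-context composition operators.

Each operator o carries two sparse binary matrices: ``A`` (H x H), whose
transpose maps the completed left child's context vector into the parent
apex vector, and ``B`` (H x 2H), which maps the concatenation of the outer
predicted base's vector and the left child's vector into the newly
predicted base (right sibling) vector.

The operator inventory is constructed programmatically from the block
layout of the context space (own-referent block, argument blocks 1..V,
non-local blocks 1..E):

* ``identity_carry`` — A^T = I, B = [I | 0]: the prediction is carried
  downward unchanged.
* ``conjunction_carry`` — A^T = I, B = [I | I]: the new base shares all
  contexts of both the prediction and the left conjunct.
* ``arg_k`` (k = 1..V) — head-left argument attachment: the parent shares
  the head child's referent; the predicted sibling's own block receives the
  head's own contexts role-shifted from 0 to k (it is the k-th participant
  of the head's predications) plus any argument-k constraints passed down
  from the outer prediction; non-local blocks are carried down.
* ``mod`` — head-left modifier attachment: the predicted sibling is a
  modifier whose first argument slot receives the head's own contexts;
  non-local blocks are carried down.
* ``gap_intro_e`` / ``gap_fill_e`` (e = 1..E) — move contexts between the
  own block and non-local block e, introducing or discharging a non-local
  dependency.

These reconstruct the intended semantics from the block layout; they are a
package-defined inventory, documented as such in docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contexts import ContextSpace


@dataclass(frozen=True)
class CompositionOperator:
    op_id: int
    name: str
    A: np.ndarray  # (H, H) uint8; apply as A.T @ h_child
    B: np.ndarray  # (H, 2H) uint8; apply as B @ [h_base; h_child]

    def __post_init__(self):
        H = self.A.shape[0]
        assert self.A.shape == (H, H) and self.B.shape == (H, 2 * H)
        assert self.A.dtype == np.uint8 and self.B.dtype == np.uint8
        assert self.A.max(initial=0) <= 1 and self.B.max(initial=0) <= 1

    @property
    def AT(self) -> np.ndarray:
        return self.A.T

    @property
    def B_base(self) -> np.ndarray:
        """Left half of B (acts on the outer predicted base vector)."""
        H = self.A.shape[0]
        return self.B[:, :H]

    @property
    def B_child(self) -> np.ndarray:
        """Right half of B (acts on the completed left child vector)."""
        H = self.A.shape[0]
        return self.B[:, H:]

    @property
    def Z_step(self) -> np.ndarray:
        """[0, I] B^T: the per-step factor of the Z propagation matrix."""
        return self.B_child.T.copy()


def _role_shift(space: ContextSpace, k: int) -> np.ndarray:
    """K x K map sending <p, 0> to <p, k> and dropping everything else."""
    S = np.zeros((space.K, space.K), dtype=np.uint8)
    for p in range(len(space.predicates)):
        S[space.ctx_index(p, k), space.ctx_index(p, 0)] = 1
    return S


def _place(M: np.ndarray, space: ContextSpace, dst_block: int, src_block: int,
           kmat: np.ndarray) -> None:
    M[space.block_slice(dst_block), space.block_slice(src_block)] |= kmat


def build_operators(space: ContextSpace) -> list[CompositionOperator]:
    """Canonical operator inventory for a context space.

    Order (fixed): identity_carry, conjunction_carry, arg_1..arg_V, mod,
    gap_intro_1..E, gap_fill_1..E.
    """
    H, K, V, E = space.H, space.K, space.V, space.E
    I_H = np.eye(H, dtype=np.uint8)
    I_K = np.eye(K, dtype=np.uint8)
    Z_H = np.zeros((H, H), dtype=np.uint8)
    ops: list[CompositionOperator] = []

    def add(name, AT, L, R):
        ops.append(
            CompositionOperator(
                len(ops), name, np.ascontiguousarray(AT.T), np.hstack([L, R])
            )
        )

    # identity_carry
    add("identity_carry", I_H.copy(), I_H.copy(), Z_H.copy())
    # conjunction_carry
    add("conjunction_carry", I_H.copy(), I_H.copy(), I_H.copy())
    # arg_k
    for k in range(1, V + 1):
        AT = I_H.copy()
        _place(AT, space, k, 0, _role_shift(space, k))  # parent's arg-k from own
        L = np.zeros((H, H), dtype=np.uint8)
        _place(L, space, 0, k, I_K)  # outer base's arg-k constraints -> sibling own
        for e in range(1, E + 1):
            _place(L, space, V + e, V + e, I_K)  # gaps propagate rightward
        R = np.zeros((H, H), dtype=np.uint8)
        _place(R, space, 0, 0, _role_shift(space, k))  # sibling is participant k
        add(f"arg_{k}", AT, L, R)
    # mod
    AT = I_H.copy()
    L = np.zeros((H, H), dtype=np.uint8)
    for e in range(1, E + 1):
        _place(L, space, V + e, V + e, I_K)
    R = np.zeros((H, H), dtype=np.uint8)
    if V >= 1:
        _place(R, space, 1, 0, I_K)  # head is argument 1 of the modifier
    else:
        _place(R, space, 0, 0, I_K)
    add("mod", AT, L, R)
    # gap operators
    for e in range(1, E + 1):
        AT = I_H.copy()
        _place(AT, space, V + e, 0, I_K)  # own contexts become a pending gap
        L = I_H.copy()
        R = np.zeros((H, H), dtype=np.uint8)
        _place(R, space, V + e, 0, I_K)
        add(f"gap_intro_{e}", AT, L, R)
    for e in range(1, E + 1):
        AT = I_H.copy()
        AT[space.block_slice(V + e), :] = 0  # gap discharged
        L = I_H.copy()
        _place(L, space, 0, V + e, I_K)  # gap contexts land on the filler
        R = np.zeros((H, H), dtype=np.uint8)
        add(f"gap_fill_{e}", AT, L, R)
    return ops
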