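"""Predicate context vectors.

A predicate context is a <predicate, role> pair constraining which
participant of which predication a node's referent is.  Each node carries a
binary vector over ``H = K + V*K + E*K`` entries: one block of ``K`` entries
for the node's own referent, one block per local argument slot ``1..V`` and
one block per non-local (gap) slot ``1..E``.  ``K`` is the number of
distinct <predicate, role> pairs, laid out as ``predicate * (V+1) + role``.

The block layout (own block first, then argument blocks, then non-local
blocks) is a package convention; only the total dimension is dictated by
the model.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError

UNK_PREDICATE = "-UNK-"

_TOKEN_RE = re.compile(r"^(?P<pred>[^\s_]+)_(?P<role>\d+)(?:\.(?P<block>\d+))?$")


def to_bytes(vec: np.ndarray) -> bytes:
    return np.ascontiguousarray(vec, dtype=np.uint8).tobytes()


def binarize(vec: np.ndarray) -> np.ndarray:
    """Saturating reduction to {0,1} (logical OR semantics for +)."""
    return (np.asarray(vec) > 0).astype(np.uint8)


@dataclass(frozen=True)
class ContextSpace:
    """Dimensions and codecs for predicate context vectors.

    Parameters
    ----------
    predicates : tuple of str
        Predicate (lemma) inventory.  Index 0 is reserved for the unknown
        predicate so that arbitrary corpora can be scored.
    V : int
        Maximum valence (local argument slots) of any syntactic category.
    E : int
        Maximum number of non-local dependency slots.
    """

    predicates: tuple[str, ...]
    V: int
    E: int
    _pred_index: dict = field(init=False, repr=False, hash=False, compare=False)

    def __post_init__(self):
        if self.V < 0 or self.E < 0:
            raise ValueError("V and E must be non-negative")
        if not self.predicates or self.predicates[0] != UNK_PREDICATE:
            raise ValueError("predicates[0] must be the reserved unknown predicate")
        object.__setattr__(
            self, "_pred_index", {p: i for i, p in enumerate(self.predicates)}
        )

    @classmethod
    def build(cls, predicates, V: int, E: int) -> "ContextSpace":
        preds = [UNK_PREDICATE] + [p for p in predicates if p != UNK_PREDICATE]
        return cls(tuple(preds), V, E)

    @property
    def n_roles(self) -> int:
        return self.V + 1

    @property
    def K(self) -> int:
        return len(self.predicates) * self.n_roles

    @property
    def n_blocks(self) -> int:
        return 1 + self.V + self.E

    @property
    def H(self) -> int:
        return self.K * self.n_blocks

    # -- indexing ---------------------------------------------------------

    def pred_id(self, predicate: str) -> int:
        return self._pred_index.get(predicate, 0)

    def ctx_index(self, pred_id: int, role: int) -> int:
        if not (0 <= role < self.n_roles):
            raise ValueError(f"role {role} outside 0..{self.V}")
        return pred_id * self.n_roles + role

    def block_slice(self, block: int) -> slice:
        if not (0 <= block < self.n_blocks):
            raise ValueError(f"block {block} outside 0..{self.n_blocks - 1}")
        return slice(block * self.K, (block + 1) * self.K)

    # -- vectors ----------------------------------------------------------

    def zero(self) -> np.ndarray:
        return np.zeros(self.H, dtype=np.uint8)

    def zero_bytes(self) -> bytes:
        return bytes(self.H)

    def own_onehot(self, predicate: str, role: int = 0) -> np.ndarray:
        """Vector with the single entry <predicate, role> set in the own block."""
        v = self.zero()
        v[self.ctx_index(self.pred_id(predicate), role)] = 1
        return v

    # -- text codec -------------------------------------------------------

    def parse_token(self, token: str, line: int | None = None) -> int:
        """Parse ``PREDICATE_role[.block]`` into a flat vector index."""
        m = _TOKEN_RE.match(token)
        if m is None:
            raise FormatError(f"malformed context token {token!r}", line)
        pred = self.pred_id(m.group("pred"))
        role = int(m.group("role"))
        block = int(m.group("block") or 0)
        if role >= self.n_roles:
            raise FormatError(f"role {role} exceeds V={self.V} in {token!r}", line)
        if block >= self.n_blocks:
            raise FormatError(f"block {block} exceeds 1+V+E in {token!r}", line)
        return block * self.K + self.ctx_index(pred, role)

    def vec_from_tokens(self, tokens, line: int | None = None) -> np.ndarray:
        v = self.zero()
        for tok in tokens:
            if tok:
                v[self.parse_token(tok, line)] = 1
        return v

    def tokens_from_vec(self, vec: np.ndarray) -> list[str]:
        out = []
        for idx in np.flatnonzero(vec):
            block, within = divmod(int(idx), self.K)
            pred_id, role = divmod(within, self.n_roles)
            tok = f"{self.predicates[pred_id]}_{role}"
            if block:
                tok += f".{block}"
            out.append(tok)
        return out
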