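"""Decision distributions and the one-word transition over store states.

Each time step consumes one word in two phases: a lexical decision
(match bit, lexical context vector, and — on a no-match — a fresh
preterminal category), word generation conditioned on the resulting
preterminal, and a grammatical decision (match bit, composition operator,
and the categories of the new fragment).  Supports are finite: context
vectors range over the frozen lexical-context inventory, categories over
the generable inventory, operators over the canonical operator set.

Support restrictions (applied as softmax masks, identically in training
and decoding):

* at depth 0 the lexical match is unavailable (nothing to complete);
* a grammatical match against the axiom (conditioning index 0) is the
  sentence-termination event and is collapsed onto operator id 0 with no
  category decisions.

A grammatical no-match that would push beyond the depth bound D keeps its
probability in the decision distribution but yields no successor: that
mass is pruned, exactly as a bounded-memory parser loses it.
"""

from __future__ import annotations

import numpy as np

from .nn import log_softmax
from .state import (
    COMPLETE,
    PRUNED,
    EMPTY_Z,
    GrammaticalDecision,
    LexicalDecision,
    Node,
    StoreState,
    TERMINATION,
    ZState,
    apply_grammatical,
    apply_lexical,
    conditioning_base,
    h_vec,
    update_store,
    update_z,
)
from .categories import N_RESERVED_CATS
from .wordmodel import word_logprob

NEG_INF = -np.inf


def lex_support_mask(depth: int, n_h: int) -> np.ndarray:
    """(2, n_h) mask over joint (m_l, h_l) outcomes."""
    mask = np.ones((2, n_h), dtype=bool)
    if depth == 0:
        mask[1, :] = False
    return mask


def gram_support_mask(j: int, n_ops: int) -> np.ndarray:
    """(2, n_ops) mask over joint (m_g, o_g) outcomes; j = depth - m_l."""
    mask = np.ones((2, n_ops), dtype=bool)
    if j == 0:
        mask[1, 1:] = False  # termination collapses onto operator 0
    return mask


class StepOutcome:
    """Aggregated successor mass with the best single derivation tracked."""

    __slots__ = ("logp", "best_logp", "best_decisions")

    def __init__(self):
        self.logp = NEG_INF
        self.best_logp = NEG_INF
        self.best_decisions = None

    def add(self, logp: float, decisions) -> None:
        self.logp = np.logaddexp(self.logp, logp)
        if logp > self.best_logp:
            self.best_logp = logp
            self.best_decisions = decisions


class TransitionModel:
    """Probabilistic left-corner transition driven by a parameter set."""

    def __init__(self, params):
        self.params = params
        self.inv = params.inv
        self.ops = params.operators
        self.H = params.H
        self.D = params.D
        self._lex_cache: dict = {}
        self._gram_cache: dict = {}
        self._word_cache: dict = {}
        self._step_cache: dict = {}

    def clear_caches(self):
        self._lex_cache.clear()
        self._gram_cache.clear()
        self._word_cache.clear()
        self._step_cache.clear()
        if hasattr(self.params, "clear_caches"):
            self.params.clear_caches()

    # ------------------------------------------------------------------

    def lexical_distribution(
        self, q: StoreState
    ) -> list[tuple[LexicalDecision, float]]:
        """Enumerated P(l | q): pairs of (decision, log probability).

        Sums to 1 over the returned support.
        """
        depth = len(q)
        base = conditioning_base(q, self.H)
        key = (depth, base)
        if key in self._lex_cache:
            return self._lex_cache[key]
        n_h = self.inv.n_lex_contexts
        mask = lex_support_mask(depth, n_h)
        lp_mh = log_softmax(
            self.params.lex_logits(depth, base).reshape(-1), mask.reshape(-1)
        ).reshape(2, n_h)
        out: list[tuple[LexicalDecision, float]] = []
        for h_idx in range(n_h):
            if mask[1, h_idx] and lp_mh[1, h_idx] > NEG_INF:
                out.append(
                    (LexicalDecision(1, base.cat, h_idx), float(lp_mh[1, h_idx]))
                )
            if mask[0, h_idx] and lp_mh[0, h_idx] > NEG_INF:
                lp_cat = log_softmax(
                    self.params.lex_cat_logits(depth, base, 0, h_idx)
                )
                for i, lp in enumerate(lp_cat):
                    if lp > NEG_INF:
                        out.append(
                            (
                                LexicalDecision(0, N_RESERVED_CATS + i, h_idx),
                                float(lp_mh[0, h_idx] + lp),
                            )
                        )
        self._lex_cache[key] = out
        return out

    # ------------------------------------------------------------------

    def grammatical_distribution(
        self, q: StoreState, m_l: int, apex: Node
    ) -> list[tuple[GrammaticalDecision, float]]:
        """Enumerated P(g | q, l, w); sums to 1 over the support."""
        depth = len(q)
        j = depth - m_l
        cond = conditioning_base(q, self.H, back=m_l)
        key = (depth, j == 0, cond, apex)
        if key in self._gram_cache:
            return self._gram_cache[key]
        n_ops = len(self.ops)
        mask = gram_support_mask(j, n_ops)
        lp_mo = log_softmax(
            self.params.gram_logits(depth, cond, apex).reshape(-1),
            mask.reshape(-1),
        ).reshape(2, n_ops)
        out: list[tuple[GrammaticalDecision, float]] = []
        for op in range(n_ops):
            # no-match: generate both the parent and the new base category
            if lp_mo[0, op] > NEG_INF:
                lp_cg = log_softmax(
                    self.params.gram_cat_logits(depth, cond, apex, 0, op)
                )
                for i, lp1 in enumerate(lp_cg):
                    if lp1 == NEG_INF:
                        continue
                    c_g = N_RESERVED_CATS + i
                    lp_cb = log_softmax(
                        self.params.gram_base_cat_logits(
                            depth, cond, apex, 0, op, c_g
                        )
                    )
                    for k, lp2 in enumerate(lp_cb):
                        if lp2 > NEG_INF:
                            out.append(
                                (
                                    GrammaticalDecision(
                                        0, op, c_g, N_RESERVED_CATS + k
                                    ),
                                    float(lp_mo[0, op] + lp1 + lp2),
                                )
                            )
            # match: parent category is the satisfied prediction
            if mask[1, op] and lp_mo[1, op] > NEG_INF:
                if j == 0:
                    out.append((TERMINATION, float(lp_mo[1, op])))
                else:
                    c_g = cond.cat
                    lp_cb = log_softmax(
                        self.params.gram_base_cat_logits(
                            depth, cond, apex, 1, op, c_g
                        )
                    )
                    for k, lp2 in enumerate(lp_cb):
                        if lp2 > NEG_INF:
                            out.append(
                                (
                                    GrammaticalDecision(
                                        1, op, c_g, N_RESERVED_CATS + k
                                    ),
                                    float(lp_mo[1, op] + lp2),
                                )
                            )
        self._gram_cache[key] = out
        return out

    # ------------------------------------------------------------------

    def word_logprob(self, word: str, pret_cat: int, h_l: bytes) -> float:
        key = (word, pret_cat, h_l)
        if key not in self._word_cache:
            self._word_cache[key] = word_logprob(
                self.params, word, pret_cat, h_l
            )
        return self._word_cache[key]

    # ------------------------------------------------------------------

    def step_distribution(
        self, q: StoreState, z: ZState, word: str
    ) -> tuple[dict, StepOutcome]:
        """All successors of (q, z) on consuming ``word``.

        Returns ``(successors, completed)`` where ``successors`` maps
        (q', z') to a :class:`StepOutcome` and ``completed`` holds the
        sentence-termination mass.  Summed over all words and successors
        the step mass is 1 minus the depth-bound pruning mass.
        """
        key = (q, z, word)
        if key in self._step_cache:
            return self._step_cache[key]
        succ: dict = {}
        completed = StepOutcome()
        for lex, lp_l in self.lexical_distribution(q):
            h_l = self.inv.lex_contexts[lex.h_index]
            h_vecf = h_vec(h_l)
            p, apex = apply_lexical(q, z, lex.match, lex.cat, h_vecf)
            lp_w = self.word_logprob(word, p.cat, h_l)
            if lp_l + lp_w == NEG_INF:
                continue
            for g, lp_g in self.grammatical_distribution(q, lex.match, apex):
                total = lp_l + lp_w + lp_g
                if total == NEG_INF:
                    continue
                op = self.ops[g.op]
                nodes = apply_grammatical(q, z, lex.match, apex, g, op, self.H)
                if nodes is None:
                    completed.add(total, (lex, g))
                    continue
                new_apex, new_base = nodes
                q2 = update_store(q, lex.match, g.match, new_apex, new_base,
                                  self.D)
                if q2 is PRUNED:
                    continue
                z2 = update_z(z, lex.match, g, op, self.H)
                outcome = succ.get((q2, z2))
                if outcome is None:
                    outcome = succ[(q2, z2)] = StepOutcome()
                outcome.add(total, (lex, g))
        self._step_cache[key] = (succ, completed)
        return succ, completed
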