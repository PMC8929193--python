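"""Model-parameter interface and the tabular implementation.

Two interchangeable parameterizations drive the transition model:

* :class:`TabularParameters` — explicit conditional probability tables over
  the decision supports, keyed by the same conditioning features the neural
  scorers see (store depth, base/apex categories).  The synthetic-grammar
  module uses these as generator ("teacher") parameterizations, which makes
  maximum-likelihood recovery by the neural model well-posed.
* :class:`~lcsurp.neural.NeuralParameters` — the dense-embedding
  feedforward/recurrent scorers.

Both expose the same duck-typed surface:

``lex_logits(depth, base) -> (2, n_lex_contexts)``
    unnormalized scores for the joint (match, context-vector) lexical
    outcome; the transition layer applies the support mask and softmax.
``lex_cat_logits(depth, base, m, h_idx) -> (n_real_cats,)``
``gram_logits(depth, cond, apex) -> (2, n_operators)``
``gram_cat_logits / gram_base_cat_logits -> (n_real_cats,)``
``lemma_logprob(lemma, pret_cat, h_l) -> float`` (normalized)
``rule_logprob(rule_id, lemma, pret_cat, h_l) -> float`` (normalized)
``word_table`` — ``None``, or the relative-frequency table of the -morph
    ablation.
"""

from __future__ import annotations

import json

import numpy as np

from .categories import Inventories
from .errors import ConfigError
from .operators import build_operators
from .state import Node

NEG_INF = -np.inf

FORMAT_VERSION = 1


class BaseParameters:
    """Shared plumbing: inventories, operators, derived sizes."""

    def __init__(self, inv: Inventories):
        self.inv = inv
        self.operators = build_operators(inv.space)
        self.word_table = None  # set by the -morph ablation

    @property
    def n_ops(self) -> int:
        return len(self.operators)

    @property
    def H(self) -> int:
        return self.inv.space.H

    @property
    def D(self) -> int:
        return self.inv.D

    def operator(self, op_id: int):
        if not (0 <= op_id < len(self.operators)):
            raise ConfigError(f"unknown operator id {op_id}")
        return self.operators[op_id]


def _logp(weights: np.ndarray) -> np.ndarray:
    """Normalize non-negative weights to log probabilities (-inf on zeros)."""
    w = np.asarray(weights, dtype=float)
    total = w.sum()
    if total <= 0:
        raise ValueError("weights must have positive mass")
    with np.errstate(divide="ignore"):
        return np.log(w / total)


class TabularParameters(BaseParameters):
    """Explicit conditional tables over decision supports.

    Table keys use the conditioning features of the corresponding neural
    scorer (depth and category ids); missing keys fall back to uniform
    distributions so that the parameterization is total.
    """

    def __init__(self, inv: Inventories):
        super().__init__(inv)
        self.lex_mh: dict = {}  # (depth, base_cat) -> (2, n_h) logp
        self.lex_cat: dict = {}  # (m, h_idx) -> (n_real,) logp
        self.gram: dict = {}  # (depth, cond_cat, apex_cat) -> (2, n_ops) logp
        self.gram_cat: dict = {}  # (cond_cat, apex_cat, op) -> (n_real,) logp
        self.gram_base: dict = {}  # (cond_cat, apex_cat, m, op, c_g) -> (n_real,)
        self.lemma_table: dict = {}  # (pret_cat, h_l bytes) -> {lemma: logp}
        self.rule_table: dict = {}  # (pret_cat, lemma) -> (n_rules,) logp

    # -- transition scorers -------------------------------------------------

    def lex_logits(self, depth: int, base: Node) -> np.ndarray:
        key = (depth, base.cat)
        if key in self.lex_mh:
            return self.lex_mh[key]
        return np.zeros((2, self.inv.n_lex_contexts))

    def lex_cat_logits(self, depth, base, m, h_idx) -> np.ndarray:
        key = (m, h_idx)
        if key in self.lex_cat:
            return self.lex_cat[key]
        return np.zeros(self.inv.n_real_cats)

    def gram_logits(self, depth: int, cond: Node, apex: Node) -> np.ndarray:
        key = (depth, cond.cat, apex.cat)
        if key in self.gram:
            return self.gram[key]
        return np.zeros((2, self.n_ops))

    def gram_cat_logits(self, depth, cond, apex, m, op) -> np.ndarray:
        key = (cond.cat, apex.cat, op)
        if key in self.gram_cat:
            return self.gram_cat[key]
        return np.zeros(self.inv.n_real_cats)

    def gram_base_cat_logits(self, depth, cond, apex, m, op, c_g) -> np.ndarray:
        key = (cond.cat, apex.cat, m, op, c_g)
        if key in self.gram_base:
            return self.gram_base[key]
        return np.zeros(self.inv.n_real_cats)

    # -- word model ----------------------------------------------------------

    def _lemma_dist(self, pret_cat: int, h_l: bytes) -> dict:
        dist = self.lemma_table.get((pret_cat, h_l))
        if dist is None:
            dist = self.lemma_table.get((pret_cat, None))
        if dist is None:
            raise ConfigError(
                f"no lemma table for preterminal category {pret_cat}"
            )
        return dist

    def lemma_logprob(self, lemma: str, pret_cat: int, h_l: bytes) -> float:
        return self._lemma_dist(pret_cat, h_l).get(lemma, NEG_INF)

    def rule_logprob(self, rule_id: int, lemma: str, pret_cat: int,
                     h_l: bytes) -> float:
        row = self.rule_table.get((pret_cat, lemma))
        if row is None:
            row = self.rule_table.get((None, lemma))
        if row is None:
            return NEG_INF
        return row[rule_id]

    def sample_lemma_rule(self, pret_cat: int, h_l: bytes, rng) -> tuple[str, int]:
        dist = self._lemma_dist(pret_cat, h_l)
        lemmas = sorted(dist)
        probs = np.exp([dist[x] for x in lemmas])
        probs = probs / probs.sum()
        lemma = lemmas[rng.choice(len(lemmas), p=probs)]
        row = np.exp(self.rule_table[(pret_cat, lemma)]
                     if (pret_cat, lemma) in self.rule_table
                     else self.rule_table[(None, lemma)])
        row = row / row.sum()
        rule_id = int(rng.choice(len(row), p=row))
        return lemma, rule_id

    # -- serialization ---------------------------------------------------------

    def to_json(self) -> dict:
        return {
            "version": FORMAT_VERSION,
            "kind": "tabular",
            "inventories": self.inv.to_json(),
            "lex_mh": [
                [list(k), np.asarray(v).tolist()] for k, v in self.lex_mh.items()
            ],
            "lex_cat": [
                [list(k), np.asarray(v).tolist()] for k, v in self.lex_cat.items()
            ],
            "gram": [[list(k), np.asarray(v).tolist()] for k, v in self.gram.items()],
            "gram_cat": [
                [list(k), np.asarray(v).tolist()] for k, v in self.gram_cat.items()
            ],
            "gram_base": [
                [list(k), np.asarray(v).tolist()] for k, v in self.gram_base.items()
            ],
            "lemma_table": [
                [[k[0], k[1].hex() if k[1] is not None else None], v]
                for k, v in self.lemma_table.items()
            ],
            "rule_table": [
                [[k[0], k[1]], np.asarray(v).tolist()]
                for k, v in self.rule_table.items()
            ],
        }

    @classmethod
    def from_json(cls, data: dict) -> "TabularParameters":
        if data.get("version") != FORMAT_VERSION:
            raise ConfigError(
                f"model file version {data.get('version')} != {FORMAT_VERSION}"
            )
        inv = Inventories.from_json(data["inventories"])
        tp = cls(inv)
        for name in ("lex_mh", "lex_cat", "gram", "gram_cat", "gram_base"):
            table = getattr(tp, name)
            for k, v in data[name]:
                table[tuple(k)] = np.asarray(v, dtype=float)
        for (cat, hhex), dist in data["lemma_table"]:
            key = (cat, bytes.fromhex(hhex) if hhex is not None else None)
            tp.lemma_table[key] = dict(dist)
        for (cat, lemma), row in data["rule_table"]:
            tp.rule_table[(cat, lemma)] = np.asarray(row, dtype=float)
        return tp

    def save(self, path):
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_json(), fh)

    @classmethod
    def load(cls, path):
        with open(path, encoding="utf-8") as fh:
            return cls.from_json(json.load(fh))
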