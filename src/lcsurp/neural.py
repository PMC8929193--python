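"""Dense-embedding neural parameterization of the transition model.

Scorers (all sharing the layout of :mod:`lcsurp.params`):

* lexical (match, context-vector) scorer: one-hidden-layer tanh feedforward
  network over [one-hot depth, embedded base node];
* lexical category classifier: adds the match bit and the embedded lexical
  context vector;
* grammatical (match, operator) scorer: feedforward over [one-hot depth,
  embedded conditioning base, embedded apex];
* two chained category classifiers for the parent and new-base categories;
* character-level recurrent lemma model and rule classifier, conditioned on
  the preterminal category and lexical context vector.

Embedding matrices have one row per category and one per context-vector
entry, plus character rows for the word model; a node embedding is the sum
of its category row and the rows of its active contexts.  The ``-cat``
ablation zeroes the category contribution in the lexical and grammatical
conditioning features (the word model keeps its category input).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import nn
from .categories import Inventories, N_RESERVED_CATS
from .errors import ConfigError
from .params import BaseParameters, FORMAT_VERSION
from .state import Node

UNK_CHAR_ID = 0
BOS_CHAR_ID = 1
EOS_CHAR_ID = 2


@dataclass(frozen=True)
class NeuralConfig:
    e_lex: int = 16
    e_gram: int = 16
    e_word: int = 16
    mlp_hidden: int = 32
    rnn_hidden: int = 128
    cell: str = "gru"  # or "rnn" (simple recurrent)

    def __post_init__(self):
        if self.cell not in nn.CELLS:
            raise ConfigError(f"unknown recurrent cell {self.cell!r}")


class NeuralParameters(BaseParameters):
    def __init__(
        self,
        inv: Inventories,
        config: NeuralConfig | None = None,
        seed: int = 0,
        ablate_cat: bool = False,
    ):
        super().__init__(inv)
        self.config = config or NeuralConfig()
        self.ablate_cat = ablate_cat
        self.seed = seed
        cfg = self.config
        rng = np.random.default_rng(seed)
        n_cats, H = inv.n_cats, self.H
        n_h, n_real = inv.n_lex_contexts, inv.n_real_cats
        dd = inv.D + 1  # one-hot depth 0..D
        P: dict = {}
        nn.init_embedding(P, rng, "E_L", n_cats + H, cfg.e_lex)
        nn.init_mlp(P, rng, "ffL", dd + cfg.e_lex, cfg.mlp_hidden, 2 * n_h)
        nn.init_mlp(
            P, rng, "lexcat", dd + 2 * cfg.e_lex + 1, cfg.mlp_hidden, n_real
        )
        nn.init_embedding(P, rng, "E_G", n_cats + H, cfg.e_gram)
        nn.init_mlp(P, rng, "ffG", dd + 2 * cfg.e_gram, cfg.mlp_hidden,
                    2 * self.n_ops)
        base_in = dd + 2 * cfg.e_gram + 1 + self.n_ops
        nn.init_mlp(P, rng, "gramcat", base_in, cfg.mlp_hidden, n_real)
        nn.init_mlp(P, rng, "grambase", base_in + cfg.e_gram, cfg.mlp_hidden,
                    n_real)
        n_chars = inv.n_chars
        nn.init_embedding(P, rng, "E_X", n_cats + H + n_chars, cfg.e_word)
        nn.init_embedding(P, rng, "E_R", n_cats + H + n_chars, cfg.e_word)
        init_cell, self._cell_step, self._cell_back = nn.CELLS[cfg.cell]
        init_cell(P, rng, "rnnX", cfg.e_word, cfg.rnn_hidden)
        init_cell(P, rng, "rnnR", cfg.e_word, cfg.rnn_hidden)
        P["WX"] = np.zeros((cfg.rnn_hidden, n_chars))
        P["bX"] = np.zeros(n_chars)
        P["WR"] = np.zeros((cfg.rnn_hidden, len(inv.rules)))
        P["bR"] = np.zeros(len(inv.rules))
        self.P = P
        # characters the lemma model may emit: everything except <s>
        self._char_mask = np.ones(n_chars, dtype=bool)
        self._char_mask[BOS_CHAR_ID] = False
        self._caches: dict = {}

    # ------------------------------------------------------------------
    # feature construction

    def _h_float(self, h: bytes) -> np.ndarray:
        return np.frombuffer(h, dtype=np.uint8).astype(float)

    def _depth_onehot(self, depth: int) -> np.ndarray:
        v = np.zeros(self.inv.D + 1)
        v[min(depth, self.inv.D)] = 1.0
        return v

    def _node_emb(self, table: str, cat: int, h: bytes,
                  ablatable: bool) -> np.ndarray:
        E = self.P[table]
        hv = self._h_float(h)
        emb = hv @ E[self.inv.n_cats:]
        if not (ablatable and self.ablate_cat):
            emb = emb + E[cat]
        return emb

    def _node_emb_backward(self, G: dict, table: str, cat: int, h: bytes,
                           demb: np.ndarray, ablatable: bool) -> None:
        hv = self._h_float(h)
        G[table][self.inv.n_cats:] += np.outer(hv, demb)
        if not (ablatable and self.ablate_cat):
            G[table][cat] += demb

    def _lex_features(self, depth: int, base: Node) -> np.ndarray:
        return np.concatenate(
            [self._depth_onehot(depth),
             self._node_emb("E_L", base.cat, base.h, ablatable=True)]
        )

    def _gram_features(self, depth: int, cond: Node, apex: Node) -> np.ndarray:
        return np.concatenate(
            [
                self._depth_onehot(depth),
                self._node_emb("E_G", cond.cat, cond.h, ablatable=True),
                self._node_emb("E_G", apex.cat, apex.h, ablatable=True),
            ]
        )

    # ------------------------------------------------------------------
    # transition scorers (forward only)

    def lex_logits(self, depth: int, base: Node) -> np.ndarray:
        out, _ = nn.mlp_forward(self.P, "ffL", self._lex_features(depth, base))
        return out.reshape(2, self.inv.n_lex_contexts)

    def _lexcat_features(self, depth, base, m, h_idx):
        h_l = self.inv.lex_contexts[h_idx]
        hv = self._h_float(h_l)
        emb_h = hv @ self.P["E_L"][self.inv.n_cats:]
        return np.concatenate(
            [self._lex_features(depth, base), [float(m)], emb_h]
        )

    def lex_cat_logits(self, depth, base, m, h_idx) -> np.ndarray:
        out, _ = nn.mlp_forward(
            self.P, "lexcat", self._lexcat_features(depth, base, m, h_idx)
        )
        return out

    def gram_logits(self, depth: int, cond: Node, apex: Node) -> np.ndarray:
        out, _ = nn.mlp_forward(
            self.P, "ffG", self._gram_features(depth, cond, apex)
        )
        return out.reshape(2, self.n_ops)

    def _gramcat_features(self, depth, cond, apex, m, op):
        onehot_op = np.zeros(self.n_ops)
        onehot_op[op] = 1.0
        return np.concatenate(
            [self._gram_features(depth, cond, apex), [float(m)], onehot_op]
        )

    def gram_cat_logits(self, depth, cond, apex, m, op) -> np.ndarray:
        out, _ = nn.mlp_forward(
            self.P, "gramcat", self._gramcat_features(depth, cond, apex, m, op)
        )
        return out

    def gram_base_cat_logits(self, depth, cond, apex, m, op, c_g) -> np.ndarray:
        E = self.P["E_G"]
        emb_cg = np.zeros(self.config.e_gram) if self.ablate_cat else E[c_g]
        x = np.concatenate(
            [self._gramcat_features(depth, cond, apex, m, op), emb_cg]
        )
        out, _ = nn.mlp_forward(self.P, "grambase", x)
        return out

    # ------------------------------------------------------------------
    # word model

    def _word_cond(self, table: str, pret_cat: int, h_l: bytes) -> np.ndarray:
        E = self.P[table]
        hv = self._h_float(h_l)
        return E[pret_cat] + hv @ E[self.inv.n_cats: self.inv.n_cats + self.H]

    def _char_emb(self, table: str, char_id: int) -> np.ndarray:
        return self.P[table][self.inv.n_cats + self.H + char_id]

    def _lemma_pass(self, lemma_ids, pret_cat, h_l, collect=False):
        """Forward pass of the lemma LM; returns (logp, caches)."""
        cond = self._word_cond("E_X", pret_cat, h_l)
        seq = [BOS_CHAR_ID] + list(lemma_ids)
        targets = list(lemma_ids) + [EOS_CHAR_ID]
        h = np.zeros(self.config.rnn_hidden)
        logp = 0.0
        caches = [] if collect else None
        for cid, tgt in zip(seq, targets):
            x = cond + self._char_emb("E_X", cid)
            h, cache = self._cell_step(self.P, "rnnX", x, h)
            logits = h @ self.P["WX"] + self.P["bX"]
            lp = nn.log_softmax(logits, self._char_mask)
            logp += lp[tgt]
            if collect:
                caches.append((cid, tgt, cache, h.copy(), logits))
        return logp, caches

    def _rule_pass(self, lemma_ids, pret_cat, h_l, collect=False):
        """Final hidden state of the rule RNN (no framing symbols)."""
        cond = self._word_cond("E_R", pret_cat, h_l)
        h = np.zeros(self.config.rnn_hidden)
        caches = [] if collect else None
        for cid in lemma_ids:
            x = cond + self._char_emb("E_R", cid)
            h, cache = self._cell_step(self.P, "rnnR", x, h)
            if collect:
                caches.append((cid, cache))
        return h, caches

    def lemma_logprob(self, lemma: str, pret_cat: int, h_l: bytes) -> float:
        key = ("x", lemma, pret_cat, h_l)
        if key not in self._caches:
            ids = self.inv.encode_lemma(lemma)
            self._caches[key], _ = self._lemma_pass(ids, pret_cat, h_l)
        return self._caches[key]

    def rule_logprob(self, rule_id: int, lemma: str, pret_cat: int,
                     h_l: bytes) -> float:
        key = ("r", lemma, pret_cat, h_l)
        if key not in self._caches:
            ids = self.inv.encode_lemma(lemma)
            h, _ = self._rule_pass(ids, pret_cat, h_l)
            logits = h @ self.P["WR"] + self.P["bR"]
            self._caches[key] = nn.log_softmax(logits)
        return float(self._caches[key][rule_id])

    def sample_lemma_rule(self, pret_cat: int, h_l: bytes, rng,
                          max_len: int = 24) -> tuple[str, int]:
        cond = self._word_cond("E_X", pret_cat, h_l)
        h = np.zeros(self.config.rnn_hidden)
        cid = BOS_CHAR_ID
        chars: list[str] = []
        alphabet = {i + 3: ch for i, ch in enumerate(self.inv.charset)}
        for _ in range(max_len):
            x = cond + self._char_emb("E_X", cid)
            h, _ = self._cell_step(self.P, "rnnX", x, h)
            p = np.exp(nn.log_softmax(h @ self.P["WX"] + self.P["bX"],
                                      self._char_mask))
            cid = int(rng.choice(len(p), p=p / p.sum()))
            if cid == EOS_CHAR_ID:
                break
            chars.append(alphabet.get(cid, "?"))
        lemma = "".join(chars) or "?"
        ids = self.inv.encode_lemma(lemma)
        hr, _ = self._rule_pass(ids, pret_cat, h_l)
        pr = np.exp(nn.log_softmax(hr @ self.P["WR"] + self.P["bR"]))
        rule_id = int(rng.choice(len(pr), p=pr / pr.sum()))
        return lemma, rule_id

    def clear_caches(self):
        self._caches.clear()

    # ------------------------------------------------------------------
    # training losses (accumulate gradients into G)

    def lex_loss(self, G, depth, base, m, h_idx, mask2) -> float:
        x = self._lex_features(depth, base)
        out, cache = nn.mlp_forward(self.P, "ffL", x)
        n_h = self.inv.n_lex_contexts
        loss, dlogits = nn.softmax_xent_grad(
            out, m * n_h + h_idx, mask2.reshape(-1)
        )
        dx = nn.mlp_backward(self.P, G, "ffL", dlogits, cache)
        demb = dx[self.inv.D + 1:]
        self._node_emb_backward(G, "E_L", base.cat, base.h, demb, True)
        return loss

    def lexcat_loss(self, G, depth, base, m, h_idx, c_l) -> float:
        x = self._lexcat_features(depth, base, m, h_idx)
        out, cache = nn.mlp_forward(self.P, "lexcat", x)
        loss, dlogits = nn.softmax_xent_grad(out, c_l - N_RESERVED_CATS)
        dx = nn.mlp_backward(self.P, G, "lexcat", dlogits, cache)
        dd = self.inv.D + 1
        e = self.config.e_lex
        self._node_emb_backward(G, "E_L", base.cat, base.h, dx[dd:dd + e], True)
        h_l = self.inv.lex_contexts[h_idx]
        hv = self._h_float(h_l)
        G["E_L"][self.inv.n_cats:] += np.outer(hv, dx[dd + e + 1:])
        return loss

    def gram_loss(self, G, depth, cond, apex, m, op, mask2) -> float:
        x = self._gram_features(depth, cond, apex)
        out, cache = nn.mlp_forward(self.P, "ffG", x)
        loss, dlogits = nn.softmax_xent_grad(
            out, m * self.n_ops + op, mask2.reshape(-1)
        )
        dx = nn.mlp_backward(self.P, G, "ffG", dlogits, cache)
        self._gram_features_backward(G, cond, apex, dx)
        return loss

    def _gram_features_backward(self, G, cond, apex, dx):
        dd = self.inv.D + 1
        e = self.config.e_gram
        self._node_emb_backward(G, "E_G", cond.cat, cond.h, dx[dd:dd + e], True)
        self._node_emb_backward(
            G, "E_G", apex.cat, apex.h, dx[dd + e:dd + 2 * e], True
        )

    def gramcat_loss(self, G, depth, cond, apex, m, op, c_g) -> float:
        x = self._gramcat_features(depth, cond, apex, m, op)
        out, cache = nn.mlp_forward(self.P, "gramcat", x)
        loss, dlogits = nn.softmax_xent_grad(out, c_g - N_RESERVED_CATS)
        dx = nn.mlp_backward(self.P, G, "gramcat", dlogits, cache)
        self._gram_features_backward(G, cond, apex, dx)
        return loss

    def grambase_loss(self, G, depth, cond, apex, m, op, c_g, c_gp) -> float:
        base_x = self._gramcat_features(depth, cond, apex, m, op)
        emb_cg = (np.zeros(self.config.e_gram) if self.ablate_cat
                  else self.P["E_G"][c_g])
        x = np.concatenate([base_x, emb_cg])
        out, cache = nn.mlp_forward(self.P, "grambase", x)
        loss, dlogits = nn.softmax_xent_grad(out, c_gp - N_RESERVED_CATS)
        dx = nn.mlp_backward(self.P, G, "grambase", dlogits, cache)
        self._gram_features_backward(G, cond, apex, dx)
        if not self.ablate_cat:
            G["E_G"][c_g] += dx[len(base_x):]
        return loss

    def word_loss(self, G, lemma: str, rule_id: int, pret_cat: int,
                  h_l: bytes) -> float:
        """Joint -log P(lemma chars) - log P(rule) with full backprop."""
        ids = self.inv.encode_lemma(lemma)
        n_cats, H = self.inv.n_cats, self.H
        # lemma LM
        logp, caches = self._lemma_pass(ids, pret_cat, h_l, collect=True)
        loss = -logp
        dh_next = np.zeros(self.config.rnn_hidden)
        dcond = np.zeros(self.config.e_word)
        for cid, tgt, cache, h, logits in reversed(caches):
            _, dlogits = nn.softmax_xent_grad(logits, tgt, self._char_mask)
            G["WX"] += np.outer(h, dlogits)
            G["bX"] += dlogits
            dh = self.P["WX"] @ dlogits + dh_next
            dx, dh_next = self._cell_back(self.P, G, "rnnX", dh, cache)
            G["E_X"][n_cats + H + cid] += dx
            dcond += dx
        hv = self._h_float(h_l)
        G["E_X"][pret_cat] += dcond
        G["E_X"][n_cats:n_cats + H] += np.outer(hv, dcond)
        # rule classifier
        hr, rcaches = self._rule_pass(ids, pret_cat, h_l, collect=True)
        logits = hr @ self.P["WR"] + self.P["bR"]
        rloss, dlogits = nn.softmax_xent_grad(logits, rule_id)
        loss += rloss
        G["WR"] += np.outer(hr, dlogits)
        G["bR"] += dlogits
        dh_next = self.P["WR"] @ dlogits
        dcond = np.zeros(self.config.e_word)
        for cid, cache in reversed(rcaches):
            dx, dh_next = self._cell_back(self.P, G, "rnnR", dh_next, cache)
            G["E_R"][n_cats + H + cid] += dx
            dcond += dx
        G["E_R"][pret_cat] += dcond
        G["E_R"][n_cats:n_cats + H] += np.outer(hv, dcond)
        return loss

    # ------------------------------------------------------------------
    # serialization

    def save(self, path) -> None:
        header = {
            "version": FORMAT_VERSION,
            "kind": "neural",
            "inventories": self.inv.to_json(),
            "config": asdict(self.config),
            "ablate_cat": self.ablate_cat,
            "seed": self.seed,
            "word_table": self.word_table,
        }
        buf = {k: v for k, v in self.P.items()}
        with open(path, "wb") as fh:
            np.savez(fh, __header__=np.frombuffer(
                json.dumps(header).encode(), dtype=np.uint8), **buf)

    @classmethod
    def load(cls, path) -> "NeuralParameters":
        with np.load(path) as data:
            header = json.loads(bytes(data["__header__"]).decode())
            if header.get("version") != FORMAT_VERSION:
                raise ConfigError(
                    f"model file version {header.get('version')} != "
                    f"{FORMAT_VERSION}"
                )
            inv = Inventories.from_json(header["inventories"])
            obj = cls(
                inv,
                NeuralConfig(**header["config"]),
                seed=header.get("seed", 0),
                ablate_cat=header["ablate_cat"],
            )
            for k in obj.P:
                obj.P[k] = data[k]
            wt = header.get("word_table")
            if wt is not None:
                obj.word_table = {int(k): v for k, v in wt.items()}
        return obj
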