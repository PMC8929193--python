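"""Seeded toy grammars and synthetic treebanks.

A :class:`ToyGrammar` bundles a small category inventory, binary rewrite
rules with weights and composition-operator assignments, a lexicon of
(lemma, category, predicate) entries with emission weights, and a
morphological rule set with application weights.  Its sampling semantics
are defined *through the left-corner transition model*: the grammar is
compiled into :class:`~lcsurp.params.TabularParameters` (conditional
decision tables keyed by the conditioning features the neural scorers see)
and sentences are drawn by ancestral sampling of decisions.  This makes
the generator a bona-fide parameterization of the processing model, so

* the forward algorithm under the generator's own parameterization assigns
  each sampled sentence at least (and, for unambiguous grammars, exactly)
  the summed log probability of its sampled decisions, and
* maximum-likelihood recovery of the generator by the neural model is
  well-posed: the generator's conditionals are measurable functions of the
  features the neural scorers condition on.

Rewrite-rule weights enter as the relative weights of grammatical
decisions compatible with a conditioning state, so empirical production
frequencies match the *renormalized* rule weights per conditioning state.
Generated trees have left-corner depth <= the grammar's depth bound by
construction (deeper samples are rejected and logged).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import NamedTuple

import numpy as np

from .categories import Category, Inventories, START_CAT, N_RESERVED_CATS, \
    make_inventories
from .contexts import to_bytes
from .errors import ConfigError, GenerationError
from .morph import MorphRule, RuleInventory
from .params import TabularParameters
from .state import EMPTY_STORE, EMPTY_Z, PRUNED, apply_grammatical, \
    apply_lexical, h_vec, update_store, update_z
from .training import DecisionStep, decisions_to_tree, unresolve_tree
from .transition import TransitionModel
from .treebank import TreebankHeader
from .wordmodel import sample_word


class RewriteRule(NamedTuple):
    parent: str
    left: str
    right: str
    op: int  # composition operator id
    weight: float


class LexEntry(NamedTuple):
    lemma: str
    cat: str
    predicate: str
    weight: float


@dataclass
class ToyGrammar:
    categories: list[Category]
    predicates: list[str]
    V: int
    E: int
    D: int
    rewrite_rules: list[RewriteRule]
    lexicon: list[LexEntry]
    morph_rules: list[MorphRule]
    morph_weights: list[float]  # one application weight per rule id
    lex_match_bias: float = 1.0
    gram_match_bias: float = 1.0
    term_bias: float = 2.0
    zero_ctx_weight: float = 0.1

    def validate(self) -> None:
        labels = {c.label for c in self.categories}
        with_lexicon = {e.cat for e in self.lexicon}
        if not labels:
            raise GenerationError("empty category inventory")
        missing = labels - with_lexicon
        if missing:
            raise GenerationError(
                f"categories without lexicon entries: {sorted(missing)}"
            )
        for r in self.rewrite_rules:
            for lab in (r.parent, r.left, r.right):
                if lab not in labels:
                    raise GenerationError(f"rewrite rule uses unknown {lab!r}")
            if r.weight <= 0:
                raise GenerationError("rewrite weights must be positive")
        if len(self.morph_weights) != len(self.morph_rules) + 2:
            raise GenerationError("need one morph weight per rule id")

    def to_json(self) -> dict:
        d = asdict(self)
        d["rewrite_rules"] = [list(r) for r in self.rewrite_rules]
        d["lexicon"] = [list(e) for e in self.lexicon]
        d["categories"] = [[c.label, c.valence, c.nonlocal_arity]
                           for c in self.categories]
        d["morph_rules"] = [[r.lhs, r.rhs, r.kind] for r in self.morph_rules]
        return d


def generate_grammar(
    seed: int,
    n_categories: int = 2,
    n_predicates: int = 2,
    n_rules: int = 3,
    max_valence: int = 1,
    n_morph_rules: int = 1,
    alphabet: str = "abt",
    lemmas_per_category: int = 2,
    D: int = 2,
    E: int = 0,
    branch_mass: float = 1.0,
) -> ToyGrammar:
    """Deterministic random toy grammar.

    Raises :class:`GenerationError` on infeasible sizes (all sizes must be
    at least 1; see :meth:`ToyGrammar.validate` for structural constraints).
    """
    if min(n_categories, n_predicates, n_rules, lemmas_per_category) < 1:
        raise GenerationError("all grammar sizes must be >= 1")
    rng = np.random.default_rng(seed)
    V = max(max_valence, 0)
    cats = [
        Category(f"C{i}", int(rng.integers(0, V + 1)), 0)
        for i in range(n_categories)
    ]
    labels = [c.label for c in cats]
    preds = [f"P{i}" for i in range(n_predicates)]
    # lexicon: every category gets entries; lemmas are short random strings
    lexicon: list[LexEntry] = []
    for lab in labels:
        w = rng.dirichlet(np.ones(lemmas_per_category))
        for k in range(lemmas_per_category):
            length = int(rng.integers(1, 4))
            lemma = "".join(rng.choice(list(alphabet), size=length))
            lexicon.append(
                LexEntry(lemma, lab, preds[int(rng.integers(len(preds)))],
                         float(w[k]))
            )
    # operators available for a (V, E) context space, in canonical order:
    # identity_carry, conjunction_carry, arg_1..arg_V, mod, gaps
    usable_ops = [0] + ([2] if V >= 1 else [1])
    rules = []
    w = rng.dirichlet(np.ones(n_rules))
    for i in range(n_rules):
        rules.append(
            RewriteRule(
                labels[int(rng.integers(len(labels)))],
                labels[int(rng.integers(len(labels)))],
                labels[int(rng.integers(len(labels)))],
                usable_ops[int(rng.integers(len(usable_ops)))],
                branch_mass * float(w[i]) + 1e-3,
            )
        )
    # productivity: every category must occur as a left corner, otherwise a
    # fragment headed by it can never combine and the derivation dead-ends
    lefts = {r.left for r in rules}
    for lab in labels:
        if lab not in lefts:
            rules.append(
                RewriteRule(
                    labels[int(rng.integers(len(labels)))],
                    lab,
                    labels[int(rng.integers(len(labels)))],
                    usable_ops[int(rng.integers(len(usable_ops)))],
                    branch_mass * 0.5 / n_rules + 1e-3,
                )
            )
    morph: list[MorphRule] = []
    if n_morph_rules >= 1 and len(alphabet) >= 2:
        # one vowel-ish substitution per pair of alphabet letters
        for i in range(n_morph_rules):
            src, dst = (
                alphabet[i % len(alphabet)],
                alphabet[(i + 1) % len(alphabet)],
            )
            morph.append(MorphRule(f"%{src}", f"%{dst}{src}"))
    morph_weights = [1.0, 0.2] + [0.5] * len(morph)
    g = ToyGrammar(
        categories=cats,
        predicates=preds,
        V=V,
        E=E,
        D=D,
        rewrite_rules=rules,
        lexicon=lexicon,
        morph_rules=morph,
        morph_weights=morph_weights,
        lex_match_bias=float(rng.uniform(0.6, 1.4)),
        gram_match_bias=float(rng.uniform(0.8, 1.6)),
        term_bias=float(rng.uniform(0.25, 0.6)),
    )
    g.validate()
    return g


def grammar_inventories(grammar: ToyGrammar) -> Inventories:
    rules = RuleInventory(grammar.morph_rules)
    chars = set()
    for e in grammar.lexicon:
        chars.update(e.lemma)
    for r in rules:
        chars.update(r.lhs_suffix)
        chars.update(r.rhs_suffix)
    inv = make_inventories(
        categories=grammar.categories,
        predicates=grammar.predicates,
        V=grammar.V,
        E=grammar.E,
        rules=rules,
        charset="".join(sorted(chars)),
        D=grammar.D,
    )
    for p in grammar.predicates:
        inv.add_lex_context(to_bytes(inv.space.own_onehot(p)))
    return inv


def to_parameters(grammar: ToyGrammar) -> TabularParameters:
    """Compile the grammar into tabular transition-model parameters."""
    grammar.validate()
    inv = grammar_inventories(grammar)
    tp = TabularParameters(inv)
    space = inv.space
    n_h = inv.n_lex_contexts
    n_real = inv.n_real_cats
    n_ops = tp.n_ops
    cat_id = {c.label: inv.cat_id(c.label) for c in grammar.categories}
    h_of_pred = {
        p: to_bytes(space.own_onehot(p)) for p in grammar.predicates
    }
    h_idx = {h: inv.lex_context_id(h) for h in inv.lex_contexts}

    # lexical (m, h) weights: emission mass per context vector
    h_weight = np.zeros(n_h)
    h_weight[0] = grammar.zero_ctx_weight
    cat_h_weight: dict[tuple[int, int], float] = {}
    for e in grammar.lexicon:
        i = h_idx[h_of_pred[e.predicate]]
        h_weight[i] += e.weight
        key = (cat_id[e.cat], i)
        cat_h_weight[key] = cat_h_weight.get(key, 0.0) + e.weight
    all_cats = [START_CAT] + list(cat_id.values())
    for depth in range(grammar.D + 1):
        for c in all_cats:
            w = np.zeros((2, n_h))
            w[0] = h_weight
            if depth >= 1:
                w[1] = grammar.lex_match_bias * h_weight / h_weight.sum()
            with np.errstate(divide="ignore"):
                tp.lex_mh[(depth, c)] = np.log(w / w.sum())
    # lexical category given (m=0, h)
    for i in range(n_h):
        w = np.zeros(n_real)
        for (c, hi), wt in cat_h_weight.items():
            if hi == i:
                w[c - N_RESERVED_CATS] += wt
        if w.sum() == 0:  # zero vector or unused context: category marginal
            for (c, _), wt in cat_h_weight.items():
                w[c - N_RESERVED_CATS] += wt
        with np.errstate(divide="ignore"):
            tp.lex_cat[(0, i)] = np.log(w / w.sum())

    # grammatical decisions
    by_left: dict[str, list[RewriteRule]] = {}
    for r in grammar.rewrite_rules:
        by_left.setdefault(r.left, []).append(r)
    label_of = {v: k for k, v in cat_id.items()}
    for depth in range(grammar.D + 1):
        for cond_c in all_cats:
            for apex_c in cat_id.values():
                rules_l = by_left.get(label_of[apex_c], [])
                w = np.zeros((2, n_ops))
                for r in rules_l:
                    w[0, r.op] += r.weight
                if cond_c == START_CAT:
                    w[1, 0] = grammar.term_bias
                else:
                    for r in rules_l:
                        if r.parent == label_of[cond_c]:
                            w[1, r.op] += grammar.gram_match_bias * r.weight
                if w.sum() == 0:
                    w[0, 0] = 1.0  # dead-end fallback: identity push
                with np.errstate(divide="ignore"):
                    tp.gram[(depth, cond_c, apex_c)] = np.log(w / w.sum())
                for op in range(n_ops):
                    wc = np.zeros(n_real)
                    for r in rules_l:
                        if r.op == op:
                            wc[cat_id[r.parent] - N_RESERVED_CATS] += r.weight
                    if wc.sum() > 0:
                        with np.errstate(divide="ignore"):
                            tp.gram_cat[(cond_c, apex_c, op)] = np.log(
                                wc / wc.sum()
                            )
                    for m in (0, 1):
                        for cg_label, cg in cat_id.items():
                            wb = np.zeros(n_real)
                            for r in rules_l:
                                if r.op == op and r.parent == cg_label:
                                    wb[cat_id[r.right] - N_RESERVED_CATS] += \
                                        r.weight
                            if wb.sum() > 0:
                                with np.errstate(divide="ignore"):
                                    tp.gram_base[
                                        (cond_c, apex_c, m, op, cg)
                                    ] = np.log(wb / wb.sum())

    # word model tables
    by_cat: dict[int, dict[str, float]] = {}
    by_cat_h: dict[tuple[int, bytes], dict[str, float]] = {}
    for e in grammar.lexicon:
        c = cat_id[e.cat]
        by_cat.setdefault(c, {})
        by_cat[c][e.lemma] = by_cat[c].get(e.lemma, 0.0) + e.weight
        key = (c, h_of_pred[e.predicate])
        by_cat_h.setdefault(key, {})
        by_cat_h[key][e.lemma] = by_cat_h[key].get(e.lemma, 0.0) + e.weight
    for c, dist in by_cat.items():
        total = sum(dist.values())
        tp.lemma_table[(c, None)] = {
            x: float(np.log(v / total)) for x, v in dist.items()
        }
    for key, dist in by_cat_h.items():
        total = sum(dist.values())
        tp.lemma_table[key] = {
            x: float(np.log(v / total)) for x, v in dist.items()
        }
    all_lemmas = sorted({e.lemma for e in grammar.lexicon})
    mw = np.asarray(grammar.morph_weights, dtype=float)
    for lemma in all_lemmas:
        w = np.array(
            [mw[rid] if inv.rules[rid].apply(lemma) is not None else 0.0
             for rid in range(len(inv.rules))]
        )
        with np.errstate(divide="ignore"):
            tp.rule_table[(None, lemma)] = np.log(w / w.sum())
    return tp


def word_support(params: TabularParameters) -> list[str]:
    """All word forms the tabular word model can emit."""
    words = set()
    lemmas = {x for dist in params.lemma_table.values() for x in dist}
    for lemma in lemmas:
        row = params.rule_table.get((None, lemma))
        if row is None:
            continue
        for rid, lp in enumerate(row):
            if lp > -np.inf:
                w = params.inv.rules[rid].apply(lemma)
                if w is not None:
                    words.add(w)
    return sorted(words)


def sample_decisions(
    params: TabularParameters,
    rng: np.random.Generator,
    max_len: int = 10,
    max_tries: int = 200,
):
    """Ancestral sample of one sentence's decision sequence.

    Returns (steps, total_logp, n_rejected).  Rejected draws (depth-bound
    prunes or overlong sentences) are resampled.
    """
    model = TransitionModel(params)
    inv = params.inv
    H, D = params.H, params.D
    rejected = 0
    for _ in range(max_tries):
        q, z = EMPTY_STORE, EMPTY_Z
        steps: list[DecisionStep] = []
        logp = 0.0
        ok = True
        while True:
            if len(steps) >= max_len:
                ok = False
                break
            lex_dist = model.lexical_distribution(q)
            probs = np.exp([lp for _, lp in lex_dist])
            lex, lp_l = lex_dist[int(rng.choice(len(probs),
                                                p=probs / probs.sum()))]
            h_l = inv.lex_contexts[lex.h_index]
            p, apex = apply_lexical(q, z, lex.match, lex.cat, h_vec(h_l))
            word, lemma, rule_id = sample_word(params, p.cat, h_l, rng)
            lp_w = (params.lemma_logprob(lemma, p.cat, h_l)
                    + params.rule_logprob(rule_id, lemma, p.cat, h_l))
            gram_dist = model.grammatical_distribution(q, lex.match, apex)
            gprobs = np.exp([lp for _, lp in gram_dist])
            g, lp_g = gram_dist[int(rng.choice(len(gprobs),
                                               p=gprobs / gprobs.sum()))]
            logp += lp_l + lp_w + lp_g
            steps.append(
                DecisionStep(lex.match, p.cat, h_l, word, lemma, rule_id,
                             g.match, g.op, g.parent_cat, g.base_cat,
                             g.is_termination)
            )
            nodes = apply_grammatical(q, z, lex.match, apex, g,
                                      params.operators[g.op], H)
            if nodes is None:
                break  # terminated
            q2 = update_store(q, lex.match, g.match, *nodes, D)
            if q2 is PRUNED:
                ok = False
                break
            z = update_z(z, lex.match, g, params.operators[g.op], H)
            q = q2
        if ok:
            return steps, logp, rejected
        rejected += 1
    raise ConfigError(
        f"rejection rate too high: {max_tries} consecutive rejected samples"
    )


def sample_treebank(
    grammar: ToyGrammar,
    n_sentences: int,
    seed: int,
    max_len: int = 10,
):
    """Sample an annotated treebank from a toy grammar.

    Returns ``(trees, sentences, info)`` where trees are string-level
    :class:`~lcsurp.treebank.TreeNode` objects, sentences are token lists,
    and ``info`` carries the teacher parameters, decision sequences,
    sampled log probabilities, rejection count, and the treebank header.
    """
    params = to_parameters(grammar)
    rng = np.random.default_rng(seed)
    trees = []
    sentences = []
    sequences = []
    logps = []
    n_rejected = 0
    for _ in range(n_sentences):
        steps, logp, rej = sample_decisions(params, rng, max_len=max_len)
        n_rejected += rej
        if n_rejected > 99 * max(1, n_sentences):
            raise ConfigError("rejection rate exceeds 99%")
        root = decisions_to_tree(steps, params)
        trees.append(unresolve_tree(root, params.inv))
        sentences.append([s.word for s in steps])
        sequences.append(steps)
        logps.append(logp)
    header = TreebankHeader(
        categories=list(grammar.categories),
        predicates=list(grammar.predicates),
        V=grammar.V,
        E=grammar.E,
        D=grammar.D,
    )
    info = {
        "params": params,
        "sequences": sequences,
        "logps": logps,
        "n_rejected": n_rejected,
        "header": header,
    }
    return trees, sentences, info
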