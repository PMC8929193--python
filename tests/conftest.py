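import numpy as np
import pytest

from lcsurp import generate_grammar, sample_treebank, to_parameters
from lcsurp.categories import make_inventories
from lcsurp.morph import MorphRule, RuleInventory


@pytest.fixture(scope="session")
def toy_grammar():
    return generate_grammar(42, D=2, branch_mass=1.5)


@pytest.fixture(scope="session")
def toy_teacher(toy_grammar):
    return to_parameters(toy_grammar)


@pytest.fixture(scope="session")
def toy_sample(toy_grammar):
    """A small sampled treebank shared across tests (trees, sentences, info)."""
    return sample_treebank(toy_grammar, 100, seed=11, max_len=10)


@pytest.fixture(scope="session")
def tiny_inventories():
    """Hand-built inventories: 2 categories, 2 predicates, V=1, E=0."""
    rules = RuleInventory([MorphRule("%a", "%ba")])
    return make_inventories(
        categories=[("N", 0, 0), ("V", 1, 0)],
        predicates=["P0", "P1"],
        V=1,
        E=0,
        rules=rules,
        charset="ab",
        D=3,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def unambiguous_teacher():
    """A right-branching toy model where every sentence has exactly one
    derivation: single predicate, one rewrite rule, distinct lemmas per
    category, identity morphology, no zero-context lexical outcome."""
    from lcsurp.synth import LexEntry, RewriteRule

    g = generate_grammar(
        21, n_categories=2, n_predicates=1, n_rules=1, lemmas_per_category=1,
        n_morph_rules=0, alphabet="ab", branch_mass=1.0,
    )
    c0, c1 = g.categories[0].label, g.categories[1].label
    g.rewrite_rules = [RewriteRule(c0, c1, c0, 2, 1.0)]
    g.lexicon = [
        LexEntry("aa", c1, g.predicates[0], 1.0),
        LexEntry("bb", c0, g.predicates[0], 1.0),
    ]
    g.zero_ctx_weight = 0.0
    g.morph_weights = [1.0, 0.0]
    g.term_bias = 8.0  # thin length tail: the language is effectively finite
    return to_parameters(g)
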