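"""Syntactic categories and frozen model inventories."""

from __future__ import annotations

from dataclasses import dataclass, field

from .contexts import ContextSpace
from .morph import RuleInventory

START_LABEL = "-START-"
UNK_LABEL = "-UNK-"

# conditioning-only category ids (never generated by the classifiers)
START_CAT = 0
UNK_CAT = 1
N_RESERVED_CATS = 2

UNK_CHAR = "\x00"
BOS_CHAR = "\x02"
EOS_CHAR = "\x03"


@dataclass(frozen=True)
class Category:
    label: str
    valence: int = 0
    nonlocal_arity: int = 0

    def __post_init__(self):
        if self.valence < 0 or self.nonlocal_arity < 0:
            raise ValueError("valence and nonlocal_arity must be non-negative")


@dataclass
class Inventories:
    """Finite inventories frozen into a model at training time.

    ``categories`` includes the reserved START (sentence-initial axiom) and
    UNK (decode-time fallback) categories at ids 0 and 1; only ids >= 2 are
    generable outcomes of the category classifiers.
    """

    categories: list[Category]
    space: ContextSpace
    rules: RuleInventory
    charset: str  # generable characters, excluding the reserved symbols
    lex_contexts: list[bytes] = field(default_factory=list)  # h_l support
    D: int = 4

    def __post_init__(self):
        if (
            len(self.categories) < N_RESERVED_CATS
            or self.categories[START_CAT].label != START_LABEL
            or self.categories[UNK_CAT].label != UNK_LABEL
        ):
            raise ValueError("categories must start with the reserved START/UNK")
        for c in self.categories:
            if c.valence > self.space.V or c.nonlocal_arity > self.space.E:
                raise ValueError(f"category {c.label} exceeds V/E bounds")
        self._cat_index = {c.label: i for i, c in enumerate(self.categories)}
        zero = self.space.zero_bytes()
        if zero not in self.lex_contexts:
            self.lex_contexts.insert(0, zero)
        self._lex_index = {h: i for i, h in enumerate(self.lex_contexts)}
        # char ids: 0=UNK, 1=BOS, 2=EOS, then the charset
        self._char_index = {ch: i + 3 for i, ch in enumerate(self.charset)}

    # -- categories --------------------------------------------------------

    @property
    def n_cats(self) -> int:
        return len(self.categories)

    @property
    def n_real_cats(self) -> int:
        return len(self.categories) - N_RESERVED_CATS

    def cat_id(self, label: str) -> int:
        return self._cat_index.get(label, UNK_CAT)

    def real_cat_ids(self) -> range:
        return range(N_RESERVED_CATS, len(self.categories))

    # -- lexical context support -------------------------------------------

    @property
    def n_lex_contexts(self) -> int:
        return len(self.lex_contexts)

    def lex_context_id(self, h: bytes) -> int | None:
        return self._lex_index.get(h)

    def add_lex_context(self, h: bytes) -> int:
        if h not in self._lex_index:
            self._lex_index[h] = len(self.lex_contexts)
            self.lex_contexts.append(h)
        return self._lex_index[h]

    # -- characters ----------------------------------------------------------

    @property
    def n_chars(self) -> int:
        return len(self.charset) + 3

    def char_id(self, ch: str) -> int:
        return self._char_index.get(ch, 0)

    def encode_lemma(self, lemma: str) -> list[int]:
        return [self.char_id(c) for c in lemma]

    # -- serialization -------------------------------------------------------

    def to_json(self) -> dict:
        return {
            "categories": [
                [c.label, c.valence, c.nonlocal_arity] for c in self.categories
            ],
            "predicates": list(self.space.predicates),
            "V": self.space.V,
            "E": self.space.E,
            "rules": self.rules.to_json(),
            "charset": self.charset,
            "lex_contexts": [h.hex() for h in self.lex_contexts],
            "D": self.D,
        }

    @classmethod
    def from_json(cls, data: dict) -> "Inventories":
        return cls(
            categories=[Category(*c) for c in data["categories"]],
            space=ContextSpace(tuple(data["predicates"]), data["V"], data["E"]),
            rules=RuleInventory.from_json(data["rules"]),
            charset=data["charset"],
            lex_contexts=[bytes.fromhex(h) for h in data["lex_contexts"]],
            D=data["D"],
        )


def make_inventories(
    categories, predicates, V, E, rules=None, charset="", lex_contexts=(), D=4
) -> Inventories:
    """Build inventories, prepending the reserved categories."""
    cats = [Category(START_LABEL), Category(UNK_LABEL)]
    for c in categories:
        cats.append(c if isinstance(c, Category) else Category(*c))
    return Inventories(
        categories=cats,
        space=ContextSpace.build(predicates, V, E),
        rules=rules if rules is not None else RuleInventory(),
        charset=charset,
        lex_contexts=list(lex_contexts),
        D=D,
    )
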