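"""Morphological rules: wildcard suffix substitution between lemma and word.

A rule ``%ay -> %aid`` maps any lemma ending in ``ay`` to the word formed by
replacing that suffix with ``aid`` (so ``say -> said``), binding the ``%``
wildcard to the shared prefix.  Rules are restricted to a single leading
wildcard (suffix morphology).  Two reserved rules always occupy ids 0 and 1:
the identity rule (bare forms) and a "no semantics" rule, identity-shaped
but flagged so that function words generated by it can be told apart.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import FormatError

IDENTITY = "identity"
NO_SEMANTICS = "no_semantics"
SUBSTITUTION = "substitution"

IDENTITY_RULE_ID = 0
NO_SEMANTICS_RULE_ID = 1

_ARROWS = ("→", "->")


@dataclass(frozen=True)
class MorphRule:
    lhs: str  # e.g. "%ay"; "%" alone matches any lemma
    rhs: str
    kind: str = SUBSTITUTION
    capitalize: bool = False  # apply to a lowercased lemma, capitalize the word

    def __post_init__(self):
        for side, name in ((self.lhs, "lhs"), (self.rhs, "rhs")):
            if side.count("%") > 1:
                raise FormatError(f"multiple wildcards in {name} {side!r}")
            if "%" in side and not side.startswith("%"):
                raise FormatError(f"wildcard not at position 0 in {name} {side!r}")
        if ("%" in self.lhs) != ("%" in self.rhs):
            raise FormatError(
                f"wildcard must appear on both sides or neither: "
                f"{self.lhs!r}->{self.rhs!r}"
            )

    @property
    def wildcard(self) -> bool:
        return self.lhs.startswith("%")

    @property
    def lhs_suffix(self) -> str:
        return self.lhs[1:] if self.wildcard else self.lhs

    @property
    def rhs_suffix(self) -> str:
        return self.rhs[1:] if self.wildcard else self.rhs

    def apply(self, lemma: str) -> str | None:
        """Inflect ``lemma``; None when the rule does not match."""
        if not lemma:
            raise ValueError("lemma must be nonempty")
        if self.wildcard:
            if not lemma.endswith(self.lhs_suffix):
                return None
            stem = lemma[: len(lemma) - len(self.lhs_suffix)]
            word = stem + self.rhs_suffix
        else:
            if lemma != self.lhs:
                return None
            word = self.rhs
        if not word:
            return None
        if self.capitalize:
            word = word[0].upper() + word[1:]
        return word

    def invert(self, word: str) -> set[str]:
        """All lemmas x with apply(x) == word (at most one for suffix rules)."""
        if not word:
            raise ValueError("word must be nonempty")
        if self.capitalize:
            if not word[0].isupper():
                return set()
            word = word[0].lower() + word[1:]
        if not self.wildcard:
            return {self.lhs} if word == self.rhs else set()
        if not word.endswith(self.rhs_suffix):
            return set()
        stem = word[: len(word) - len(self.rhs_suffix)]
        lemma = stem + self.lhs_suffix
        # guard: apply must regenerate the word (e.g. empty-lemma edge cases)
        base = MorphRule(self.lhs, self.rhs, self.kind)
        if lemma and base.apply(lemma) == (
            word if not self.capitalize else word
        ):
            return {lemma}
        return set()


def identity_rule(kind: str = IDENTITY) -> MorphRule:
    return MorphRule("%", "%", kind)


def parse_rule(text: str, line: int | None = None) -> MorphRule:
    """Parse one ``lhs->rhs`` rule-file line."""
    body = text.split("#", 1)[0].strip()
    for arrow in _ARROWS:
        if arrow in body:
            lhs, _, rhs = body.partition(arrow)
            lhs, rhs = lhs.strip(), rhs.strip()
            if not lhs or not rhs:
                raise FormatError(f"empty rule side in {text!r}", line)
            try:
                rule = MorphRule(lhs, rhs)
            except FormatError as exc:
                raise FormatError(str(exc), line) from None
            if lhs == "%" and rhs == "%":
                return identity_rule()
            return rule
    raise FormatError(f"missing arrow in rule line {text!r}", line)


class RuleInventory:
    """Ordered rule set; ids 0/1 reserved for identity / no-semantics."""

    def __init__(self, rules=(), capitalized_twins: bool = False):
        self.rules: list[MorphRule] = [
            identity_rule(IDENTITY),
            identity_rule(NO_SEMANTICS),
        ]
        seen = {(r.lhs, r.rhs, r.kind, r.capitalize) for r in self.rules}
        for r in rules:
            key = (r.lhs, r.rhs, r.kind, r.capitalize)
            if key not in seen:
                seen.add(key)
                self.rules.append(r)
        if capitalized_twins:
            for r in list(self.rules):
                twin = MorphRule(r.lhs, r.rhs, r.kind, capitalize=True)
                key = (twin.lhs, twin.rhs, twin.kind, True)
                if key not in seen:
                    seen.add(key)
                    self.rules.append(twin)

    def __len__(self):
        return len(self.rules)

    def __getitem__(self, rule_id: int) -> MorphRule:
        return self.rules[rule_id]

    def __iter__(self):
        return iter(self.rules)

    @classmethod
    def from_lines(cls, lines, capitalized_twins: bool = False) -> "RuleInventory":
        rules = []
        for i, raw in enumerate(lines, start=1):
            body = raw.split("#", 1)[0].strip()
            if not body:
                continue
            rules.append(parse_rule(body, line=i))
        return cls(rules, capitalized_twins=capitalized_twins)

    @classmethod
    def read(cls, path, **kw) -> "RuleInventory":
        with open(path, encoding="utf-8") as fh:
            return cls.from_lines(fh, **kw)

    def write(self, path):
        with open(path, "w", encoding="utf-8") as fh:
            for r in self.rules:
                fh.write(f"{r.lhs}→{r.rhs}\n")

    def to_json(self):
        return [
            {"lhs": r.lhs, "rhs": r.rhs, "kind": r.kind, "cap": r.capitalize}
            for r in self.rules
        ]

    @classmethod
    def from_json(cls, data) -> "RuleInventory":
        inv = cls()
        inv.rules = [
            MorphRule(d["lhs"], d["rhs"], d["kind"], d.get("cap", False))
            for d in data
        ]
        return inv
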