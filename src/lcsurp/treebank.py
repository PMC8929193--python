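"""Reader/writer for the annotated-treebank dialect.

One tree per line, PTB-style bracketing.  Nonterminal labels have the form
``CATEGORY:ctx1,ctx2,...`` where each context token is
``PREDICATE_role[.block]``; leaves are ``word|lemma|ruleid``.  Optional
header lines declare the inventories so that fixture files are
self-describing::

    #! V 1
    #! E 0
    #! predicate EAT
    #! category S 0 0
    (S:EAT_0 (N people|people|0) (V:EAT_0 ate|eat|2))

Convention for node annotations (used by the left-corner oracle):
preterminals store the lexical increment vector h_l; nonterminals store
their creation-time vector.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

from .categories import Category
from .errors import FormatError
from .morph import RuleInventory

_TOKENIZE = re.compile(r"\(|\)|[^\s()]+")


@dataclass(frozen=True)
class TreeNode:
    label: str
    ctx_tokens: tuple[str, ...] = ()
    children: tuple["TreeNode", ...] = ()
    word: str | None = None
    lemma: str | None = None
    rule_id: int | None = None

    @property
    def is_leaf(self) -> bool:
        return self.word is not None

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for ch in self.children:
            out.extend(ch.leaves())
        return out

    def words(self) -> list[str]:
        return [lf.word for lf in self.leaves()]

    def __len__(self) -> int:
        return len(self.leaves())


@dataclass
class TreebankHeader:
    categories: list[Category] = field(default_factory=list)
    predicates: list[str] = field(default_factory=list)
    V: int = 0
    E: int = 0
    D: int = 4


def _parse_label(token: str, line: int) -> tuple[str, tuple[str, ...]]:
    label, sep, ctxs = token.partition(":")
    if not label:
        raise FormatError(f"empty category label in {token!r}", line)
    tokens = tuple(t for t in ctxs.split(",") if t) if sep else ()
    return label, tokens


def _parse_leaf(token: str, line: int) -> tuple[str, str, int]:
    parts = token.split("|")
    if len(parts) != 3:
        raise FormatError(f"leaf must be word|lemma|ruleid, got {token!r}", line)
    word, lemma, rid = parts
    if not word or not lemma:
        raise FormatError(f"empty word or lemma in {token!r}", line)
    try:
        rule_id = int(rid)
    except ValueError:
        raise FormatError(f"non-integer rule id in {token!r}", line) from None
    return word, lemma, rule_id


def parse_tree(text: str, line: int = 0) -> TreeNode:
    tokens = _TOKENIZE.findall(text)
    pos = 0

    def parse_node() -> TreeNode:
        nonlocal pos
        if pos >= len(tokens) or tokens[pos] != "(":
            raise FormatError("expected '('", line)
        pos += 1
        if pos >= len(tokens) or tokens[pos] in "()":
            raise FormatError("expected node label after '('", line)
        label, ctxs = _parse_label(tokens[pos], line)
        pos += 1
        children: list[TreeNode] = []
        word = lemma = None
        rule_id = None
        while pos < len(tokens) and tokens[pos] != ")":
            if tokens[pos] == "(":
                children.append(parse_node())
            else:
                if word is not None or children:
                    raise FormatError(
                        "terminal must be the only child of a preterminal", line
                    )
                word, lemma, rule_id = _parse_leaf(tokens[pos], line)
                pos += 1
        if pos >= len(tokens):
            raise FormatError("unbalanced brackets (missing ')')", line)
        pos += 1  # consume ')'
        if word is not None:
            return TreeNode(label, ctxs, (), word, lemma, rule_id)
        if len(children) != 2:
            raise FormatError(
                f"nonterminal {label!r} must be binary (got {len(children)} children)",
                line,
            )
        return TreeNode(label, ctxs, tuple(children))

    node = parse_node()
    if pos != len(tokens):
        raise FormatError("trailing material after tree", line)
    return node


def format_tree(node: TreeNode) -> str:
    label = node.label
    if node.ctx_tokens:
        label += ":" + ",".join(node.ctx_tokens)
    if node.is_leaf:
        return f"({label} {node.word}|{node.lemma}|{node.rule_id})"
    return f"({label} " + " ".join(format_tree(c) for c in node.children) + ")"


def validate_tree(
    node: TreeNode, rules: RuleInventory | None = None, line: int = 0
) -> None:
    """Check the n-unary / (n-1)-binary CNF shape and leaf consistency."""
    if node.is_leaf:
        if rules is not None:
            if node.rule_id >= len(rules):
                raise FormatError(
                    f"unknown rule id {node.rule_id} at leaf {node.word!r}", line
                )
            got = rules[node.rule_id].apply(node.lemma)
            if got != node.word:
                raise FormatError(
                    f"rule {node.rule_id} maps {node.lemma!r} to {got!r}, "
                    f"leaf says {node.word!r}",
                    line,
                )
        return
    if len(node.children) != 2:
        raise FormatError(f"non-binary nonterminal {node.label!r}", line)
    for ch in node.children:
        validate_tree(ch, rules, line)


def branch_counts(node: TreeNode) -> tuple[int, int]:
    """(unary preterminal branches, binary branches)."""
    if node.is_leaf:
        return 1, 0
    u = b = 0
    for ch in node.children:
        cu, cb = branch_counts(ch)
        u += cu
        b += cb
    return u, b + 1


def _parse_header_line(body: str, header: TreebankHeader, line: int) -> None:
    parts = body.split()
    if not parts:
        return
    key = parts[0]
    try:
        if key == "V":
            header.V = int(parts[1])
        elif key == "E":
            header.E = int(parts[1])
        elif key == "D":
            header.D = int(parts[1])
        elif key == "predicate":
            header.predicates.extend(parts[1:])
        elif key == "category":
            header.categories.append(
                Category(parts[1], int(parts[2]), int(parts[3]))
            )
        else:
            raise FormatError(f"unknown header key {key!r}", line)
    except (IndexError, ValueError):
        raise FormatError(f"malformed header line {body!r}", line) from None


def read_treebank(
    source,
    rules: RuleInventory | None = None,
    strict: bool = True,
):
    """Read trees (one per line) with optional ``#!`` header lines.

    Returns ``(trees, header, errors)``; with ``strict=True`` the first
    malformed tree raises, otherwise it is recorded (with its line number)
    and skipped.  ``source`` may be a file path, an open stream, or literal
    treebank text (recognized by a newline or a leading ``(``/``#``).
    """
    if isinstance(source, str) and (
        "\n" in source or source.lstrip()[:1] in ("(", "#")
    ):
        fh = io.StringIO(source)
    elif hasattr(source, "read"):
        fh = source
    else:
        fh = open(source, encoding="utf-8")
    header = TreebankHeader()
    trees: list[TreeNode] = []
    errors: list[tuple[int, str]] = []
    try:
        for lineno, raw in enumerate(fh, start=1):
            text = raw.strip()
            if not text:
                continue
            if text.startswith("#!"):
                _parse_header_line(text[2:].strip(), header, lineno)
                continue
            if text.startswith("#"):
                continue
            try:
                tree = parse_tree(text, lineno)
                validate_tree(tree, rules, lineno)
            except FormatError as exc:
                if strict:
                    raise
                errors.append((lineno, str(exc)))
                continue
            trees.append(tree)
    finally:
        if fh is not source and not isinstance(source, str):
            fh.close()
        elif isinstance(source, str):
            fh.close()
    return trees, header, errors


def write_treebank(trees, path_or_fh, header: TreebankHeader | None = None) -> None:
    fh = (
        path_or_fh
        if hasattr(path_or_fh, "write")
        else open(path_or_fh, "w", encoding="utf-8")
    )
    try:
        if header is not None:
            fh.write(f"#! V {header.V}\n#! E {header.E}\n#! D {header.D}\n")
            for p in header.predicates:
                fh.write(f"#! predicate {p}\n")
            for c in header.categories:
                fh.write(f"#! category {c.label} {c.valence} {c.nonlocal_arity}\n")
        for t in trees:
            fh.write(format_tree(t) + "\n")
    finally:
        if fh is not path_or_fh:
            fh.close()
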