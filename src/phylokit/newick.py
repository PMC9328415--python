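"""Newick reading and writing.

The parser is a single-pass, iterative state machine over the input text:
no recursion (nesting depth is limited only by memory), no regular-expression
backtracking, and O(length) work, which is what lets trees with 10^6 leaves
load in seconds. Supported dialect:

* nested parentheses, leaf and internal labels;
* ``:``-prefixed edge lengths in decimal or scientific notation;
* single-quoted labels with ``''`` escaping a literal quote;
* underscores in unquoted labels preserved verbatim (no space conversion);
* square-bracket comments (nesting allowed), stored verbatim on the node
  whose syntactic position they follow under attribute keys ``comment_0``,
  ``comment_1``, ...; they are never parsed as structure;
* a leading ``[&R]`` / ``[&U]`` comment setting the rootedness flag.

The writer is the inverse: children in stored order, labels quoted whenever
they contain structural characters or whitespace, lengths emitted for every
node that stores one, using the shortest representation that round-trips the
value (or a fixed number of decimals when ``precision`` is given).
"""

from __future__ import annotations

from typing import Optional

from .errors import TreeParseError
from .sources import TreeSource, read_source
from .tree import Node, Tree

__all__ = ["read_tree_newick", "read_trees_newick", "write_tree_newick"]

_LABEL_DELIMS = set("(),:;[]' \t\n\r")
_NEEDS_QUOTE = set("(),:;[]'")
_NUMBER_CHARS = set("0123456789+-.eE")


def read_tree_newick(source: TreeSource) -> Tree:
    """Parse the first ``;``-terminated Newick statement from ``source``.

    ``source`` may be a Newick string, a plaintext file path, or a gzipped
    file path (auto-detected). Use :func:`read_trees_newick` for multi-tree
    files.
    """
    text = read_source(source)
    tree, _ = _parse_statement(text, 0)
    return tree


def read_trees_newick(source: TreeSource) -> list[Tree]:
    """Parse every ``;``-terminated Newick statement from ``source``, in order."""
    text = read_source(source)
    trees = []
    i = 0
    n = len(text)
    while True:
        while i < n and text[i].isspace():
            i += 1
        if i >= n:
            break
        tree, i = _parse_statement(text, i)
        trees.append(tree)
    if not trees:
        raise TreeParseError("no Newick statement found (missing ';'?)")
    return trees


def _parse_statement(text: str, i: int) -> tuple[Tree, int]:
    n = len(text)
    root = Node()
    cur = root
    depth = 0
    is_rooted = True
    seen_structure = False  # set once any non-comment token has been consumed
    comment_counts: dict[int, int] = {}

    while i < n:
        c = text[i]
        if c.isspace():
            i += 1
        elif c == "[":
            body, i = _scan_comment(text, i)
            if not seen_structure and body.upper() in ("&R", "&U"):
                is_rooted = body.upper() == "&R"
            else:
                k = comment_counts.get(id(cur), 0)
                cur.attributes[f"comment_{k}"] = body
                comment_counts[id(cur)] = k + 1
        elif c == "(":
            seen_structure = True
            depth += 1
            child = Node()
            cur.children.append(child)
            child.parent = cur
            cur = child
            i += 1
        elif c == ",":
            seen_structure = True
            if cur.parent is None:
                raise TreeParseError("',' outside parentheses", i)
            sibling = Node()
            cur.parent.children.append(sibling)
            sibling.parent = cur.parent
            cur = sibling
            i += 1
        elif c == ")":
            seen_structure = True
            if depth == 0:
                raise TreeParseError("unbalanced ')'", i)
            depth -= 1
            cur = cur.parent
            i += 1
        elif c == ":":
            seen_structure = True
            length, i = _scan_number(text, i + 1)
            cur.edge_length = length
        elif c == ";":
            if depth != 0:
                raise TreeParseError(
                    f"unbalanced parentheses: {depth} unclosed '('", i)
            return Tree(root, is_rooted=is_rooted), i + 1
        elif c == "'":
            seen_structure = True
            cur.label, i = _scan_quoted(text, i)
        else:
            seen_structure = True
            cur.label, i = _scan_unquoted(text, i)
    raise TreeParseError("unexpected end of input: missing ';'", n)


def _scan_comment(text: str, i: int) -> tuple[str, int]:
    start = i
    depth = 0
    i0 = i
    while i < len(text):
        if text[i] == "[":
            depth += 1
        elif text[i] == "]":
            depth -= 1
            if depth == 0:
                return text[i0 + 1:i], i + 1
        i += 1
    raise TreeParseError("unterminated '[' comment", start)


def _scan_quoted(text: str, i: int) -> tuple[str, int]:
    start = i
    i += 1
    out = []
    while i < len(text):
        c = text[i]
        if c == "'":
            if i + 1 < len(text) and text[i + 1] == "'":
                out.append("'")
                i += 2
            else:
                return "".join(out), i + 1
        else:
            out.append(c)
            i += 1
    raise TreeParseError("unterminated quoted label", start)


def _scan_unquoted(text: str, i: int) -> tuple[str, int]:
    j = i
    while j < len(text) and text[j] not in _LABEL_DELIMS:
        j += 1
    return text[i:j], j


def _scan_number(text: str, i: int) -> tuple[float, int]:
    j = i
    while j < len(text) and text[j] in _NUMBER_CHARS:
        # '+'/'-' only valid at the start or right after an exponent marker
        if text[j] in "+-" and j > i and text[j - 1] not in "eE":
            break
        j += 1
    token = text[i:j]
    if not token:
        raise TreeParseError("dangling ':' with no edge length", i)
    try:
        value = float(token)
    except ValueError:
        raise TreeParseError(f"invalid edge length {token!r}", i) from None
    if value < 0:
        raise TreeParseError(f"negative edge length {token!r}", i)
    return value, j


# -- writing ----------------------------------------------------------------

def _format_label(label: Optional[str]) -> str:
    if label is None:
        return ""
    if label == "" or any(ch in _NEEDS_QUOTE or ch.isspace() for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _format_length(value: float, precision: Optional[int]) -> str:
    if precision is not None:
        return f"{value:.{precision}f}"
    return repr(value)


def write_tree_newick(tree: Tree, precision: Optional[int] = None) -> str:
    """Serialize ``tree`` to a Newick string (iteratively; safe at any depth)."""
    out: list[str] = []
    # work items are either literal text or a node to expand
    stack: list[object] = [tree.root]
    while stack:
        item = stack.pop()
        if isinstance(item, str):
            out.append(item)
            continue
        node = item
        suffix = _format_label(node.label)
        if node.edge_length is not None:
            suffix += ":" + _format_length(node.edge_length, precision)
        if not node.children:
            out.append(suffix)
            continue
        out.append("(")
        seq: list[object] = []
        for idx, child in enumerate(node.children):
            if idx:
                seq.append(",")
            seq.append(child)
        seq.append(")" + suffix)
        stack.extend(reversed(seq))
    out.append(";")
    return "".join(out)
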