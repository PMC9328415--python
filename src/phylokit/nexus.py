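"""NEXUS reading (TREES block with optional TRANSLATE table).

Only the structural subset needed to recover trees is parsed: the ``#NEXUS``
header, a ``BEGIN TREES ... END;`` block, an optional ``TRANSLATE`` table,
and ``TREE <name> = [rooting-hint] <newick>;`` statements. Statement
splitting respects single-quoted labels and square-bracket comments, so
quoted taxon names containing ``;`` survive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import TreeParseError
from .newick import read_tree_newick
from .sources import TreeSource, read_source
from .tree import Tree

__all__ = ["NexusDocument", "read_tree_nexus"]


@dataclass
class NexusDocument:
    """Trees of one NEXUS file, in file order, plus the translate table."""

    trees: dict[str, Tree] = field(default_factory=dict)
    translate: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, name: str) -> Tree:
        return self.trees[name]

    def __iter__(self):
        return iter(self.trees.values())

    def __len__(self) -> int:
        return len(self.trees)


def read_tree_nexus(source: TreeSource) -> NexusDocument:
    """Parse a NEXUS document's TREES block into named trees.

    TRANSLATE tokens are resolved to taxon labels before trees are returned.
    """
    text = read_source(source)
    stripped = text.lstrip()
    if not stripped[:6].upper() == "#NEXUS":
        raise TreeParseError("NEXUS input must begin with '#NEXUS'", 0)

    doc = NexusDocument()
    in_trees = False
    block_closed = True
    for stmt in _statements(stripped[6:]):
        words = stmt.split(None, 2)
        if not words:
            continue
        keyword = words[0].upper()
        if keyword == "BEGIN" and len(words) > 1 and \
                words[1].rstrip(";").upper() == "TREES":
            in_trees = True
            block_closed = False
        elif keyword in ("END", "ENDBLOCK"):
            if in_trees:
                block_closed = True
            in_trees = False
        elif in_trees and keyword == "TRANSLATE":
            _parse_translate(stmt[len(words[0]):], doc.translate)
        elif in_trees and keyword in ("TREE", "UTREE"):
            name, _, newick_part = stmt[len(words[0]):].partition("=")
            name = name.strip().strip("'")
            if not newick_part.strip():
                raise TreeParseError(f"TREE statement without '=': {stmt[:40]!r}")
            tree = read_tree_newick(newick_part.strip() + ";")
            if keyword == "UTREE":
                tree.is_rooted = False
            _apply_translate(tree, doc.translate)
            doc.trees[name] = tree
    if not block_closed:
        raise TreeParseError("unterminated TREES block (missing END;)")
    if not doc.trees:
        raise TreeParseError("no TREES block with TREE statements found")
    return doc


def _statements(text: str):
    """Split on ';' outside quotes and comments; yields statements sans ';'."""
    buf = []
    i = 0
    n = len(text)
    while i < n:
        c = text[i]
        if c == "'":
            j = i + 1
            while j < n:
                if text[j] == "'" and not (j + 1 < n and text[j + 1] == "'"):
                    break
                j += 2 if text[j] == "'" else 1
            buf.append(text[i:j + 1])
            i = j + 1
        elif c == "[":
            depth = 0
            j = i
            while j < n:
                if text[j] == "[":
                    depth += 1
                elif text[j] == "]":
                    depth -= 1
                    if depth == 0:
                        break
                j += 1
            buf.append(text[i:j + 1])
            i = j + 1
        elif c == ";":
            yield "".join(buf).strip()
            buf = []
            i += 1
        else:
            buf.append(c)
            i += 1
    tail = "".join(buf).strip()
    if tail:
        yield tail


def _parse_translate(body: str, table: dict[str, str]) -> None:
    for entry in body.split(","):
        parts = entry.split()
        if len(parts) >= 2:
            token = parts[0].strip("'")
            label = " ".join(parts[1:]).strip("'")
            table[token] = label


def _apply_translate(tree: Tree, table: dict[str, str]) -> None:
    if not table:
        return
    for node in tree.traverse_preorder():
        if node.label is not None and node.label in table:
            node.label = table[node.label]
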