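"""NeXML reading (structural subset: trees, nodes, edges, labels, lengths).

Node identity comes from XML ids; a node's display label is its ``label``
attribute when present, falling back to its ``otu`` reference. Edge lengths
come from ``length`` attributes and are optional. The unique node with no
incoming edge is the root; a ``<rootedge>`` element, when present, supplies
the root's own edge length. All other attributes are retained opaquely in
the node attribute map.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET

from .errors import TreeParseError
from .sources import TreeSource, read_source
from .tree import Node, Tree

__all__ = ["read_tree_nexml"]

_STRUCTURAL_ATTRS = {"id", "label", "otu", "source", "target", "length", "root"}


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def read_tree_nexml(source: TreeSource) -> list[Tree]:
    """Parse every ``<tree>`` element of a NeXML document, in document order."""
    text = read_source(source)
    try:
        xml_root = ET.fromstring(text)
    except ET.ParseError as exc:
        raise TreeParseError(f"malformed NeXML XML: {exc}") from None

    trees = []
    for elem in xml_root.iter():
        if _local(elem.tag) == "tree":
            trees.append(_build_tree(elem))
    if not trees:
        raise TreeParseError("no <tree> elements found in NeXML input")
    return trees


def _build_tree(tree_elem) -> Tree:
    nodes: dict[str, Node] = {}
    has_parent: set[str] = set()
    edges = []
    root_edge_length = None

    for child in tree_elem:
        tag = _local(child.tag)
        if tag == "node":
            node_id = child.get("id")
            if node_id is None:
                raise TreeParseError("NeXML <node> without id attribute")
            node = Node(label=child.get("label") or child.get("otu"))
            for key, value in child.attrib.items():
                if _local(key) not in _STRUCTURAL_ATTRS:
                    node.attributes[_local(key)] = value
            nodes[node_id] = node
        elif tag == "edge":
            edges.append((child.get("source"), child.get("target"),
                          child.get("length")))
        elif tag == "rootedge":
            if child.get("length") is not None:
                root_edge_length = float(child.get("length"))

    for source_id, target_id, length in edges:
        if source_id not in nodes or target_id not in nodes:
            missing = target_id if source_id in nodes else source_id
            raise TreeParseError(
                f"NeXML edge references undeclared node {missing!r}")
        parent, child = nodes[source_id], nodes[target_id]
        if length is not None:
            child.edge_length = float(length)
        parent.add_child(child)
        has_parent.add(target_id)

    parentless = [nid for nid in nodes if nid not in has_parent]
    if len(parentless) != 1:
        raise TreeParseError(
            f"NeXML tree must have exactly one root; found {len(parentless)} "
            f"parentless nodes")
    root = nodes[parentless[0]]
    if root_edge_length is not None:
        root.edge_length = root_edge_length
    return Tree(root)
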