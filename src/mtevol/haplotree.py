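"""Reference haplogroup phylogeny ("Phylotree-like") parsing.

The interchange format is indented UTF-8 text, one node per line::

    name<TAB>token token ...

with one leading TAB per tree level.  Defining-variant tokens use the same
shorthand as profiles; a ``@`` prefix is a back mutation and must cancel a
variant carried by an ancestor.  The cumulative variant set of a node is the
root path with back mutations applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from .reference import FormatError


@dataclass
class HaploNode:
    name: str
    tokens: list[str]
    children: list["HaploNode"] = field(default_factory=list)
    parent: "HaploNode | None" = None

    @property
    def depth(self) -> int:
        d, node = 0, self
        while node.parent is not None:
            d, node = d + 1, node.parent
        return d

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"HaploNode({self.name!r}, {self.tokens!r}, {len(self.children)} children)"


class HaploTree:
    """Rooted reference haplogroup tree with unique node names."""

    def __init__(self, root: HaploNode):
        self.root = root
        self.nodes: dict[str, HaploNode] = {}
        for node in self.walk():
            if node.name in self.nodes:
                raise FormatError(f"duplicate haplogroup name {node.name!r}")
            self.nodes[node.name] = node
        # validate back mutations against ancestral state
        for node in self.walk():
            self.cumulative_tokens(node.name)

    def walk(self) -> Iterator[HaploNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def __contains__(self, name: str) -> bool:
        return name in self.nodes

    def path_to(self, name: str) -> list[HaploNode]:
        """Root-to-node list of nodes."""
        node = self.nodes[name]
        path = [node]
        while node.parent is not None:
            node = node.parent
            path.append(node)
        return path[::-1]

    def cumulative_tokens(self, name: str) -> set[str]:
        """Variant set accumulated from the root, back mutations cancelled."""
        state: set[str] = set()
        for node in self.path_to(name):
            for token in node.tokens:
                if token.startswith("@"):
                    base = token[1:]
                    if base not in state:
                        raise FormatError(
                            f"back mutation {token} at {node.name} cancels "
                            f"nothing on its root path"
                        )
                    state.discard(base)
                else:
                    state.add(token)
        return state


def parse_haplotree(text: str) -> HaploTree:
    """Parse the indented tree format; see module docstring."""
    root: HaploNode | None = None
    stack: list[HaploNode] = []  # stack[i] = last node at depth i
    for line_no, raw in enumerate(text.splitlines(), 1):
        if not raw.strip() or raw.lstrip().startswith("#"):
            continue
        depth = len(raw) - len(raw.lstrip("\t"))
        body = raw.strip()
        parts = body.split("\t") if "\t" in body else body.split(None, 1)
        name = parts[0]
        tokens = parts[1].split() if len(parts) > 1 else []
        node = HaploNode(name, tokens)
        if depth == 0:
            if root is not None:
                raise FormatError(f"line {line_no}: multiple roots")
            root = node
            stack = [node]
        else:
            if depth > len(stack):
                raise FormatError(f"line {line_no}: indentation jumps a level")
            parent = stack[depth - 1]
            node.parent = parent
            parent.children.append(node)
            stack[depth:] = [node]
    if root is None:
        raise FormatError("empty haplogroup tree")
    return HaploTree(root)


def load_haplotree(path: str | Path) -> HaploTree:
    return parse_haplotree(Path(path).read_text())


def format_haplotree(tree: HaploTree) -> str:
    lines: list[str] = []

    def emit(node: HaploNode, depth: int) -> None:
        tokens = (" " .join(node.tokens)).strip()
        lines.append("\t" * depth + node.name + ("\t" + tokens if tokens else ""))
        for child in node.children:
            emit(child, depth + 1)

    emit(tree.root, 0)
    return "\n".join(lines) + "\n"
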