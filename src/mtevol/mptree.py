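"""Backbone-constrained maximum-parsimony tree of sample profiles.

Samples are placed on the reference haplogroup phylogeny at their called
node; within a node, samples sharing extra variants are grouped greedily
(largest shared set first, ties by lowest position) into sub-branches, and
whatever remains becomes terminal-edge events.  Defining variants expected
on the root path but absent from a profile are emitted as back-mutation
events (``@POS``) on the terminal edge, so that replaying events from the
root reconstructs every masked profile exactly.  The total number of edge
events is the parsimony score; positions carried by two or more independent
edges are recurrent (homoplasic).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator

from .haplocall import HaplogroupCall
from .haplotree import HaploNode, HaploTree

_NEWICK_UNSAFE = re.compile(r"[\s()\[\]{}:;,']")


def token_position(token: str) -> int:
    """Leading reference position of a shorthand token ('@' stripped)."""
    m = re.match(r"@?(\d+)", token)
    if m is None:
        raise ValueError(f"cannot extract position from token {token!r}")
    return int(m.group(1))


@dataclass
class MPNode:
    """Tree node; ``events`` sit on the edge leading into the node."""

    name: str
    kind: str  # 'root' | 'backbone' | 'subbranch' | 'sample'
    events: list[str] = field(default_factory=list)
    children: list["MPNode"] = field(default_factory=list)

    @property
    def is_tip(self) -> bool:
        return self.kind == "sample"


@dataclass
class EventRecord:
    edge: str  # name of the node the edge leads into
    token: str
    position: int
    status: str  # 'private' (terminal edge) or 'haplogroup-defining' (internal)
    backbone: bool  # True when the edge is part of the reference phylogeny
    haplogroup: str  # nearest enclosing backbone haplogroup


class MPTree:
    def __init__(self, root: MPNode):
        self.root = root

    def walk(self) -> Iterator[tuple[MPNode, MPNode | None]]:
        """Yield (node, parent) pairs, root first."""
        stack: list[tuple[MPNode, MPNode | None]] = [(self.root, None)]
        while stack:
            node, parent = stack.pop()
            yield node, parent
            stack.extend((c, node) for c in reversed(node.children))

    def tips(self) -> list[MPNode]:
        return [n for n, _ in self.walk() if n.is_tip]

    def parsimony_score(self) -> int:
        return sum(len(n.events) for n, _ in self.walk() if n is not self.root)

    def reconstruct_profiles(self) -> dict[str, set[str]]:
        """Replay edge events root-to-tip; back mutations cancel."""
        out: dict[str, set[str]] = {}

        def descend(node: MPNode, state: set[str]) -> None:
            state = set(state)
            for token in node.events:
                if token.startswith("@"):
                    state.discard(token[1:])
                else:
                    state.add(token)
            if node.is_tip:
                out[node.name] = state
            for child in node.children:
                descend(child, state)

        descend(self.root, set())
        return out


def parsimony_score(tree: MPTree) -> int:
    return tree.parsimony_score()


def _group_samples(
    parent: MPNode, extras: dict[str, set[str]], counter: list[int]
) -> None:
    """Greedy shared-variant grouping below one backbone node."""
    while True:
        carriers_of: dict[str, list[str]] = {}
        for sample, toks in extras.items():
            for t in toks:
                carriers_of.setdefault(t, []).append(sample)
        shared = {t: c for t, c in carriers_of.items() if len(c) >= 2}
        if not shared:
            break
        # largest carrier set first; ties by lowest position
        best = min(shared, key=lambda t: (-len(shared[t]), token_position(t)))
        members = sorted(shared[best])
        common = set.intersection(*(extras[s] for s in members))
        counter[0] += 1
        sub = MPNode(
            name=f"br{counter[0]}",
            kind="subbranch",
            events=sorted(common, key=token_position),
        )
        parent.children.append(sub)
        _group_samples(sub, {s: extras[s] - common for s in members}, counter)
        for s in members:
            del extras[s]
    for sample in sorted(extras):
        parent.children.append(
            MPNode(
                name=sample,
                kind="sample",
                events=sorted(extras[sample], key=token_position),
            )
        )


def build_mp_tree(
    profiles: dict[str, set[str]],
    backbone: HaploTree,
    calls: dict[str, HaplogroupCall],
) -> MPTree:
    """Build the backbone-constrained parsimony tree.

    ``profiles`` must already be hotspot-masked; every sample needs a call.
    The tree is the backbone subtree induced by the called haplogroups; each
    backbone edge carries the node's defining variants restricted to those
    any descendant sample actually matched (so masked or untyped defining
    variants never enter the event count).
    """
    missing_calls = set(profiles) - set(calls)
    if missing_calls:
        raise ValueError(f"profiles without haplogroup calls: {sorted(missing_calls)}")

    used = set()
    for sample in profiles:
        for node in backbone.path_to(calls[sample].haplogroup):
            used.add(node.name)

    # union over descendant samples of matched defining tokens, per node
    matched_at: dict[str, set[str]] = {name: set() for name in used}
    for sample in profiles:
        call = calls[sample]
        remaining = set(call.matched)
        for node in backbone.path_to(call.haplogroup):
            matched_at[node.name] |= remaining & set(
                t for t in node.tokens if not t.startswith("@")
            )
            remaining -= set(node.tokens)

    root = MPNode(name=backbone.root.name, kind="root")
    counter = [0]

    def build(hnode: HaploNode, mnode: MPNode) -> None:
        here = {
            s: set(calls[s].extras) | {f"@{t}" for t in calls[s].missing}
            for s in profiles
            if calls[s].haplogroup == hnode.name
        }
        _group_samples(mnode, here, counter)
        for child in hnode.children:
            if child.name not in used:
                continue
            events = [
                t
                for t in child.tokens
                if t.startswith("@") or t in matched_at[child.name]
            ]
            cnode = MPNode(
                name=child.name,
                kind="backbone",
                events=sorted(events, key=token_position),
            )
            mnode.children.append(cnode)
            build(child, cnode)

    build(backbone.root, root)
    tree = MPTree(root)
    _prune_dangling_back_mutations(tree)
    return tree


def _prune_dangling_back_mutations(tree: MPTree) -> None:
    """Drop ``@X`` events whose cancelled variant X never entered the tree
    upstream (e.g. a reference-tree reversion below a branch none of the
    cohort's samples actually carries); they would otherwise inflate the
    event count without representing an observable mutation."""

    def descend(node: MPNode, state: set[str]) -> None:
        kept: list[str] = []
        state = set(state)
        for token in node.events:
            if token.startswith("@"):
                if token[1:] in state:
                    state.discard(token[1:])
                    kept.append(token)
                # else: dangling reversion, dropped
            else:
                state.add(token)
                kept.append(token)
        node.events = kept
        for child in node.children:
            descend(child, state)

    descend(tree.root, set())


# --- variant partition ----------------------------------------------------


@dataclass
class VariantPartition:
    events: list[EventRecord]

    @property
    def recurrence(self) -> dict[int, list[str]]:
        """position -> edges carrying it, for positions on >=2 edges."""
        edges_at: dict[int, set[str]] = {}
        for ev in self.events:
            edges_at.setdefault(ev.position, set()).add(ev.edge)
        return {
            pos: sorted(edges) for pos, edges in edges_at.items() if len(edges) >= 2
        }

    def recurrent_positions(self, lo: int | None = None, hi: int | None = None) -> set[int]:
        return {
            pos
            for pos in self.recurrence
            if (lo is None or pos >= lo) and (hi is None or pos <= hi)
        }

    def by_status(self, status: str) -> list[EventRecord]:
        return [ev for ev in self.events if ev.status == status]


def partition_variants(tree: MPTree) -> VariantPartition:
    """Classify every placed event as private (terminal edge) vs
    haplogroup-defining (internal edge) and collect recurrences."""
    events: list[EventRecord] = []

    def descend(node: MPNode, context: str) -> None:
        if node.kind == "backbone":
            context = node.name
        for token in node.events:
            events.append(
                EventRecord(
                    edge=node.name,
                    token=token,
                    position=token_position(token),
                    status="private" if node.is_tip else "haplogroup-defining",
                    backbone=node.kind == "backbone",
                    haplogroup=context,
                )
            )
        for child in node.children:
            descend(child, context)

    for child in tree.root.children:
        descend(child, tree.root.name)
    return VariantPartition(events=events)


# --- newick export --------------------------------------------------------


def _newick_name(name: str) -> str:
    if _NEWICK_UNSAFE.search(name):
        return "'" + name.replace("'", "''") + "'"
    return name


def to_newick(tree: MPTree) -> str:
    """Newick string; sample ids label the leaves, branch length = number of
    mutation events on the edge."""

    def render(node: MPNode) -> str:
        if node.is_tip or not node.children:
            return f"{_newick_name(node.name)}:{len(node.events)}"
        inner = ",".join(render(c) for c in node.children)
        label = "" if node.kind in ("root",) else _newick_name(node.name)
        length = "" if node.kind == "root" else f":{len(node.events)}"
        return f"({inner}){label}{length}"

    return render(tree.root) + ";"


def write_events_table(partition: VariantPartition, labels: dict[str, str], path) -> None:
    """Events TSV: edge, token, suffix label, status, recurrent flag."""
    rec = partition.recurrence
    with open(path, "w") as fh:
        fh.write("edge\ttoken\tlabel\tstatus\thaplogroup\trecurrent\n")
        for ev in partition.events:
            fh.write(
                f"{ev.edge}\t{ev.token}\t{labels.get(ev.token, '')}\t{ev.status}\t"
                f"{ev.haplogroup}\t{int(ev.position in rec)}\n"
            )
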