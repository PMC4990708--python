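"""Time-calibrated trees, trait tables and ontogenetic series.

The central container is :class:`TimeTree`, a rooted tree whose branch
lengths are durations in millions of years.  Node ids are assigned in
preorder after sorting every node's children by the lexicographically
smallest tip label in their subtree, so the same topology always yields
the same ids — posterior summaries keyed by node id are then comparable
across runs and across tools.

Trees are read with dendropy and converted; trait tables and ontogeny
series are delimited text loaded with pandas.  Measurements are expected
in millimetres and natural-logged at load time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "TimeTree",
    "Node",
    "NewickParseError",
    "MissingBranchLengthError",
    "UnknownTaxonError",
    "parse_newick",
    "read_newick",
    "write_newick",
    "prune_to_taxa",
    "ancestor_chain",
    "read_trait_table",
    "trait_table_from_raw",
    "read_ontogeny_series",
]


class NewickParseError(ValueError):
    """The Newick string could not be parsed."""


class MissingBranchLengthError(ValueError):
    """A non-root node lacks a (positive) branch duration."""


class UnknownTaxonError(KeyError):
    """A requested taxon is not a tip of the tree."""

    def __str__(self) -> str:  # KeyError quotes its message; keep it readable
        return self.args[0] if self.args else ""


@dataclass
class Node:
    """One node of a :class:`TimeTree`."""

    id: int
    parent: int | None
    label: str | None
    duration: float | None  # Myr; None for the root
    children: list[int] = field(default_factory=list)

    @property
    def is_tip(self) -> bool:
        return not self.children


# internal proto-tree: [label, duration, [children]]
_Proto = list


class TimeTree:
    """Rooted tree with branch durations in Myr and stable integer node ids.

    Invariants enforced at construction: exactly one root, every non-root
    node has a strictly positive duration, tip labels are unique.  The tree
    need not be ultrametric (fossil tips end earlier than extant tips).
    """

    def __init__(self, nodes: dict[int, Node], root_id: int):
        self._nodes = nodes
        self._root_id = root_id
        self._tip_index: dict[str, int] = {}
        for node in nodes.values():
            if node.is_tip:
                if node.label is None:
                    raise ValueError(f"tip node {node.id} has no label")
                if node.label in self._tip_index:
                    raise ValueError(f"duplicate tip label {node.label!r}")
                self._tip_index[node.label] = node.id
            if node.id != root_id:
                if node.duration is None:
                    raise MissingBranchLengthError(
                        f"node {node.label or node.id} has no branch duration"
                    )
                if node.duration <= 0:
                    raise MissingBranchLengthError(
                        f"node {node.label or node.id} has non-positive "
                        f"duration {node.duration}"
                    )

    # -- construction ---------------------------------------------------

    @classmethod
    def from_proto(cls, proto: _Proto) -> "TimeTree":
        """Build from nested [label, duration, children] lists, assigning
        deterministic preorder ids (children sorted by smallest tip label)."""

        def min_tip(p: _Proto) -> str:
            label, _, children = p
            if not children:
                return label if label is not None else ""
            return min(min_tip(c) for c in children)

        nodes: dict[int, Node] = {}
        counter = [0]

        def build(p: _Proto, parent: int | None) -> int:
            nid = counter[0]
            counter[0] += 1
            label, duration, children = p
            nodes[nid] = Node(id=nid, parent=parent, label=label, duration=duration)
            for child in sorted(children, key=min_tip):
                cid = build(child, nid)
                nodes[nid].children.append(cid)
            return nid

        root_id = build(proto, None)
        return cls(nodes, root_id)

    def _to_proto(self, nid: int | None = None) -> _Proto:
        if nid is None:
            nid = self._root_id
        node = self._nodes[nid]
        return [node.label, node.duration, [self._to_proto(c) for c in node.children]]

    # -- basic accessors ------------------------------------------------

    @property
    def root_id(self) -> int:
        return self._root_id

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_tips(self) -> int:
        return len(self._tip_index)

    @property
    def tip_labels(self) -> list[str]:
        return sorted(self._tip_index)

    def node(self, nid: int) -> Node:
        return self._nodes[nid]

    def tip_id(self, label: str) -> int:
        try:
            return self._tip_index[label]
        except KeyError:
            raise UnknownTaxonError(f"unknown taxon: {label!r}") from None

    def is_tip(self, nid: int) -> bool:
        return self._nodes[nid].is_tip

    def parent(self, nid: int) -> int | None:
        return self._nodes[nid].parent

    def children(self, nid: int) -> list[int]:
        return list(self._nodes[nid].children)

    def duration(self, nid: int) -> float:
        d = self._nodes[nid].duration
        if d is None:
            raise ValueError("root has no branch duration")
        return d

    def preorder(self) -> Iterator[int]:
        stack = [self._root_id]
        while stack:
            nid = stack.pop()
            yield nid
            stack.extend(reversed(self._nodes[nid].children))

    def postorder(self) -> Iterator[int]:
        out: list[int] = []
        for nid in self.preorder():
            out.append(nid)
        return reversed(out)

    def tips(self) -> Iterator[int]:
        for nid in self.preorder():
            if self._nodes[nid].is_tip:
                yield nid

    def depth(self, nid: int) -> float:
        """Root-to-node path duration in Myr (0 for the root)."""
        total = 0.0
        while nid != self._root_id:
            total += self.duration(nid)
            nid = self._nodes[nid].parent  # type: ignore[assignment]
        return total

    def depths(self) -> dict[int, float]:
        out = {self._root_id: 0.0}
        for nid in self.preorder():
            if nid == self._root_id:
                continue
            out[nid] = out[self._nodes[nid].parent] + self.duration(nid)
        return out

    # -- serialisation --------------------------------------------------

    def to_newick(self, annotations: dict[int, str] | None = None) -> str:
        """Newick string; `annotations` maps node id -> comment string placed
        after the branch length as ``[&...]``."""

        def fmt(nid: int) -> str:
            node = self._nodes[nid]
            if node.children:
                inner = ",".join(fmt(c) for c in node.children)
                s = f"({inner})" + (node.label or "")
            else:
                s = node.label or ""
            if node.duration is not None:
                s += f":{node.duration!r}"
            if annotations and nid in annotations:
                s += f"[&{annotations[nid]}]"
            return s

        return fmt(self._root_id) + ";"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TimeTree):
            return NotImplemented
        return self.to_newick() == other.to_newick()

    def __repr__(self) -> str:
        return f"<TimeTree {self.n_tips} tips, {self.n_nodes} nodes>"


# ---------------------------------------------------------------------------
# Newick I/O


def parse_newick(newick: str) -> TimeTree:
    """Parse a single Newick string into a :class:`TimeTree`.

    Branch lengths are required on every non-root node; zero-length
    branches are rejected (a rate on a zero-duration branch is
    unidentifiable under Brownian models).
    """
    try:
        dtree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        offset = getattr(exc, "col_num", None)
        where = f" (near character {offset})" if offset is not None else ""
        raise NewickParseError(f"malformed Newick{where}: {exc}") from exc

    def convert(dnode: dendropy.Node) -> _Proto:
        if dnode.taxon is not None:
            label = dnode.taxon.label
        else:
            label = dnode.label
        children = [convert(c) for c in dnode.child_nodes()]
        if dnode.parent_node is not None and dnode.edge.length is None:
            name = label or f"internal node above {{{', '.join(_tip_names(dnode))}}}"
            raise MissingBranchLengthError(f"node {name} lacks a branch length")
        duration = dnode.edge.length if dnode.parent_node is not None else None
        return [label, duration, children]

    def _tip_names(dnode: dendropy.Node) -> list[str]:
        return [l.taxon.label for l in dnode.leaf_iter() if l.taxon is not None]

    return TimeTree.from_proto(convert(dtree.seed_node))


def read_newick(path: str | Path) -> TimeTree:
    """Read one Newick tree from a file."""
    text = Path(path).read_text().strip()
    if not text:
        raise NewickParseError(f"{path}: empty file")
    return parse_newick(text)


def write_newick(tree: TimeTree, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# Pruning and ancestor chains


def prune_to_taxa(tree: TimeTree, keep: Iterable[str]) -> TimeTree:
    """Prune the tree to the tips in `keep`.

    Degree-2 internal nodes created by pruning are collapsed with their
    durations summed, so the root-to-tip path duration of every kept tip
    is exactly preserved.  The original root is always retained (it may be
    left with a single child) — re-rooting at the MRCA of the kept taxa
    would shorten kept tips' root-to-tip paths.
    """
    keep = set(keep)
    if not keep:
        raise ValueError("keep must be a nonempty set of taxon names")
    unknown = keep - set(tree.tip_labels)
    if unknown:
        raise UnknownTaxonError(f"unknown taxa: {sorted(unknown)}")

    def rec(nid: int) -> _Proto | None:
        node = tree.node(nid)
        if node.is_tip:
            if node.label in keep:
                return [node.label, node.duration, []]
            return None
        kept = [p for p in (rec(c) for c in node.children) if p is not None]
        if not kept:
            return None
        if len(kept) == 1 and nid != tree.root_id:
            # collapse this degree-2 node into its single surviving child
            child = kept[0]
            child[1] = child[1] + node.duration
            return child
        return [node.label, node.duration, kept]

    proto = rec(tree.root_id)
    assert proto is not None  # keep is nonempty and validated
    return TimeTree.from_proto(proto)


def ancestor_chain(tree: TimeTree, tip: str) -> list[int]:
    """Node ids from the root to the named tip, inclusive, parent-first."""
    nid = tree.tip_id(tip)
    chain = [nid]
    while (p := tree.parent(nid)) is not None:
        chain.append(p)
        nid = p
    return chain[::-1]


# ---------------------------------------------------------------------------
# Trait tables and ontogeny series


def _read_delimited(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def trait_table_from_raw(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a taxon/rap_mm/hw_mm frame and add ln columns.

    Measurements are in millimetres; natural logs are taken here so that
    downstream modules only ever see ln-scaled traits.
    """
    if df["taxon"].duplicated().any():
        dupes = sorted(df.loc[df["taxon"].duplicated(), "taxon"])
        raise ValueError(f"duplicate taxa: {dupes}")
    if (df[["rap_mm", "hw_mm"]] <= 0).any().any():
        raise ValueError("rap_mm and hw_mm must be strictly positive")
    out = df.set_index("taxon").copy()
    out["ln_rap"] = np.log(out["rap_mm"].astype(float))
    out["ln_hw"] = np.log(out["hw_mm"].astype(float))
    return out


def read_trait_table(path: str | Path) -> pd.DataFrame:
    """Load a per-taxon trait table (columns taxon, rap_mm, hw_mm).

    Returns a DataFrame indexed by taxon with raw and ln-scaled columns.
    """
    return trait_table_from_raw(_read_delimited(path, ["taxon", "rap_mm", "hw_mm"]))


def read_ontogeny_series(path: str | Path) -> pd.DataFrame:
    """Load an ontogenetic series (specimen, total_length_cm, rap_mm, hw_mm)."""
    df = _read_delimited(path, ["specimen", "total_length_cm", "rap_mm", "hw_mm"])
    if (df[["total_length_cm", "rap_mm", "hw_mm"]] <= 0).any().any():
        raise ValueError("all measurements must be strictly positive")
    return df.reset_index(drop=True)
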