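"""Rooted phylogenetic trees: data model, Newick I/O, and topology primitives.

This module provides the tree container used throughout the package
(:class:`PhyloTree`), Newick reading/writing, and the unrooted-topology
primitives every downstream analysis consumes: bipartitions, Robinson-Foulds
distance, MRCA lookup, branch-length sums, node-support summaries, and a
canonical topology identifier.

Newick parsing is delegated to :mod:`dendropy`; the parsed tree is converted
into the lightweight node model defined here.  Internal-node labels that parse
as numbers in [0, 100] are interpreted as supports (the IQ-TREE convention),
which can be disabled or adapted for compound ``support/other`` labels.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import dendropy

__all__ = [
    "TreeError",
    "NewickParseError",
    "LeafSetMismatchError",
    "Node",
    "PhyloTree",
    "Bipartition",
    "parse_newick",
    "write_newick",
    "read_tree_file",
    "write_tree_file",
    "bipartitions",
    "rf_distance",
    "mrca",
    "total_tree_length",
    "mean_support",
    "topology_id",
    "reroot_on_leaf",
    "restrict",
]


class TreeError(ValueError):
    """Invalid tree structure or invalid operation on a tree."""


class NewickParseError(TreeError):
    """Malformed Newick input; carries a human-readable position when known."""


class LeafSetMismatchError(TreeError):
    """Two trees that must share a leaf set do not; names the differing taxa."""

    def __init__(self, only_first: Iterable[str], only_second: Iterable[str]):
        self.only_first = sorted(only_first)
        self.only_second = sorted(only_second)
        super().__init__(
            "leaf sets differ: only in first tree: "
            f"{self.only_first or '[]'}; only in second tree: {self.only_second or '[]'}"
        )


@dataclass
class Node:
    """One tree node.

    ``length`` is the branch length of the edge above the node (absent at the
    root), ``support`` a value in [0, 100] (internal nodes only), ``name`` the
    taxon label for leaves (optional elsewhere).
    """

    name: str | None = None
    length: float | None = None
    support: float | None = None
    children: list["Node"] = field(default_factory=list)
    parent: "Node | None" = field(default=None, repr=False, compare=False)

    @property
    def is_leaf(self) -> bool:
        return not self.children


class PhyloTree:
    """A rooted, leaf-labeled tree with optional branch lengths and supports.

    Invariants enforced at construction: unique non-empty leaf labels, a
    connected acyclic parent/child structure, branch lengths >= 0 and supports
    in [0, 100] where present.  ``unit`` is a free-form tag recording what the
    branch lengths mean (e.g. ``"subs/site"`` or ``"coalescent"``).
    """

    def __init__(self, root: Node, unit: str | None = None, validate: bool = True):
        self.root = root
        self.unit = unit
        self._fix_parents()
        if validate:
            self._validate()

    def _fix_parents(self) -> None:
        self.root.parent = None
        stack = [self.root]
        while stack:
            nd = stack.pop()
            for c in nd.children:
                c.parent = nd
                stack.append(c)

    def _validate(self) -> None:
        seen: set[str] = set()
        for nd in self.postorder():
            if nd.is_leaf:
                if not nd.name:
                    raise TreeError("leaf with empty label")
                if nd.name in seen:
                    raise TreeError(f"duplicate leaf label: {nd.name!r}")
                seen.add(nd.name)
            if nd.length is not None and nd.length < 0:
                raise TreeError(f"negative branch length at {nd.name or '<internal>'}")
            if nd.support is not None and not (0 <= nd.support <= 100):
                raise TreeError(f"support outside [0, 100]: {nd.support}")

    # -- traversal ---------------------------------------------------------

    def postorder(self) -> Iterator[Node]:
        stack: list[tuple[Node, bool]] = [(self.root, False)]
        while stack:
            nd, expanded = stack.pop()
            if expanded or nd.is_leaf:
                yield nd
            else:
                stack.append((nd, True))
                for c in reversed(nd.children):
                    stack.append((c, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            nd = stack.pop()
            yield nd
            stack.extend(reversed(nd.children))

    def leaves(self) -> list[Node]:
        return [nd for nd in self.postorder() if nd.is_leaf]

    def leaf_names(self) -> frozenset[str]:
        return frozenset(nd.name for nd in self.leaves())  # type: ignore[misc]

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self.leaves())

    def internal_nodes(self, exclude_root: bool = False) -> list[Node]:
        out = [nd for nd in self.postorder() if not nd.is_leaf]
        if exclude_root:
            out = [nd for nd in out if nd is not self.root]
        return out

    def find_leaf(self, name: str) -> Node:
        for nd in self.leaves():
            if nd.name == name:
                return nd
        raise TreeError(f"taxon not in tree: {name!r}")

    def leaf_sets(self) -> dict[int, frozenset[str]]:
        """Map ``id(node) -> frozenset of descendant leaf names``."""
        out: dict[int, frozenset[str]] = {}
        for nd in self.postorder():
            if nd.is_leaf:
                out[id(nd)] = frozenset((nd.name,))  # type: ignore[arg-type]
            else:
                s: set[str] = set()
                for c in nd.children:
                    s |= out[id(c)]
                out[id(nd)] = frozenset(s)
        return out

    def copy(self) -> "PhyloTree":
        def _cp(nd: Node) -> Node:
            return Node(nd.name, nd.length, nd.support, [_cp(c) for c in nd.children])

        return PhyloTree(_cp(self.root), unit=self.unit, validate=False)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<PhyloTree {self.n_leaves} leaves>"


@dataclass(frozen=True)
class Bipartition:
    """An unrooted split, canonically the side *not* containing a reference taxon."""

    side: frozenset[str]
    taxa: frozenset[str]

    @staticmethod
    def make(side: Iterable[str], taxa: Iterable[str], ref: str | None = None) -> "Bipartition":
        taxa = frozenset(taxa)
        side = frozenset(side)
        if ref is None:
            ref = min(taxa)
        if ref in side:
            side = taxa - side
        if not side or side == taxa:
            raise TreeError("bipartition side must be a non-empty proper subset")
        return Bipartition(side, taxa)


# -- Newick I/O ------------------------------------------------------------


def _label_to_support(
    label: str | None,
    split: str | None = None,
    split_index: int = 0,
) -> tuple[float | None, str | None]:
    """Interpret an internal-node label as a support value if possible."""
    if label is None or label == "":
        return None, None
    part = label
    if split is not None and split in label:
        parts = label.split(split)
        if split_index < len(parts):
            part = parts[split_index]
    try:
        val = float(part)
    except ValueError:
        return None, label
    if 0 <= val <= 100:
        return val, None
    return None, label


def parse_newick(
    text: str,
    *,
    supports_from_labels: bool = True,
    support_split: str | None = None,
    support_split_index: int = 0,
    unit: str | None = None,
) -> PhyloTree:
    """Parse one Newick statement into a :class:`PhyloTree`.

    Internal-node labels parsing as numbers in [0, 100] become node supports
    unless ``supports_from_labels`` is disabled.  Compound labels such as
    ``"95/87"`` can be split with ``support_split="/"`` and
    ``support_split_index`` selecting which part is the support.
    """
    if not text.strip():
        raise NewickParseError("empty Newick string")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several DataError subclasses
        raise NewickParseError(f"malformed Newick: {exc}") from exc

    def _convert(dnode: dendropy.Node) -> Node:
        children = [_convert(c) for c in dnode.child_nodes()]
        length = dnode.edge.length
        if children:
            support, name = (None, dnode.label)
            if supports_from_labels:
                support, name = _label_to_support(
                    dnode.label, support_split, support_split_index
                )
            return Node(name=name, length=length, support=support, children=children)
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        return Node(name=label, length=length)

    return PhyloTree(_convert(dtree.seed_node), unit=unit)


_NEEDS_QUOTE = re.compile(r"[\s()\[\]{}:;,'\"]")


def _fmt_label(name: str) -> str:
    if _NEEDS_QUOTE.search(name):
        return "'" + name.replace("'", "''") + "'"
    return name


def write_newick(tree: PhyloTree, *, include_supports: bool = True) -> str:
    """Serialize to Newick; branch lengths with up to 10 significant digits."""
    buf = io.StringIO()

    def _write(nd: Node) -> None:
        if nd.is_leaf:
            buf.write(_fmt_label(nd.name or ""))
        else:
            buf.write("(")
            for i, c in enumerate(nd.children):
                if i:
                    buf.write(",")
                _write(c)
            buf.write(")")
            if include_supports and nd.support is not None and nd is not tree.root:
                buf.write(f"{nd.support:.10g}")
            elif nd.name:
                buf.write(_fmt_label(nd.name))
        if nd.length is not None and nd is not tree.root:
            buf.write(f":{nd.length:.10g}")

    _write(tree.root)
    buf.write(";")
    return buf.getvalue()


_NAMED_LINE = re.compile(r"^\s*([^\s:;(),]+)\s*:\s*(\(.*)$")


def read_tree_file(path, **kw) -> list[tuple[str, PhyloTree]]:
    """Read one tree per line; lines may carry a ``name: (...)...;`` prefix.

    Bare lines are named ``gene<line number>``.
    """
    out: list[tuple[str, PhyloTree]] = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            m = _NAMED_LINE.match(line)
            if m:
                name, nwk = m.group(1), m.group(2)
            else:
                name, nwk = f"gene{i + 1}", line
            out.append((name, parse_newick(nwk, **kw)))
    return out


def write_tree_file(path, trees: Sequence[tuple[str, PhyloTree]], **kw) -> None:
    with open(path, "w") as fh:
        for name, tree in trees:
            fh.write(f"{name}: {write_newick(tree, **kw)}\n")


# -- topology primitives ---------------------------------------------------


def bipartitions(tree: PhyloTree, ref: str | None = None) -> set[Bipartition]:
    """Non-trivial splits of the unrooted topology, one per internal edge.

    Trees with fewer than four leaves have no non-trivial split and yield the
    empty set.  The canonical side of each split is the one not containing the
    reference taxon (default: lexicographically smallest leaf).
    """
    taxa = tree.leaf_names()
    n = len(taxa)
    if n < 4:
        return set()
    if ref is None:
        ref = min(taxa)
    sets = tree.leaf_sets()
    out: set[Bipartition] = set()
    for nd in tree.postorder():
        if nd is tree.root:
            continue
        s = sets[id(nd)]
        if 2 <= len(s) <= n - 2:
            out.add(Bipartition.make(s, taxa, ref))
    return out


def rf_distance(t1: PhyloTree, t2: PhyloTree) -> int:
    """Robinson-Foulds distance: size of the symmetric difference of split sets."""
    n1, n2 = t1.leaf_names(), t2.leaf_names()
    if n1 != n2:
        raise LeafSetMismatchError(n1 - n2, n2 - n1)
    return len(bipartitions(t1) ^ bipartitions(t2))


def mrca(tree: PhyloTree, taxa: Iterable[str]) -> Node:
    """Most recent common ancestor of ``taxa`` in the rooted tree."""
    want = frozenset(taxa)
    if not want:
        raise TreeError("mrca of an empty taxon set")
    missing = want - tree.leaf_names()
    if missing:
        raise TreeError(f"taxa not in tree: {sorted(missing)}")
    sets = tree.leaf_sets()
    nd = tree.root
    while True:
        nxt = None
        for c in nd.children:
            if want <= sets[id(c)]:
                nxt = c
                break
        if nxt is None:
            return nd
        nd = nxt


def total_tree_length(tree: PhyloTree) -> float:
    """Sum of all branch lengths; errors if any non-root branch lacks a length."""
    missing = []
    total = 0.0
    for nd in tree.postorder():
        if nd is tree.root:
            continue
        if nd.length is None:
            missing.append(nd.name or "<internal>")
        else:
            total += nd.length
    if missing:
        raise TreeError(f"branch lengths missing at: {missing}")
    return total


def mean_support(tree: PhyloTree) -> float:
    """Mean support over internal nodes carrying one (root excluded)."""
    vals = [
        nd.support
        for nd in tree.internal_nodes(exclude_root=True)
        if nd.support is not None
    ]
    if not vals:
        raise TreeError("tree carries no internal-node supports")
    return float(sum(vals) / len(vals))


def topology_id(tree: PhyloTree) -> str:
    """Canonical string equal for two trees iff their unrooted topologies match."""
    taxa = ",".join(sorted(tree.leaf_names()))
    parts = sorted(
        "|".join(sorted(bp.side)) for bp in bipartitions(tree)
    )
    return taxa + "#" + ";".join(parts)


# -- rerooting and restriction --------------------------------------------


def reroot_on_leaf(tree: PhyloTree, leaf_name: str) -> PhyloTree:
    """Return a copy rooted on the edge above ``leaf_name``.

    The new root has two children: the named leaf (keeping its branch length)
    and the rest of the tree.  Supports travel with their unrooted edges.
    """
    t = tree.copy()
    leaf = t.find_leaf(leaf_name)
    p = leaf.parent
    if p is None:
        raise TreeError("cannot reroot a single-leaf tree")
    if p is t.root and len(t.root.children) == 2:
        return PhyloTree(t.root, unit=t.unit)

    path = []
    cur: Node | None = p
    while cur is not None:
        path.append(cur)
        cur = cur.parent
    orig_len = [nd.length for nd in path]
    orig_sup = [nd.support for nd in path]

    p.children.remove(leaf)
    new_root = Node(children=[leaf, p])
    for i in range(len(path) - 1):
        parent = path[i + 1]
        parent.children.remove(path[i])
        path[i].children.append(parent)
        parent.length = orig_len[i]
        parent.support = orig_sup[i]
    p.length = 0.0
    p.support = None

    old_root = path[-1]
    if len(old_root.children) == 1 and old_root is not p:
        # the old root lay on a now-ordinary edge: splice it out
        only = old_root.children[0]
        carrier = path[-2]
        carrier.children[carrier.children.index(old_root)] = only
        if old_root.length is not None or only.length is not None:
            only.length = (old_root.length or 0.0) + (only.length or 0.0)
        if only.support is None:
            only.support = old_root.support
    return PhyloTree(new_root, unit=t.unit)


def restrict(tree: PhyloTree, taxa: Iterable[str]) -> PhyloTree:
    """Induced rooted subtree on ``taxa``; unifurcations are spliced out with
    branch lengths summed."""
    keep = frozenset(taxa)
    missing = keep - tree.leaf_names()
    if missing:
        raise TreeError(f"taxa not in tree: {sorted(missing)}")

    def _r(nd: Node) -> Node | None:
        if nd.is_leaf:
            if nd.name in keep:
                return Node(nd.name, nd.length)
            return None
        kids = [k for k in (_r(c) for c in nd.children) if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            k = kids[0]
            if nd.length is not None or k.length is not None:
                k.length = (nd.length or 0.0) + (k.length or 0.0)
            return k
        return Node(nd.name, nd.length, nd.support, kids)

    root = _r(tree.root)
    if root is None:
        raise TreeError("restriction to an empty taxon set")
    root.length = None
    return PhyloTree(root, unit=tree.unit)
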