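"""Unrooted phylogenetic trees as split systems.

A tree on a fixed leaf set is stored as a map from internal *splits*
(bipartitions of the leaves) to branch lengths, plus one pendant branch
length per leaf.  This is the natural coordinate system of
Billera-Holmes-Vogtmann (BHV) tree space, where every binary topology
owns one Euclidean orthant whose axes are the internal branch lengths.

Trees are unrooted throughout: a rooted Newick input is unrooted on
parse (the root is suppressed; a degree-2 root's two incident branch
lengths are summed into one edge).  Rooting is presentational only.
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence


class NewickError(ValueError):
    """Raised for malformed Newick text or invalid tree structure."""


class LeafSetMismatchError(ValueError):
    """Raised when an operation requires identical leaf sets."""


@dataclass(frozen=True)
class Split:
    """A bipartition of the leaf set, canonically oriented.

    ``side`` is the part that does *not* contain the lexicographically
    smallest leaf label, so each bipartition has a unique encoding.
    Pendant (external) splits have ``|side| == 1``; internal splits have
    ``2 <= |side| <= n - 2``.
    """

    side: frozenset
    full_leafset_size: int

    def __post_init__(self):
        n = self.full_leafset_size
        if not (1 <= len(self.side) <= n - 1):
            raise ValueError(f"split side size {len(self.side)} invalid for {n} leaves")

    @property
    def is_pendant(self) -> bool:
        return len(self.side) == 1

    def sort_key(self) -> tuple:
        return tuple(sorted(self.side))

    def __repr__(self):  # pragma: no cover - debugging aid
        return "Split({%s})" % ",".join(sorted(map(str, self.side)))


def make_split(side: Iterable[str], leaf_labels: Sequence[str]) -> Split:
    """Build a canonical :class:`Split` from either side of a bipartition."""
    labels = frozenset(leaf_labels)
    side = frozenset(side)
    if not side <= labels:
        raise ValueError(f"split side {sorted(side)} not a subset of the leaf set")
    smallest = min(labels)
    if smallest in side:
        side = labels - side
    return Split(side, len(labels))


def splits_compatible(s1: Split, s2: Split) -> bool:
    """True iff the two bipartitions can coexist in one tree.

    Two splits are compatible iff at least one of the four pairwise
    intersections of their sides is empty.  With canonical orientation
    both co-sides contain the smallest label, so this reduces to:
    disjoint sides, or one side nested in the other.
    """
    if s1.full_leafset_size != s2.full_leafset_size:
        raise LeafSetMismatchError("splits are over different leaf sets")
    a, b = s1.side, s2.side
    return a.isdisjoint(b) or a <= b or b <= a


@dataclass
class PhyloTree:
    """Leaf-labeled unrooted tree with non-negative branch lengths."""

    leaf_labels: tuple
    internal_edges: dict  # Split -> float
    external_edges: dict  # leaf label -> float
    name: str = ""

    def __post_init__(self):
        self.leaf_labels = tuple(sorted(self.leaf_labels))
        n = len(self.leaf_labels)
        if set(self.external_edges) != set(self.leaf_labels):
            raise ValueError("external edges must cover every leaf exactly once")
        for s in self.internal_edges:
            if s.full_leafset_size != n or not (2 <= len(s.side) <= n - 2):
                raise ValueError(f"invalid internal split {s!r} for {n} leaves")
        if len(self.internal_edges) > n - 3:
            raise ValueError("too many internal splits for a tree")
        for length in list(self.internal_edges.values()) + list(self.external_edges.values()):
            if length < 0:
                raise ValueError("negative branch length")
        splits = list(self.internal_edges)
        for i, s in enumerate(splits):
            for t in splits[i + 1:]:
                if not splits_compatible(s, t):
                    raise ValueError(f"incompatible internal splits {s!r}, {t!r}")

    # -- basic properties -------------------------------------------------

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    @property
    def m(self) -> int:
        """Internal-edge count of a fully resolved tree on this leaf set."""
        return self.n_leaves - 3

    def total_length(self) -> float:
        return sum(self.internal_edges.values()) + sum(self.external_edges.values())

    def sum_squared_lengths(self) -> float:
        """Sum of squared branch lengths over ALL branches."""
        return (sum(v * v for v in self.internal_edges.values())
                + sum(v * v for v in self.external_edges.values()))

    def copy(self, name: str | None = None) -> "PhyloTree":
        return PhyloTree(self.leaf_labels, dict(self.internal_edges),
                         dict(self.external_edges), self.name if name is None else name)

    def collapsed(self, tol: float = 0.0) -> "PhyloTree":
        """Copy with internal edges of length <= tol removed (contracted)."""
        kept = {s: v for s, v in self.internal_edges.items() if v > tol}
        return PhyloTree(self.leaf_labels, kept, dict(self.external_edges), self.name)

    def topology(self) -> frozenset:
        return frozenset(self.internal_edges)

    def __eq__(self, other):
        if not isinstance(other, PhyloTree):
            return NotImplemented
        return (self.leaf_labels == other.leaf_labels
                and self.internal_edges == other.internal_edges
                and self.external_edges == other.external_edges)


def is_binary(tree: PhyloTree, tol: float = 0.0) -> bool:
    """A tree is binary iff fully resolved with all internal lengths > tol."""
    if len(tree.internal_edges) != tree.n_leaves - 3:
        return False
    return all(v > tol for v in tree.internal_edges.values())


# ---------------------------------------------------------------------------
# Newick parsing
# ---------------------------------------------------------------------------

_TOKEN = re.compile(r"""
    \s*(
        [(),;]
      | :[^,():;\s]+
      | '(?:[^']|'')*'
      | [^,():;\s]+
    )""", re.VERBOSE)


def _tokenize(text: str):
    text = re.sub(r"\[[^\]]*\]", "", text)  # strip comments
    pos = 0
    while pos < len(text):
        mm = _TOKEN.match(text, pos)
        if mm is None:
            rest = text[pos:].strip()
            if rest:
                raise NewickError(f"unparseable Newick near {rest[:20]!r}")
            return
        yield mm.group(1)
        pos = mm.end()


class _Node:
    __slots__ = ("children", "label", "length")

    def __init__(self):
        self.children: list[_Node] = []
        self.label: str | None = None
        self.length: float | None = None


def _parse_structure(text: str) -> _Node:
    tokens = list(_tokenize(text))
    if not tokens or tokens[-1] != ";":
        raise NewickError("Newick string must end with ';'")
    tokens = tokens[:-1]
    root = _Node()
    stack = [root]
    current = root
    expecting_new = True
    for tok in tokens:
        if tok == "(":
            node = _Node()
            current.children.append(node)
            stack.append(node)
            current = node
            expecting_new = True
        elif tok == ")":
            if len(stack) < 2:
                raise NewickError("unbalanced parentheses")
            stack.pop()
            current = stack[-1]
            expecting_new = False
        elif tok == ",":
            expecting_new = True
        elif tok.startswith(":"):
            # a length attaches to the most recently closed or named node
            if not current.children:
                raise NewickError("branch length with no node")
            try:
                current.children[-1].length = float(tok[1:])
            except ValueError as exc:
                raise NewickError(f"bad branch length {tok[1:]!r}") from exc
            expecting_new = False
        else:
            label = tok
            if label.startswith("'") and label.endswith("'"):
                label = label[1:-1].replace("''", "'")
            if expecting_new:
                node = _Node()
                node.label = label
                current.children.append(node)
                expecting_new = False
            else:
                # label after ')': internal node label (e.g. support) — ignored
                current.children[-1].label = label if not current.children[-1].children else current.children[-1].label
    if len(stack) != 1:
        raise NewickError("unbalanced parentheses")
    if len(root.children) == 1:
        return root.children[0]
    top = _Node()
    top.children = root.children
    return top


def parse_newick(text: str, missing_length: float | None = None,
                 clamp_negative: bool = False, name: str = "") -> PhyloTree:
    """Parse one Newick string into a canonical unrooted :class:`PhyloTree`.

    Parameters
    ----------
    text : str
        Newick with leaf labels; branch lengths required on every edge
        unless ``missing_length`` supplies a default.
    missing_length : float, optional
        If given, edges without a length get this value; otherwise a
        missing length is an error.
    clamp_negative : bool
        Replace negative branch lengths by 0 (with a warning) instead of
        raising.
    name : str
        Name recorded on the returned tree (e.g. the gene identifier).
    """
    root = _parse_structure(text)
    # contract degree-2 internal nodes below the root (lengths summed)
    root = _merge_degree2(root)
    # a root with a single child is itself degree-2 relative to the
    # unrooted tree; drop it (its dangling edge length has nowhere to go)
    while len(root.children) == 1 and root.children[0].children:
        root = root.children[0]
        root.length = None
        root = _merge_degree2(root)
    root.length = None

    # unroot: a degree-2 root is suppressed, summing its two edges
    if len(root.children) == 2:
        a, b = root.children
        merged_len = _edge_len(a, missing_length) + _edge_len(b, missing_length)
        if a.children and not b.children:
            a, b = b, a
        if not a.children:  # a is a leaf: hang it off b
            if not b.children:
                raise NewickError("trees with fewer than 3 leaves are not supported")
            a.length = merged_len
            b.children.append(a)
            root = b
            root.length = None
        else:
            a.length = None
            a.children.append(b)
            b.length = merged_len
            root = a

    leaves: list[str] = []
    _collect_leaves(root, leaves)
    if len(leaves) != len(set(leaves)):
        dup = sorted({x for x in leaves if leaves.count(x) > 1})
        raise NewickError(f"duplicate leaf labels: {dup}")
    if len(leaves) < 3:
        raise NewickError("trees with fewer than 3 leaves are not supported")
    leaf_labels = tuple(sorted(leaves))

    internal: dict[Split, float] = {}
    external: dict[str, float] = {}

    def getlen(node: _Node) -> float:
        length = node.length
        if length is None:
            if missing_length is None:
                raise NewickError(f"missing branch length at node {node.label!r}")
            length = missing_length
        if length < 0:
            if clamp_negative:
                warnings.warn(f"negative branch length {length} clamped to 0 "
                              f"in tree {name!r}", stacklevel=3)
                length = 0.0
            else:
                raise NewickError(f"negative branch length {length}")
        return float(length)

    def walk(node: _Node) -> set:
        if not node.children:
            external[node.label] = external.get(node.label, 0.0) + getlen(node)
            return {node.label}
        below = set()
        for child in node.children:
            sub = walk(child)
            if child.children:  # internal edge
                split = make_split(sub, leaf_labels)
                internal[split] = internal.get(split, 0.0) + getlen(child)
            below |= sub
        return below

    walk(root)
    return PhyloTree(leaf_labels, internal, external, name=name)


def _merge_degree2(node: _Node) -> _Node:
    new_children = []
    for child in node.children:
        child = _merge_degree2(child)
        while len(child.children) == 1:
            grand = child.children[0]
            grand.length = (grand.length if grand.length is not None else 0.0) + \
                           (child.length if child.length is not None else 0.0)
            child = grand
        new_children.append(child)
    node.children = new_children
    return node


def _edge_len(node: _Node, missing: float | None) -> float:
    if node.length is None:
        if missing is None:
            raise NewickError("missing branch length at root edge")
        return missing
    return float(node.length)


def _collect_leaves(node: _Node, out: list):
    if not node.children:
        if node.label is None:
            raise NewickError("leaf without a label")
        out.append(node.label)
    for child in node.children:
        _collect_leaves(child, out)


# ---------------------------------------------------------------------------
# Newick writing
# ---------------------------------------------------------------------------

def _quote(label: str) -> str:
    if re.search(r"[\s(),:;\[\]']", label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: PhyloTree, precision: int = 17) -> str:
    """Serialize as an unrooted Newick string (trifurcating base node).

    ``parse_newick(write_newick(t))`` preserves the split set and all
    branch lengths.
    """
    fmt = f"%.{precision}g"
    # nest splits: children of a split are the maximal splits/leaves
    # strictly inside its side; root children are the maximal items
    sides = sorted(tree.internal_edges, key=lambda s: (len(s.side), s.sort_key()))

    def node_text(item) -> str:
        if isinstance(item, str):
            return f"{_quote(item)}:{fmt % tree.external_edges[item]}"
        children = _direct_children(item.side, sides, tree)
        inner = ",".join(node_text(c) for c in children)
        return f"({inner}):{fmt % tree.internal_edges[item]}"

    root_children = _direct_children(frozenset(tree.leaf_labels), sides, tree,
                                     at_root=True)
    return "(" + ",".join(node_text(c) for c in root_children) + ");"


def _direct_children(region: frozenset, sides: list, tree: PhyloTree,
                     at_root: bool = False):
    """Maximal splits/leaves properly nested in ``region``."""
    maximal = []
    covered = set()
    for s in sorted(sides, key=lambda s: -len(s.side)):
        if (s.side < region or (at_root and s.side <= region)) and \
                not any(s.side <= m.side for m in maximal):
            maximal.append(s)
            covered |= s.side
    items: list = sorted(maximal, key=lambda s: s.sort_key())
    items += [leaf for leaf in tree.leaf_labels
              if leaf in region and leaf not in covered]
    # put leaves and splits in deterministic label order
    items.sort(key=lambda it: (it,) if isinstance(it, str) else it.sort_key())
    return items


# ---------------------------------------------------------------------------
# Collections and files
# ---------------------------------------------------------------------------

def read_trees(path) -> list[PhyloTree]:
    """Read trees from a Newick file (or directory of ``*.nwk`` files).

    A multi-tree file is split on ';'.  Tree names come from file names
    (one tree per file) or ``<stem>_<i>`` (multi-tree file).
    """
    path = Path(path)
    trees = []
    if path.is_dir():
        for f in sorted(path.glob("*.nwk")) + sorted(path.glob("*.tre")) + \
                sorted(path.glob("*.newick")):
            trees.extend(read_trees(f))
        if not trees:
            raise FileNotFoundError(f"no Newick files found in {path}")
        return trees
    text = path.read_text()
    chunks = [c.strip() for c in text.split(";") if c.strip()]
    for i, chunk in enumerate(chunks):
        tname = path.stem if len(chunks) == 1 else f"{path.stem}_{i}"
        trees.append(parse_newick(chunk + ";", name=tname))
    return trees


def write_trees(trees: Iterable[PhyloTree], path) -> None:
    path = Path(path)
    path.write_text("\n".join(write_newick(t) for t in trees) + "\n")


def validate_collection(trees: Sequence[PhyloTree]) -> list[PhyloTree]:
    """Assert all trees share one leaf set; return them with shared order.

    BHV geodesics and log maps are only defined for trees on identical
    leaf sets, so every downstream entry point calls this first.
    """
    if not trees:
        raise ValueError("empty tree collection")
    ref = set(trees[0].leaf_labels)
    for t in trees[1:]:
        cur = set(t.leaf_labels)
        if cur != ref:
            diff = sorted(ref.symmetric_difference(cur))
            raise LeafSetMismatchError(
                f"trees {trees[0].name!r} and {t.name!r} have different leaf sets; "
                f"symmetric difference: {diff}")
    return list(trees)


def read_metadata(path) -> dict:
    """Read a gene-metadata CSV with required column ``gene``.

    Returns a dict gene -> category (missing category column maps all
    genes to ``""``).
    """
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "gene" not in reader.fieldnames:
            raise ValueError("metadata CSV must have a 'gene' column")
        has_cat = "category" in reader.fieldnames
        return {row["gene"]: (row["category"] if has_cat else "")
                for row in reader}
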