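"""Tree data model, Newick I/O, placement editing and nodal-distance machinery.

The placement problem never modifies the reference topology except by
attaching one or two query tips, so the tree model here is deliberately
small: rooted node/child structure with optional branch lengths and node
ages, plus an unrooted view used for bipartition-stable edge identifiers
and node-path distances.

Edges are identified by the *unrooted bipartition* they induce, encoded as
the frozenset of tip labels on the side that does not contain the
lexicographically smallest tip of the tree.  This key is stable across
re-rooting, I/O round-trips and child reordering, and automatically
collapses the two rooted child edges of the root into the single unrooted
edge they represent.
"""

from __future__ import annotations

import io
import itertools
from collections import deque
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import dendropy

__all__ = [
    "TreeError",
    "NewickParseError",
    "Node",
    "ReferenceTree",
    "Backbone",
    "Placement",
    "parse_newick",
    "write_newick",
    "prune_query",
    "apply_placement",
    "enumerate_placements",
    "edge_nodal_distance",
    "edge_distances_from",
    "max_edge_distance",
    "scaled_error",
]


class TreeError(ValueError):
    """Raised on invalid tree structure or invalid tree operations."""


class NewickParseError(TreeError):
    """Raised when Newick text cannot be parsed."""


class Node:
    """A node of a rooted tree.

    Attributes
    ----------
    label : str or None
        Tip label (internal nodes may also carry labels).
    length : float or None
        Length of the edge subtending this node (None for the root or for
        cladograms without branch lengths).
    age : float or None
        Node age in Ma, with the present at 0.0.  Only meaningful for
        dated (ultrametric) trees.
    """

    __slots__ = ("label", "length", "age", "children", "parent")

    def __init__(self, label=None, length=None, age=None, children=None):
        self.label = label
        self.length = length
        self.age = age
        self.children: list[Node] = []
        self.parent: Optional[Node] = None
        for child in children or ():
            self.add_child(child)

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def remove_child(self, child: "Node") -> None:
        self.children.remove(child)
        child.parent = None

    @property
    def is_tip(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["Node"]:
        stack, out = [self], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"<Node {self.label or '*'}>"


class ReferenceTree:
    """A rooted tree with optional branch lengths and node ages."""

    def __init__(self, root: Node, rooted: bool = True):
        self.root = root
        self.rooted = rooted
        self._validate()

    # -- structure ---------------------------------------------------------

    def _validate(self) -> None:
        labels = [t.label for t in self.tips()]
        if any(lbl in (None, "") for lbl in labels):
            raise TreeError("every tip must carry a non-empty label")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeError(f"duplicate tip labels: {dupes}")

    def tips(self) -> list[Node]:
        return [n for n in self.root.postorder() if n.is_tip]

    @property
    def tip_labels(self) -> list[str]:
        return [t.label for t in self.tips()]

    def n_tips(self) -> int:
        return len(self.tips())

    def postorder(self) -> Iterator[Node]:
        return self.root.postorder()

    def find_tip(self, label: str) -> Node:
        for tip in self.tips():
            if tip.label == label:
                return tip
        raise KeyError(f"tip {label!r} not in tree")

    def copy(self) -> "ReferenceTree":
        def clone(node: Node) -> Node:
            new = Node(node.label, node.length, node.age)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return ReferenceTree(clone(self.root), rooted=self.rooted)

    # -- edges and bipartition keys ---------------------------------------

    def _anchor(self) -> str:
        return min(self.tip_labels)

    def _clade_sets(self) -> dict[int, frozenset[str]]:
        sets: dict[int, frozenset[str]] = {}
        for node in self.root.postorder():
            if node.is_tip:
                sets[id(node)] = frozenset((node.label,))
            else:
                acc: set[str] = set()
                for child in node.children:
                    acc |= sets[id(child)]
                sets[id(node)] = frozenset(acc)
        return sets

    def edge_key(self, node: Node) -> frozenset[str]:
        """Unrooted bipartition key of the edge subtending ``node``."""
        if node is self.root:
            raise TreeError("the root subtends no edge")
        sets = self._clade_sets()
        return self._key_from_clade(sets[id(node)], sets[id(self.root)])

    def _key_from_clade(self, clade, all_tips) -> frozenset[str]:
        anchor = min(all_tips)
        return frozenset(all_tips - clade) if anchor in clade else clade

    def edges(self, unrooted: bool = True) -> list[tuple[frozenset[str], Node]]:
        """(key, child node) pairs for every edge.

        With ``unrooted=True`` the two child edges of a bifurcating root
        (which form a single unrooted edge) are reported once.
        """
        sets = self._clade_sets()
        all_tips = sets[id(self.root)]
        seen: set[frozenset[str]] = set()
        out = []
        for node in self.root.postorder():
            if node is self.root:
                continue
            key = self._key_from_clade(sets[id(node)], all_tips)
            if unrooted and key in seen:
                continue
            seen.add(key)
            out.append((key, node))
        return out

    def find_edge(self, key: frozenset[str]) -> Node:
        for k, node in self.edges(unrooted=True):
            if k == key:
                return node
        raise KeyError(f"edge {set(key)!r} not in tree")

    def bipartitions(self) -> set[frozenset[str]]:
        """The unrooted bipartition set (topology fingerprint)."""
        return {k for k, _ in self.edges(unrooted=True)}

    # -- ages / ultrametricity --------------------------------------------

    def set_ages_from_lengths(self, tol: float = 1e-6) -> None:
        """Derive node ages (Ma before present) from branch lengths.

        Requires an ultrametric tree: all root-to-tip path lengths equal
        within ``tol``.
        """
        depths = {id(self.root): 0.0}
        for node in reversed(list(self.root.postorder())):  # parents first
            if node is self.root:
                continue
            if node.length is None:
                raise TreeError("cannot derive ages: missing branch length")
            depths[id(node)] = depths[id(node.parent)] + node.length
        tip_depths = [depths[id(t)] for t in self.tips()]
        height = max(tip_depths)
        if max(tip_depths) - min(tip_depths) > tol * max(height, 1.0):
            raise TreeError("tree is not ultrametric; cannot assign ages")
        for node in self.root.postorder():
            node.age = height - depths[id(node)]
        for tip in self.tips():
            tip.age = 0.0

    def set_lengths_from_ages(self) -> None:
        for node in self.root.postorder():
            if node is self.root:
                node.length = None
            else:
                node.length = node.parent.age - node.age
                if node.length < 0:
                    raise TreeError(
                        f"negative duration on edge above {node.label or 'internal node'}"
                    )

    def is_ultrametric(self, tol: float = 1e-6) -> bool:
        try:
            probe = self.copy()
            probe.set_ages_from_lengths(tol=tol)
        except TreeError:
            return False
        return True

    def is_binary(self) -> bool:
        return all(
            len(n.children) == 2 for n in self.root.postorder() if not n.is_tip
        )

    def total_length(self) -> float:
        return sum(n.length or 0.0 for n in self.root.postorder() if n is not self.root)

    def __repr__(self):  # pragma: no cover
        return f"<ReferenceTree {self.n_tips()} tips>"


# ---------------------------------------------------------------------------
# Newick I/O (via dendropy)
# ---------------------------------------------------------------------------


def parse_newick(text: str) -> ReferenceTree:
    """Parse a Newick string into a :class:`ReferenceTree`.

    Branch lengths are optional; scientific notation is accepted.  Raises
    :class:`NewickParseError` for malformed input (with the position
    reported by the underlying parser) and :class:`TreeError` for duplicate
    tip labels.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickParseError(f"malformed Newick: {exc}") from exc

    def convert(dnode) -> Node:
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        node = Node(label=label, length=dnode.edge.length)
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    root = convert(dtree.seed_node)
    if not root.children:
        raise NewickParseError("Newick describes no tree")
    return ReferenceTree(root)


def _newick_node(node: Node, precision: int) -> str:
    if node.is_tip:
        core = node.label
    else:
        inner = ",".join(
            _newick_node(c, precision)
            for c in sorted(node.children, key=_sort_key)
        )
        core = f"({inner})" + (node.label or "")
    if node.length is not None:
        core += f":{node.length:.{precision}g}"
    return core


def _sort_key(node: Node) -> str:
    return min(t.label for t in node.postorder() if t.is_tip)


def write_newick(tree: ReferenceTree, precision: int = 17) -> str:
    """Serialize to Newick with children in canonical (label-sorted) order."""
    return _newick_node(tree.root, precision) + ";"


# ---------------------------------------------------------------------------
# Backbones and placements
# ---------------------------------------------------------------------------


@dataclass
class Backbone:
    """A reference tree with one taxon pruned and the true edge remembered."""

    tree: ReferenceTree
    true_edge: frozenset[str]
    pruned_taxon: str

    def edges(self):
        return self.tree.edges(unrooted=True)

    def edge_keys(self) -> list[frozenset[str]]:
        return [k for k, _ in self.edges()]


@dataclass(frozen=True)
class Placement:
    """Attachment of one or two queries to backbone edge(s).

    mode : 'single' | 'cherry' | 'sequential' | 'pair'
    edges : one edge key (single/cherry/sequential) or two distinct keys (pair)
    queries : 1 or 2 query labels
    order : for sequential placements, the label of the rootward query
    """

    mode: str
    edges: tuple[frozenset, ...]
    queries: tuple[str, ...]
    order: Optional[str] = None

    def __post_init__(self):
        n_e, n_q = len(self.edges), len(self.queries)
        ok = {
            "single": n_e == 1 and n_q == 1,
            "cherry": n_e == 1 and n_q == 2,
            "sequential": n_e == 1 and n_q == 2,
            "pair": n_e == 2 and n_q == 2 and self.edges[0] != self.edges[1],
        }
        if self.mode not in ok:
            raise TreeError(f"unknown placement mode {self.mode!r}")
        if not ok[self.mode]:
            raise TreeError(f"mode/arity mismatch for {self.mode} placement")
        if self.mode == "sequential" and self.order not in self.queries:
            raise TreeError("sequential placement needs order = one of the queries")


def _suppress_unary(tree: ReferenceTree) -> None:
    """Remove degree-2 internal nodes, summing the merged edge lengths."""
    changed = True
    while changed:
        changed = False
        for node in list(tree.root.postorder()):
            if node.is_tip or node is tree.root or len(node.children) != 1:
                continue
            child = node.children[0]
            if node.length is not None and child.length is not None:
                child.length = child.length + node.length
            elif node.length is not None:
                child.length = node.length
            parent = node.parent
            idx = parent.children.index(node)
            parent.children[idx] = child
            child.parent = parent
            changed = True
        if len(tree.root.children) == 1 and not tree.root.children[0].is_tip:
            # collapse a unary root onto its child
            tree.root = tree.root.children[0]
            tree.root.parent = None
            tree.root.length = None
            changed = True


def prune_query(tree: ReferenceTree, taxon: str) -> Backbone:
    """Remove a tip and return the backbone with the true edge recorded.

    The pruned tip's attachment node becomes degree-2 and is suppressed;
    the two incident edges merge (lengths summed) into the true edge.
    """
    if tree.n_tips() < 4:
        raise TreeError("pruning requires a tree with at least 4 tips")
    work = tree.copy()
    tip = work.find_tip(taxon)
    parent = tip.parent
    if parent is None:
        raise TreeError("cannot prune the root")
    parent.remove_child(tip)
    _suppress_unary(work)
    backbone_tree = ReferenceTree(work.root, rooted=work.rooted)

    # the true edge is the backbone edge whose insertion recovers the
    # original topology: the edge formed by the former siblings of the tip
    remaining = frozenset(backbone_tree.tip_labels)
    sets = tree._clade_sets()
    tip_node = tree.find_tip(taxon)
    sib_clade = sets[id(tip_node.parent)] - {taxon}
    true_edge = backbone_tree._key_from_clade(frozenset(sib_clade), remaining)
    if true_edge not in backbone_tree.bipartitions():
        # the tip was adjacent to the root: the merged edge is the
        # backbone's (unrooted) root edge
        true_edge = backbone_tree.edge_key(backbone_tree.root.children[0])
    return Backbone(tree=backbone_tree, true_edge=true_edge, pruned_taxon=taxon)


def _split_edge(tree: ReferenceTree, host: Node, frac: float = 0.5) -> Node:
    """Insert a new degree-2 node on the edge above ``host``; return it."""
    parent = host.parent
    mid = Node()
    if host.length is not None:
        mid.length = host.length * (1.0 - frac)
        host.length = host.length * frac
    if host.age is not None and parent.age is not None:
        mid.age = host.age + (parent.age - host.age) * frac
    idx = parent.children.index(host)
    parent.children[idx] = mid
    mid.parent = parent
    mid.add_child(host)
    return mid


def apply_placement(
    backbone: Backbone | ReferenceTree,
    placement: Placement,
    pendant_length: Optional[float] = None,
) -> ReferenceTree:
    """Attach the placement's queries and return a new resolved tree.

    The input backbone is left untouched.  Cherry placements create a new
    internal node subtending both queries on the target edge; sequential
    placements split the target edge twice with the rootward query (given
    by ``placement.order``) attached closer to the root.
    """
    base = backbone.tree if isinstance(backbone, Backbone) else backbone
    tree = base.copy()

    def attach_single(edge_key, label):
        host = tree.find_edge(edge_key)
        mid = _split_edge(tree, host)
        mid.add_child(Node(label=label, length=pendant_length))
        return mid

    if placement.mode == "single":
        attach_single(placement.edges[0], placement.queries[0])
    elif placement.mode == "pair":
        # resolve both host nodes before editing: the first attachment
        # changes the tree's tip set and hence all bipartition keys
        hosts = [tree.find_edge(k) for k in placement.edges]
        for host, label in zip(hosts, placement.queries):
            mid = _split_edge(tree, host)
            mid.add_child(Node(label=label, length=pendant_length))
    elif placement.mode == "cherry":
        host = tree.find_edge(placement.edges[0])
        mid = _split_edge(tree, host)
        cherry = Node(length=pendant_length)
        for label in placement.queries:
            cherry.add_child(Node(label=label, length=pendant_length))
        mid.add_child(cherry)
    elif placement.mode == "sequential":
        rootward = placement.order
        tipward = next(q for q in placement.queries if q != rootward)
        host = tree.find_edge(placement.edges[0])
        lower = _split_edge(tree, host, frac=1.0 / 3.0)
        lower.add_child(Node(label=tipward, length=pendant_length))
        upper = _split_edge(tree, lower, frac=0.5)
        upper.add_child(Node(label=rootward, length=pendant_length))
    return ReferenceTree(tree.root, rooted=tree.rooted)


def enumerate_placements(
    backbone: Backbone,
    queries: Sequence[str],
    modes: Optional[Sequence[str]] = None,
) -> list[Placement]:
    """Enumerate every distinct placement of 1 or 2 queries.

    One query on a backbone with E edges admits E single placements; two
    queries admit E cherries, 2E sequentials and E(E-1) independent pairs.
    """
    keys = backbone.edge_keys()
    queries = tuple(queries)
    out: list[Placement] = []
    if len(queries) == 1:
        return [Placement("single", (k,), queries) for k in keys]
    if len(queries) != 2:
        raise TreeError("placements support one or two queries")
    modes = tuple(modes) if modes else ("cherry", "sequential", "pair")
    if "cherry" in modes:
        out += [Placement("cherry", (k,), queries) for k in keys]
    if "sequential" in modes:
        for k in keys:
            for rootward in queries:
                out.append(Placement("sequential", (k,), queries, order=rootward))
    if "pair" in modes:
        for k1, k2 in itertools.permutations(keys, 2):
            out.append(Placement("pair", (k1, k2), queries))
    return out


# ---------------------------------------------------------------------------
# Nodal distances on the unrooted backbone
# ---------------------------------------------------------------------------


def _unrooted_incidence(tree: ReferenceTree):
    """Map each unrooted edge key to its two endpoint node ids.

    A bifurcating root is suppressed (its two child edges are one unrooted
    edge joining the two children).
    """
    sets = tree._clade_sets()
    all_tips = sets[id(tree.root)]
    root = tree.root
    suppress_root = len(root.children) == 2
    incidence: dict[frozenset, tuple[int, int]] = {}
    for node in root.postorder():
        if node is root:
            continue
        key = tree._key_from_clade(sets[id(node)], all_tips)
        if node.parent is root and suppress_root:
            other = next(c for c in root.children if c is not node)
            endpoints = (id(node), id(other))
        else:
            endpoints = (id(node), id(node.parent))
        if key not in incidence:
            incidence[key] = endpoints
    return incidence


def edge_distances_from(
    backbone: Backbone | ReferenceTree, source: frozenset
) -> dict[frozenset, int]:
    """Nodal distance from ``source`` to every edge of the unrooted tree.

    The distance between two edges is the number of nodes on the path
    strictly between them: 0 for the same edge, 1 for edges sharing a node.
    """
    tree = backbone.tree if isinstance(backbone, Backbone) else backbone
    incidence = _unrooted_incidence(tree)
    if source not in incidence:
        raise KeyError(f"edge {set(source)!r} not in backbone")
    by_node: dict[int, list[frozenset]] = {}
    for key, (u, v) in incidence.items():
        by_node.setdefault(u, []).append(key)
        by_node.setdefault(v, []).append(key)
    dist = {source: 0}
    queue = deque([source])
    while queue:
        cur = queue.popleft()
        for node_id in incidence[cur]:
            for nxt in by_node[node_id]:
                if nxt not in dist:
                    dist[nxt] = dist[cur] + 1
                    queue.append(nxt)
    return dist


def edge_nodal_distance(
    backbone: Backbone | ReferenceTree, e1: frozenset, e2: frozenset
) -> int:
    """Number of nodes strictly between two edges of the unrooted backbone."""
    dist = edge_distances_from(backbone, e1)
    if e2 not in dist:
        raise KeyError(f"edge {set(e2)!r} not in backbone")
    return dist[e2]


def max_edge_distance(backbone: Backbone, true_edge: Optional[frozenset] = None) -> int:
    """Maximum nodal distance from the true edge to any backbone edge.

    This is the normalizer of the scaled placement error: the eccentricity
    of the attachment point minus one.
    """
    source = true_edge if true_edge is not None else backbone.true_edge
    return max(edge_distances_from(backbone, source).values())


def scaled_error(d: int, d_max: int) -> float:
    """Scaled placement error d / d_max, in [0, 1]."""
    if d_max < 1:
        raise TreeError("d_max must be at least 1")
    if not 0 <= d <= d_max:
        raise TreeError(f"nodal distance {d} outside [0, {d_max}]")
    return d / d_max
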