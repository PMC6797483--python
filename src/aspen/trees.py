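"""Rooted binary divergence topologies and the metrics defined over them.

A :class:`Topology` is a rooted, strictly binary tree over uniquely labelled
leaves.  Branch lengths may be carried along but are never consulted by any
topology-space operation.  The module also provides pruning of full gene
phylogenies down to the common ancestors of ortholog sets ("orthosets"),
producing the reduced paralog-divergence topologies that the rest of the
package compares, aggregates and reconstructs, and the modified
Robinson-Foulds distance RF* together with the derived accuracy and
precision statistics.

Path lengths, frequency distributions and search live in sibling modules;
this one owns the tree data model.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import dendropy

__all__ = [
    "Node",
    "Topology",
    "OrthosetMap",
    "MonophylyRecord",
    "PrunedTopology",
    "RFStarResult",
    "TreeError",
    "UnprunableError",
    "read_newick",
    "write_newick",
    "prune_to_ancestors",
    "rf_star",
    "accuracy",
    "precision",
    "enumerate_topologies",
]


class TreeError(ValueError):
    """Malformed tree, label or matrix input."""


class UnprunableError(TreeError):
    """Fewer than two orthosets could be reduced to ancestor leaves."""


class Node:
    """A node of a rooted topology.

    Leaves carry a ``label``; internal nodes have exactly two ``children``
    after canonicalization.  ``length`` is the length of the branch above
    the node (``None`` when absent).  ``spurious`` marks nodes whose
    existence depends on a non-monophyletic orthoset arrangement.
    """

    __slots__ = ("label", "children", "length", "spurious")

    def __init__(self, label=None, children=(), length=None, spurious=False):
        self.label = label
        self.children = list(children)
        self.length = length
        self.spurious = spurious

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Node({self.label!r})" if self.is_leaf else f"Node<{len(self.children)}>"


class Topology:
    """Rooted binary tree over uniquely labelled leaves."""

    def __init__(self, root: Node):
        self.root = root
        self._validate()

    # -- construction helpers ------------------------------------------------

    @classmethod
    def from_nested(cls, nested) -> "Topology":
        """Build from nested tuples/strings, e.g. ``((("A","B"),"C"))``."""

        def build(x) -> Node:
            if isinstance(x, str):
                return Node(label=x)
            return Node(children=[build(c) for c in x])

        return cls(build(nested))

    def _validate(self) -> None:
        labels = []
        for node in self.iter_nodes():
            if node.is_leaf:
                if not node.label:
                    raise TreeError("unlabelled leaf")
                labels.append(node.label)
            elif len(node.children) != 2:
                raise TreeError(
                    f"internal node with {len(node.children)} children; "
                    "topologies must be binary (see read_newick for rooting)"
                )
        if len(set(labels)) != len(labels):
            dup = sorted({x for x in labels if labels.count(x) > 1})
            raise TreeError(f"duplicate leaf labels: {dup}")
        if len(labels) < 2:
            raise TreeError("a topology needs at least two leaves")
        self._leaves = frozenset(labels)

    # -- basic queries -------------------------------------------------------

    @property
    def leaves(self) -> frozenset:
        return self._leaves

    @property
    def n_leaves(self) -> int:
        return len(self._leaves)

    def iter_nodes(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(node.children)

    def clades(self) -> frozenset:
        """Leaf sets under every internal node (the root included)."""
        out = set()

        def walk(node: Node) -> frozenset:
            if node.is_leaf:
                return frozenset((node.label,))
            below = frozenset().union(*(walk(c) for c in node.children))
            out.add(below)
            return below

        walk(self.root)
        return frozenset(out)

    def leaf_depths(self) -> dict:
        """Leaf label -> number of edges from the root."""
        depths = {}
        stack = [(self.root, 0)]
        while stack:
            node, d = stack.pop()
            if node.is_leaf:
                depths[node.label] = d
            else:
                stack.extend((c, d + 1) for c in node.children)
        return depths

    def leaf_paths(self) -> dict:
        """Leaf label -> tuple of internal nodes from the root down to it."""
        paths = {}
        stack = [(self.root, ())]
        while stack:
            node, above = stack.pop()
            if node.is_leaf:
                paths[node.label] = above
            else:
                stack.extend((c, above + (node,)) for c in node.children)
        return paths

    # -- identity ------------------------------------------------------------

    def __eq__(self, other):
        if not isinstance(other, Topology):
            return NotImplemented
        return self.leaves == other.leaves and self.clades() == other.clades()

    def __hash__(self):
        return hash(self.clades())

    def __repr__(self):
        return f"Topology({write_newick(self)!r})"

    def copy(self) -> "Topology":
        def dup(node: Node) -> Node:
            return Node(node.label, [dup(c) for c in node.children],
                        node.length, node.spurious)

        return Topology(dup(self.root))


def _min_leaf(node: Node) -> str:
    if node.is_leaf:
        return node.label
    return min(_min_leaf(c) for c in node.children)


def _sorted_children(node: Node) -> list:
    return sorted(node.children, key=_min_leaf)


def read_newick(text: str, rooting: str = "basal") -> Topology:
    """Parse a Newick string into a rooted binary :class:`Topology`.

    Unrooted inputs by convention carry a basal trifurcation.  Under the
    default ``rooting="basal"`` it is resolved deterministically by ordering
    the three root children by their smallest leaf label and joining the
    first two under a new (zero-length) node.  ``rooting="midpoint"``
    instead midpoint-roots the tree on its branch lengths — the appropriate
    choice for unrooted inference output, where the trifurcation's position
    is an artifact of the inference algorithm and, landing inside a clade,
    would falsely break its monophyly; it falls back to the basal
    convention when branch lengths are absent.  Every tree in an analysis
    must be rooted by one convention so all path lengths share one rooting.
    Any other polytomy is rejected.
    """
    if rooting not in ("basal", "midpoint"):
        raise TreeError(f"unknown rooting convention {rooting!r}")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise TreeError(f"Newick parse error: {exc}") from exc
    if rooting == "midpoint" and len(dtree.seed_node.child_nodes()) > 2:
        has_lengths = all(
            e.length is not None for e in dtree.edges() if e.head_node.parent_node
        )
        if has_lengths:
            try:
                dtree.reroot_at_midpoint(update_bipartitions=True)
            except Exception:
                pass  # degenerate lengths: keep basal convention

    def convert(dnode) -> Node:
        kids = dnode.child_nodes()
        length = dnode.edge.length
        if not kids:
            if dnode.taxon is None or not dnode.taxon.label:
                raise TreeError("Newick leaf without a label")
            return Node(label=str(dnode.taxon.label), length=length)
        return Node(children=[convert(c) for c in kids], length=length)

    root = convert(dtree.seed_node)
    if len(root.children) == 3:
        a, b, c = sorted(root.children, key=_min_leaf)
        root.children = [Node(children=[a, b], length=0.0), c]
    return Topology(root)


def write_newick(t: Topology, lengths: bool = False) -> str:
    """Serialize canonically: children ordered by smallest descendant leaf.

    Identical topologies therefore serialize to identical strings, which the
    search and deduplication machinery relies on.
    """

    def fmt(node: Node) -> str:
        if node.is_leaf:
            s = node.label
        else:
            s = "(" + ",".join(fmt(c) for c in _sorted_children(node)) + ")"
        if lengths and node.length is not None:
            s += f":{node.length:g}"
        return s

    return fmt(t.root) + ";"


# ---------------------------------------------------------------------------
# Orthoset maps and pruning
# ---------------------------------------------------------------------------


class OrthosetMap:
    """Assignment of every sequence leaf label to exactly one orthoset."""

    def __init__(self, assignment: Mapping[str, str]):
        if not assignment:
            raise TreeError("empty orthoset assignment")
        self.assignment = dict(assignment)
        self.orthosets = tuple(sorted(set(self.assignment.values())))
        if len(self.orthosets) < 2:
            raise TreeError("an orthoset map needs at least two orthosets")

    def members(self, orthoset: str) -> frozenset:
        return frozenset(k for k, v in self.assignment.items() if v == orthoset)

    def __len__(self):
        return len(self.assignment)

    @classmethod
    def read_tsv(cls, path_or_handle) -> "OrthosetMap":
        """Two-column TSV: sequence_id <tab> orthoset."""
        close = False
        fh = path_or_handle
        if not hasattr(fh, "read"):
            fh = open(fh)
            close = True
        try:
            assignment = {}
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise TreeError(f"bad orthoset TSV line: {line!r}")
                seq, oset = parts
                if seq in assignment:
                    raise TreeError(f"sequence {seq!r} assigned twice")
                assignment[seq] = oset
        finally:
            if close:
                fh.close()
        return cls(assignment)

    def write_tsv(self, path_or_handle) -> None:
        close = False
        fh = path_or_handle
        if not hasattr(fh, "write"):
            fh = open(fh, "w")
            close = True
        try:
            for seq in sorted(self.assignment):
                fh.write(f"{seq}\t{self.assignment[seq]}\n")
        finally:
            if close:
                fh.close()


@dataclass(frozen=True)
class MonophylyRecord:
    monophyletic: bool
    sampled: int


@dataclass
class PrunedTopology:
    """A divergence topology over orthoset-ancestor leaves.

    ``topology`` covers one leaf per monophyletic orthoset; orthosets whose
    sampled sequences were not monophyletic contribute no ancestor leaf and
    are listed in ``missing``.  Nodes at or below the most recent common
    ancestor of a non-monophyletic orthoset's sequences are flagged spurious
    on the pruned tree itself, and leaf pairs whose connecting path touches a
    spurious node are reported by :meth:`compromised_pairs` so ensemble
    aggregation can exclude them.
    """

    topology: Topology
    universe: tuple
    monophyly: dict = field(default_factory=dict)
    missing: frozenset = frozenset()

    def __post_init__(self):
        present = self.topology.leaves
        if not present <= set(self.universe):
            raise TreeError("ancestor leaves outside the orthoset universe")
        if present | set(self.missing) != set(self.universe):
            raise TreeError("ancestor leaves plus missing must cover the universe")

    @property
    def present(self) -> frozenset:
        return self.topology.leaves

    @classmethod
    def from_topology(cls, t: Topology) -> "PrunedTopology":
        """Wrap an already-reduced topology (e.g. a simulated truth)."""
        universe = tuple(sorted(t.leaves))
        mono = {o: MonophylyRecord(True, 1) for o in universe}
        return cls(t, universe, mono, frozenset())

    def spurious_leaves(self) -> frozenset:
        return frozenset(
            n.label for n in self.topology.iter_nodes() if n.is_leaf and n.spurious
        )

    def compromised_pairs(self) -> frozenset:
        """Unordered present-leaf pairs whose path crosses a spurious node."""
        bad_leaves = self.spurious_leaves()
        paths = self.topology.leaf_paths()
        out = set()
        for a, b in itertools.combinations(sorted(self.topology.leaves), 2):
            if a in bad_leaves or b in bad_leaves:
                out.add((a, b))
                continue
            pa, pb = paths[a], paths[b]
            shared = 0
            for x, y in zip(pa, pb):
                if x is y:
                    shared += 1
                else:
                    break
            on_path = list(pa[shared - 1 : shared]) + list(pa[shared:]) + list(pb[shared:])
            if any(n.spurious for n in on_path):
                out.add((a, b))
        return frozenset(out)

    def monophyly_report(self) -> dict:
        return {
            o: {"monophyletic": r.monophyletic, "sampled": r.sampled}
            for o, r in sorted(self.monophyly.items())
        }


def prune_to_ancestors(t: Topology, m: OrthosetMap) -> PrunedTopology:
    """Reduce a full phylogeny to the common ancestors of its orthosets.

    Each orthoset whose sampled leaves form a clade is collapsed to a single
    ancestor leaf named after the orthoset.  Non-monophyletic orthosets yield
    no ancestor leaf; every node at or below the MRCA of their sampled
    leaves is marked spurious (its existence depends on the offending
    arrangement).  Degree-two nodes arising from leaf removal are
    suppressed; a spurious suppressed node bequeaths its flag to the
    surviving child so compromised paths remain detectable.
    """
    unmapped = t.leaves - set(m.assignment)
    if unmapped:
        raise TreeError(f"leaves not in orthoset map: {sorted(unmapped)[:5]}")

    sampled = {}
    for leaf in t.leaves:
        sampled.setdefault(m.assignment[leaf], set())
        sampled[m.assignment[leaf]].add(leaf)

    clades = t.clades()
    mono, bad = {}, set()
    for oset, leaves in sampled.items():
        ok = len(leaves) == 1 or frozenset(leaves) in clades or leaves == t.leaves
        mono[oset] = MonophylyRecord(ok, len(leaves))
        if not ok:
            bad.add(oset)
    good = [o for o in sampled if o not in bad]
    if len(good) < 2:
        raise UnprunableError(
            f"only {len(good)} orthoset(s) monophyletic; cannot form a topology"
        )

    good_sets = {frozenset(sampled[o]): o for o in good}
    bad_leaf_sets = [frozenset(sampled[o]) for o in sorted(bad)]

    def reduce(node: Node, leafset: frozenset, in_spurious: bool) -> Node | None:
        # a node roots a spurious region if it is the MRCA (smallest clade
        # containing a bad orthoset's leaves) or sits below one
        is_mrca = any(
            s <= leafset and not any(s <= _leafset(c) for c in node.children)
            for s in bad_leaf_sets
        )
        spur = in_spurious or is_mrca
        if leafset in good_sets:
            return Node(label=good_sets[leafset], spurious=spur)
        if node.is_leaf:
            return None  # member of a non-monophyletic orthoset: drop
        kept = []
        for c in node.children:
            r = reduce(c, _leafset(c), spur)
            if r is not None:
                kept.append(r)
        if not kept:
            return None
        if len(kept) == 1:
            child = kept[0]
            child.spurious = child.spurious or spur
            return child
        return Node(children=kept, spurious=spur)

    cache: dict = {}

    def _leafset(node: Node) -> frozenset:
        key = id(node)
        if key not in cache:
            if node.is_leaf:
                cache[key] = frozenset((node.label,))
            else:
                cache[key] = frozenset().union(*(_leafset(c) for c in node.children))
        return cache[key]

    root = reduce(t.root, _leafset(t.root), False)
    pruned = Topology(root)
    universe = tuple(sorted(sampled))
    return PrunedTopology(pruned, universe, mono, frozenset(bad))


# ---------------------------------------------------------------------------
# RF*, accuracy, precision
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RFStarResult:
    """Components of the modified Robinson-Foulds comparison.

    ``x``/``y`` count non-trivial splits unique to each side (restricted to
    the ancestor leaves present in both topologies); ``z``/``zprime`` count
    ancestor leaves present in one topology but lost to non-monophyletic
    reconstruction in the other; ``n_ancestors`` is the number of designated
    ancestors N.  The normalized distance is (x+y+z+z')/(2N-6) and the
    comparison reduces to the classic RF metric when z = z' = 0.
    """

    x: int
    y: int
    z: int
    zprime: int
    n_ancestors: int
    distance: float

    @property
    def classic(self) -> bool:
        return self.z == 0 and self.zprime == 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "x": self.x, "y": self.y, "z": self.z, "zprime": self.zprime,
                "N": self.n_ancestors, "distance": self.distance,
                "classic": self.classic,
            }
        )


def _restricted_splits(t: Topology, common: frozenset) -> frozenset:
    """Non-trivial unrooted splits of ``common`` induced by ``t``'s clades."""
    splits = set()
    for clade in t.clades():
        if clade == t.leaves:
            continue
        a = frozenset(clade & common)
        b = frozenset(common - a)
        if len(a) >= 2 and len(b) >= 2:
            splits.add(frozenset((a, b)))
    return frozenset(splits)


def rf_star(a: PrunedTopology, b: PrunedTopology) -> RFStarResult:
    """Modified Robinson-Foulds distance between two pruned topologies."""
    if set(a.universe) != set(b.universe):
        raise TreeError("RF* requires a shared orthoset universe")
    n = len(a.universe)
    if n < 4:
        raise TreeError(f"RF* undefined for {n} ancestors (no informative splits)")
    common = frozenset(a.present & b.present)
    sa = _restricted_splits(a.topology, common)
    sb = _restricted_splits(b.topology, common)
    x = len(sa - sb)
    y = len(sb - sa)
    z = len(b.present - a.present)
    zprime = len(a.present - b.present)
    dist = (x + y + z + zprime) / (2 * n - 6)
    return RFStarResult(x, y, z, zprime, n, dist)


def accuracy(truth: PrunedTopology, recon: PrunedTopology) -> float:
    """1 - RF*(truth, reconstruction); 1 iff identical topologies."""
    return 1.0 - rf_star(truth, recon).distance


def precision(reference: PrunedTopology, ensemble: Sequence[PrunedTopology]) -> float:
    """1 minus the ensemble-mean RF* distance to the reference topology.

    The reference is typically the all-sequence reconstruction and the
    ensemble comes from high-fraction (about 90%) subsamples, making this an
    observable proxy for the (hidden) accuracy of the reference.
    """
    if not ensemble:
        raise TreeError("precision needs a non-empty ensemble")
    mean = sum(rf_star(reference, m).distance for m in ensemble) / len(ensemble)
    return 1.0 - mean


# ---------------------------------------------------------------------------
# Exhaustive enumeration (oracle-grade utility)
# ---------------------------------------------------------------------------


def enumerate_topologies(labels: Iterable[str]) -> Iterator[Topology]:
    """Yield every rooted binary topology over ``labels`` ((2n-3)!! trees).

    Built by sequential insertion of each new leaf onto every branch
    (including above the root) of every partial tree; used as the exhaustive
    scoring oracle against which the branch-and-bound search is verified.
    """
    labels = sorted(set(labels))
    if len(labels) < 2:
        raise TreeError("need at least two labels")

    def grow(nested_trees, label):
        out = []
        for tr in nested_trees:
            positions = _insertion_points(tr)
            for i in range(positions):
                out.append(_insert(tr, label, [i]))
        return out

    def _insertion_points(tr) -> int:
        if isinstance(tr, str):
            return 1
        return 1 + sum(_insertion_points(c) for c in tr)

    def _insert(tr, label, counter):
        # counter[0] counts down to the edge above the current subtree
        if counter[0] == 0:
            counter[0] -= 1
            return (tr, label)
        counter[0] -= 1
        if isinstance(tr, str):
            return tr
        return tuple(_insert(c, label, counter) for c in tr)

    partial = [(labels[0], labels[1])]
    for lab in labels[2:]:
        partial = grow(partial, lab)
    for nested in partial:
        yield Topology.from_nested(nested)
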