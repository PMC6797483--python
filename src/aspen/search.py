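"""Branch-and-bound enumeration of the N best-scoring topologies.

Topologies are assembled bottom-up from a forest of subtrees, one new
internal node at a time.  Joining two subtrees fixes the path length of
every leaf pair spanning them (the two heights plus one for the new node),
so each join's contribution to the log-frequency score is known exactly,
and an admissible projection — completed contributions plus the best
observed frequency for every still-unconnected pair — upper-bounds every
completion of a partial assembly.

The search is best-first on that projection.  Because the projection is
admissible and equals the true score once an assembly is complete,
completed topologies leave the priority queue in exact descending score
order; the run can stop as soon as the next queue head can no longer beat
the Nth completed score, with the guarantee that the N best constructible
topologies were found.  Duplicate construction states (the same forest
reached by different join orders) are pruned through canonical forest keys.
"""

from __future__ import annotations

import heapq
import itertools
import json
import math
import time
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .pathlengths import PathLengthDistribution, pair_key
from .scoring import log_frequency_score, projected_score
from .trees import Node, Topology, TreeError, write_newick

__all__ = [
    "Assembly",
    "SearchBudget",
    "ReconstructionResult",
    "branch_extensions",
    "reconstruct_n_best",
    "clade_frequencies",
    "write_annotated_newick",
]

_TOL = 1e-9  # slack on bound comparisons so float roundoff never drops a tie


@dataclass(frozen=True)
class _Component:
    """One subtree of an assembly's forest."""

    key: str  # canonical parenthesized form; doubles as identity
    min_leaf: str
    leaves: frozenset
    heights: dict  # leaf -> internal nodes up to and including this root
    node: Node

    @classmethod
    def leaf(cls, label: str) -> "_Component":
        return cls(label, label, frozenset((label,)), {label: 0}, Node(label=label))


class Assembly:
    """Partial reconstruction state for the branch-and-bound search.

    Holds a forest of disjoint subtrees over the ancestor universe, the
    lengths (and log-frequency contributions) of every path completed so
    far, and the running score.  Immutable in use: joins produce new
    assemblies sharing subtree structure.
    """

    __slots__ = ("universe", "components", "score", "floored", "completed", "key")

    def __init__(self, universe, components, score, floored, completed):
        self.universe = universe
        self.components = components
        self.score = score
        self.floored = floored
        self.completed = completed  # pair -> length
        self.key = frozenset(c.key for c in components)

    @classmethod
    def empty(cls, universe: Sequence[str]) -> "Assembly":
        universe = tuple(sorted(universe))
        comps = tuple(_Component.leaf(lab) for lab in universe)
        return cls(universe, comps, 0.0, False, {})

    @property
    def is_complete(self) -> bool:
        return len(self.components) == 1

    def remaining_pairs(self):
        for ca, cb in itertools.combinations(self.components, 2):
            for u in ca.leaves:
                for v in cb.leaves:
                    yield pair_key(u, v)

    def topology(self) -> Topology:
        if not self.is_complete:
            raise TreeError("assembly is not a complete topology")
        return Topology(self.components[0].node)

    def entry_statuses(self, entries) -> list:
        """Status of each (pair, length) entry: open/completed/incompatible.

        An entry is completed when its pair's path is built with exactly
        that length, incompatible when the pair was completed with another
        length or the forest's heights already overshoot it, and open
        otherwise.
        """
        comp_of = {}
        for c in self.components:
            for leaf in c.leaves:
                comp_of[leaf] = c
        out = []
        for e in entries:
            a, b = e.pair
            if e.pair in self.completed:
                out.append("completed" if self.completed[e.pair] == e.length
                           else "incompatible")
            elif comp_of[a].heights[a] + comp_of[b].heights[b] + 1 > e.length:
                out.append("incompatible")
            else:
                out.append("open")
        return out

    def join(self, i: int, j: int, d: PathLengthDistribution,
             allow_unobserved: bool) -> Optional["Assembly"]:
        """Join components i and j under a new root, or None if not permitted.

        Every pair spanning the two subtrees is completed with length
        h(u) + h(v) + 1.  In strict (observed-only) mode the join is
        permitted only when each completed length was observed in the
        ensemble; otherwise unobserved lengths contribute the floor
        frequency and set the floored flag.
        """
        ca, cb = self.components[i], self.components[j]
        add, floored, new_lengths = 0.0, self.floored, {}
        for u in ca.leaves:
            hu = ca.heights[u]
            for v in cb.leaves:
                length = hu + cb.heights[v] + 1
                pair = pair_key(u, v)
                total = d.valid_total(pair)
                count = d.observed_lengths(pair).get(length, 0)
                if count == 0:
                    if not allow_unobserved:
                        return None
                    add += math.log(d.floor_frequency(pair))
                    floored = True
                else:
                    add += math.log(count / total)
                new_lengths[pair] = length
        first, second = (ca, cb) if ca.min_leaf < cb.min_leaf else (cb, ca)
        merged = _Component(
            key=f"({first.key},{second.key})",
            min_leaf=first.min_leaf,
            leaves=ca.leaves | cb.leaves,
            heights={u: h + 1 for u, h in {**ca.heights, **cb.heights}.items()},
            node=Node(children=[first.node, second.node]),
        )
        comps = tuple(c for k, c in enumerate(self.components) if k not in (i, j))
        comps = tuple(sorted(comps + (merged,), key=lambda c: c.min_leaf))
        completed = {**self.completed, **new_lengths}
        return Assembly(self.universe, comps, self.score + add, floored, completed)


def branch_extensions(a: Assembly, d: PathLengthDistribution,
                      *, allow_unobserved: bool = False) -> list:
    """Every permitted single-node extension of an assembly.

    Each unordered pair of forest subtrees yields at most one candidate
    join; in strict mode a join is generated only when every pairwise path
    it completes has a length observed in the ensemble.
    """
    if a.is_complete:
        return []
    out = []
    for i, j in itertools.combinations(range(len(a.components)), 2):
        ext = a.join(i, j, d, allow_unobserved)
        if ext is not None:
            out.append(ext)
    return out


@dataclass
class SearchBudget:
    """Resource cap for a reconstruction run."""

    max_assemblies: Optional[int] = None
    max_seconds: Optional[float] = None


@dataclass
class ReconstructionResult:
    """Ranked outcome of an N-best reconstruction."""

    topologies: list  # [(Topology, TopologyScore)] sorted best-first
    complete: bool
    statistics: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "complete": self.complete,
                "statistics": self.statistics,
                "topologies": [
                    {"rank": k + 1, "newick": write_newick(t),
                     "score": s.value, "floored": s.floored}
                    for k, (t, s) in enumerate(self.topologies)
                ],
            },
            indent=1,
        )

    def write_trees(self, path) -> None:
        with open(path, "w") as fh:
            for t, _ in self.topologies:
                fh.write(write_newick(t) + "\n")


def reconstruct_n_best(
    d: PathLengthDistribution,
    n: int,
    budget: Optional[SearchBudget | int] = None,
    *,
    allow_unobserved: bool = True,
) -> ReconstructionResult:
    """Enumerate the n highest log-frequency-scoring topologies.

    With ``allow_unobserved`` (the default) the search ranges over every
    rooted binary topology on the ancestor universe, scoring unobserved
    path lengths at the floor frequency, and on completion returns exactly
    the top n of exhaustive scoring.  With ``allow_unobserved=False`` only
    topologies all of whose path lengths were observed in the ensemble are
    constructible.  ``budget`` caps assemblies created and/or wall time;
    a truncated run reports ``complete=False`` and returns the (already
    correctly ranked) topologies completed before the cap.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    universe = d.universe
    if len(universe) < 2:
        raise TreeError("need at least two ancestors")
    for pair in itertools.combinations(universe, 2):
        if d.valid_total(pair) == 0:
            raise TreeError(f"distribution has no observations for pair {pair}")
    if isinstance(budget, int):
        budget = SearchBudget(max_assemblies=budget)

    start = time.monotonic()
    root = Assembly.empty(universe)
    seq = itertools.count()
    heap = [(-projected_score(root, d), next(seq), root)]
    seen = {root.key}
    results: list = []  # (TopologyScore, newick, Topology) popped in score order
    stats = {"created": 1, "abandoned": 0, "deduplicated": 0, "completed": 0}
    complete = True

    def bound() -> Optional[float]:
        if len(results) < n:
            return None
        return results[n - 1][0].value

    while heap:
        if budget is not None:
            if (budget.max_assemblies is not None
                    and stats["created"] >= budget.max_assemblies):
                complete = False
                break
            if (budget.max_seconds is not None
                    and time.monotonic() - start > budget.max_seconds):
                complete = False
                break
        neg_proj, _, assembly = heapq.heappop(heap)
        b = bound()
        if b is not None and -neg_proj < b - _TOL:
            # best-first: everything still queued projects no better
            stats["abandoned"] += len(heap) + 1
            break
        if assembly.is_complete:
            t = assembly.topology()
            score = log_frequency_score(t, d)
            results.append((score, write_newick(t), t))
            stats["completed"] += 1
            continue
        for ext in branch_extensions(assembly, d, allow_unobserved=allow_unobserved):
            if ext.key in seen:
                stats["deduplicated"] += 1
                continue
            seen.add(ext.key)
            stats["created"] += 1
            if ext.is_complete:
                priority = log_frequency_score(ext.topology(), d).value
            else:
                priority = projected_score(ext, d)
            b = bound()
            if b is not None and priority < b - _TOL:
                stats["abandoned"] += 1
                continue
            heapq.heappush(heap, (-priority, next(seq), ext))

    results.sort(key=lambda r: (-r[0].value, r[1]))
    ranked = [(t, s) for s, _, t in results[:n]]
    return ReconstructionResult(ranked, complete, stats)


# ---------------------------------------------------------------------------
# Clade-frequency annotation of a result set
# ---------------------------------------------------------------------------


def clade_frequencies(topologies: Sequence[Topology]) -> dict:
    """Fraction of input topologies containing each observed clade."""
    if not topologies:
        raise TreeError("need at least one topology")
    universe = topologies[0].leaves
    counts: dict = {}
    for t in topologies:
        if t.leaves != universe:
            raise TreeError("clade frequencies require one shared leaf universe")
        for clade in t.clades():
            counts[clade] = counts.get(clade, 0) + 1
    return {clade: c / len(topologies) for clade, c in counts.items()}


def write_clade_tsv(freqs: dict, path_or_handle) -> None:
    close = not hasattr(path_or_handle, "write")
    fh = open(path_or_handle, "w") if close else path_or_handle
    try:
        rows = sorted(freqs.items(), key=lambda kv: (-kv[1], sorted(kv[0])))
        for clade, f in rows:
            fh.write(",".join(sorted(clade)) + f"\t{f:.6g}\n")
    finally:
        if close:
            fh.close()


def write_annotated_newick(t: Topology, freqs: dict) -> str:
    """Newick with internal nodes labelled by their clade's frequency."""

    from .trees import _sorted_children

    def clade_of(node: Node) -> frozenset:
        leaves, stack = set(), [node]
        while stack:
            x = stack.pop()
            if x.is_leaf:
                leaves.add(x.label)
            else:
                stack.extend(x.children)
        return frozenset(leaves)

    def fmt(node: Node) -> str:
        if node.is_leaf:
            return node.label
        inner = "(" + ",".join(fmt(c) for c in _sorted_children(node)) + ")"
        f = freqs.get(clade_of(node))
        return inner + (f"{f:.3g}" if f is not None else "")

    return fmt(t.root) + ";"
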