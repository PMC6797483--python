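"""Path-length matrices and ensemble frequency distributions.

A rooted binary topology is equivalently represented by the matrix of
leaf-to-leaf path lengths, where the length of a path is the number of
internal nodes on it — the root included whenever the path crosses it.
(Many libraries count edges; this package deliberately counts internal
nodes, which is what makes the representation aggregate cleanly across an
ensemble.)  For the six-leaf tree (((A,B),((C,D),E)),F) the entries include
(A,B)=1, (D,E)=2, (E,F)=3 and (B,C)=4.

Aggregating the matrices of an ensemble of pruned topologies produces, for
every unordered ancestor pair, an empirical distribution of observed path
lengths.  Pairs whose path in a particular ensemble member is compromised —
a missing ancestor leaf, or a path through a spurious node left by a
non-monophyletic orthoset — contribute nothing from that member; each
pair's frequencies are normalized by its own count of valid observations so
frequencies stay comparable across pairs.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .trees import Node, PrunedTopology, Topology, TreeError

__all__ = [
    "PathLengthMatrix",
    "PathLengthDistribution",
    "Entry",
    "to_path_matrix",
    "from_path_matrix",
    "aggregate_ensemble",
    "sorted_entries",
]

Pair = tuple  # (label_a, label_b) with label_a < label_b


def pair_key(a: str, b: str) -> Pair:
    return (a, b) if a < b else (b, a)


class PathLengthMatrix:
    """Symmetric integer matrix of internal-node counts between leaves."""

    def __init__(self, labels: Sequence[str], matrix: np.ndarray):
        self.labels = tuple(labels)
        self.index = {lab: i for i, lab in enumerate(self.labels)}
        m = np.asarray(matrix, dtype=int)
        n = len(self.labels)
        if m.shape != (n, n) or not np.array_equal(m, m.T):
            raise TreeError("path-length matrix must be square and symmetric")
        off = m[~np.eye(n, dtype=bool)]
        if n > 1 and (off.min() < 1 or off.max() > 2 * n - 3):
            raise TreeError("path lengths must lie in [1, 2n-3]")
        self.matrix = m

    def __getitem__(self, pair) -> int:
        a, b = pair
        return int(self.matrix[self.index[a], self.index[b]])

    def __eq__(self, other):
        if not isinstance(other, PathLengthMatrix):
            return NotImplemented
        return self.labels == other.labels and np.array_equal(self.matrix, other.matrix)

    def __hash__(self):
        return hash((self.labels, self.matrix.tobytes()))

    def pairs(self):
        for a, b in itertools.combinations(self.labels, 2):
            yield (a, b), self[a, b]

    def write_tsv(self, path_or_handle) -> None:
        close = not hasattr(path_or_handle, "write")
        fh = open(path_or_handle, "w") if close else path_or_handle
        try:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for i, lab in enumerate(self.labels):
                fh.write(lab + "\t" + "\t".join(str(int(v)) for v in self.matrix[i]) + "\n")
        finally:
            if close:
                fh.close()

    @classmethod
    def read_tsv(cls, path_or_handle) -> "PathLengthMatrix":
        close = not hasattr(path_or_handle, "read")
        fh = open(path_or_handle) if close else path_or_handle
        try:
            lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
        finally:
            if close:
                fh.close()
        labels = lines[0].split("\t")[1:]
        rows = []
        for ln in lines[1:]:
            parts = ln.split("\t")
            rows.append([int(v) for v in parts[1:]])
        return cls(labels, np.array(rows))


def to_path_matrix(t: Topology) -> PathLengthMatrix:
    """Count internal nodes (root included) on every leaf-to-leaf path.

    With d(x) the edge-depth of leaf x and d(lca) that of the pair's last
    common ancestor, the count is d(a) + d(b) - 2 d(lca) - 1.
    """
    labels = tuple(sorted(t.leaves))
    paths = t.leaf_paths()  # label -> internal nodes root..parent
    n = len(labels)
    m = np.zeros((n, n), dtype=int)
    for i, a in enumerate(labels):
        for j in range(i + 1, n):
            b = labels[j]
            pa, pb = paths[a], paths[b]
            shared = 0
            for x, y in zip(pa, pb):
                if x is y:
                    shared += 1
                else:
                    break
            # lca + nodes below it on either side
            m[i, j] = m[j, i] = 1 + (len(pa) - shared) + (len(pb) - shared)
    return PathLengthMatrix(labels, m)


def from_path_matrix(m: PathLengthMatrix) -> Topology:
    """Rebuild the unique topology realizing a consistent path-length matrix.

    Bottom-up construction guided by the entries sorted by length: an entry
    whose pair lies in two different subtrees forces those subtrees to be
    joined under a new internal node, which must recapitulate the entry's
    length exactly; every cross-pair length implied by the join is checked
    against the matrix.  The first entry that cannot be satisfied is named
    in the raised error.
    """
    labels = m.labels
    comp = {lab: lab for lab in labels}  # leaf -> component id
    members: dict = {lab: [lab] for lab in labels}
    height = {lab: 0 for lab in labels}  # internal nodes leaf..subtree root
    roots: dict = {lab: Node(label=lab) for lab in labels}

    def join(ca: str, cb: str) -> None:
        new_root = Node(children=[roots[ca], roots[cb]])
        merged = members[ca] + members[cb]
        new_id = min(ca, cb)
        for u in merged:
            comp[u] = new_id
            height[u] += 1
        members[new_id] = merged
        roots[new_id] = new_root
        for stale in {ca, cb} - {new_id}:
            members.pop(stale)
            roots.pop(stale)

    entries = sorted(m.pairs(), key=lambda e: (e[1], e[0]))
    # An entry whose length exceeds the current joint height is merely
    # premature (ties at one length may need other joins first), so passes
    # repeat until a full sweep makes no progress.  When the heights do
    # match, the join is forced: the entry's ancestral node must be the
    # immediate parent of both subtree roots, so any cross-pair mismatch
    # proves the matrix unrealizable.
    while True:
        progress = False
        for (a, b), length in entries:
            ca, cb = comp[a], comp[b]
            if ca == cb:
                continue
            implied = height[a] + height[b] + 1
            if implied > length:
                raise TreeError(
                    f"unsatisfiable path-length entry ({a},{b})={length}: "
                    f"construction already implies {implied}"
                )
            if implied < length:
                continue
            for u in members[ca]:
                for v in members[cb]:
                    if height[u] + height[v] + 1 != m[u, v]:
                        raise TreeError(
                            f"unsatisfiable path-length entry "
                            f"({min(u, v)},{max(u, v)})={m[u, v]}: join of "
                            f"({a},{b}) implies {height[u] + height[v] + 1}"
                        )
            join(ca, cb)
            progress = True
        if not progress:
            break

    remaining = {comp[lab] for lab in labels}
    if len(remaining) != 1:
        first_open = next(
            (e for e in entries if comp[e[0][0]] != comp[e[0][1]]), None
        )
        raise TreeError(
            f"matrix is not realizable: no consistent join for entry {first_open}"
        )
    t = Topology(roots[next(iter(remaining))])
    # same-component entries were deferred above; one structural check
    # certifies them all
    realized = to_path_matrix(t)
    if not np.array_equal(realized.matrix, m.matrix):
        pair, v = next((p, v) for p, v in m.pairs() if realized[p] != v)
        raise TreeError(f"unsatisfiable path-length entry {pair}={v}")
    return t


# ---------------------------------------------------------------------------
# Ensemble aggregation
# ---------------------------------------------------------------------------


class PathLengthDistribution:
    """Per-pair empirical path-length distributions across an ensemble."""

    def __init__(self, universe: Sequence[str], ensemble_size: int = 0):
        self.universe = tuple(sorted(universe))
        self.ensemble_size = ensemble_size
        self.counts: dict = {
            p: {} for p in itertools.combinations(self.universe, 2)
        }

    # -- building ------------------------------------------------------------

    def add_observation(self, pair: Pair, length: int, count: int = 1) -> None:
        self.counts[pair][length] = self.counts[pair].get(length, 0) + count

    # -- queries -------------------------------------------------------------

    def pairs(self):
        return self.counts.keys()

    def valid_total(self, pair: Pair) -> int:
        return sum(self.counts[pair].values())

    def frequency(self, pair: Pair, length: int) -> float:
        total = self.valid_total(pair)
        if total == 0:
            raise TreeError(f"pair {pair} has no valid observations")
        return self.counts[pair].get(length, 0) / total

    def observed_lengths(self, pair: Pair) -> dict:
        return dict(self.counts[pair])

    def best_frequency(self, pair: Pair) -> float:
        """Highest observed frequency for the pair (the max over lengths)."""
        total = self.valid_total(pair)
        if total == 0:
            raise TreeError(f"pair {pair} has no valid observations")
        return max(self.counts[pair].values()) / total

    def floor_frequency(self, pair: Pair) -> float:
        """Finite stand-in frequency for a never-observed length.

        1/(2E+1) with E the pair's valid observations: strictly below any
        observed frequency (>= 1/E), so supported topologies always outrank
        unsupported ones pairwise.
        """
        total = self.valid_total(pair)
        if total == 0:
            raise TreeError(f"pair {pair} has no valid observations")
        return 1.0 / (2 * total + 1)

    # -- serialization -------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "universe": list(self.universe),
                "ensemble_size": self.ensemble_size,
                "counts": {
                    f"{a}|{b}": {str(k): v for k, v in sorted(lens.items())}
                    for (a, b), lens in sorted(self.counts.items())
                },
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "PathLengthDistribution":
        obj = json.loads(text)
        d = cls(obj["universe"], obj["ensemble_size"])
        for key, lens in obj["counts"].items():
            a, b = key.split("|")
            for L, c in lens.items():
                d.add_observation(pair_key(a, b), int(L), int(c))
        return d


def aggregate_ensemble(ensemble: Sequence[PrunedTopology],
                       rescue_uncovered: bool = False) -> PathLengthDistribution:
    """Pool per-pair path lengths over an ensemble of pruned topologies.

    A member contributes a pair's length only when both ancestor leaves are
    present in that member and the connecting path avoids spurious nodes;
    uncompromised paths from an otherwise flawed member are still included.

    An ancestor that is almost never confidently reconstructed can leave a
    pair with zero valid observations, which would make reconstruction over
    the full universe impossible.  With ``rescue_uncovered`` such pairs —
    and only such pairs — fall back to their compromised observations (the
    pair's path lengths from members where both leaves are present,
    spurious nodes notwithstanding).  Ancestor selection should be
    revisited when this triggers; the pipeline records a warning.
    """
    if not ensemble:
        raise TreeError("cannot aggregate an empty ensemble")
    universe = set(ensemble[0].universe)
    for m in ensemble[1:]:
        if set(m.universe) != universe:
            raise TreeError("ensemble members must share one orthoset universe")
    dist = PathLengthDistribution(sorted(universe), ensemble_size=len(ensemble))
    matrices = []
    for member in ensemble:
        pm = to_path_matrix(member.topology)
        matrices.append(pm)
        excluded = member.compromised_pairs()
        for pair, length in pm.pairs():
            if pair in excluded:
                continue
            dist.add_observation(pair, length)
    if rescue_uncovered:
        n = len(dist.universe)
        for pair in dist.pairs():
            if dist.valid_total(pair) > 0:
                continue
            for member, pm in zip(ensemble, matrices):
                if pair[0] in member.present and pair[1] in member.present:
                    dist.add_observation(pair, pm[pair])
            if dist.valid_total(pair) == 0:
                # the ancestor was never reconstructed at all: the ensemble
                # carries no information about this pair.  A flat
                # pseudo-count over every feasible length is ranking-neutral
                # (each topology realizes exactly one of them).
                for length in range(1, 2 * n - 2):
                    dist.add_observation(pair, length)
    return dist


@dataclass(frozen=True)
class Entry:
    """One (pair, length, frequency) record of the sorted observation list."""

    pair: Pair
    length: int
    frequency: float


def sorted_entries(d: PathLengthDistribution) -> list:
    """Flatten a distribution into its guiding list of entries.

    Sorted by length ascending so bottom-up construction meets short paths
    first, ties broken by descending frequency and then lexicographic pair.
    Search completeness does not depend on this order.
    """
    entries = []
    for pair in d.pairs():
        total = d.valid_total(pair)
        if total == 0:
            continue
        for length, count in d.observed_lengths(pair).items():
            entries.append(Entry(pair, length, count / total))
    if not entries:
        raise TreeError("empty distribution")
    entries.sort(key=lambda e: (e.length, -e.frequency, e.pair))
    return entries
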