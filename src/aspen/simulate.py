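"""Synthetic paralog families and desk-scale perturbation fixtures.

The generator emulates the benchmark construction used throughout this
package's evaluation: a random rooted topology describes the divergence of
paralogs through duplications (the default 15 paralogs, with exponential
branch lengths of mean 0.5-1.0 expected substitutions/site); a species
tree — by default a seedable birth-death tree with 66 tips — is grafted at
every paralog leaf to represent ortholog divergence through speciation,
independently rescaled in total height and perturbed segment by segment to
mimic rate differences between paralogs (heterotachy); and sequences are
evolved along the resulting phylogeny under a substitution-only model.

Substitutions follow the classical Poisson amino-acid model (equal
exchangeabilities, uniform stationary frequencies) with per-site rate
multipliers spanning a five-fold range.  Indels are not modelled, so the
simulated sequences are implicitly aligned, which is what lets the
built-in distance adapter run without an external aligner.  The built-in
inference adapter is deliberately model-free (p-distance neighbor
joining), so inference never assumes the simulation model.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .trees import Node, PrunedTopology, Topology, TreeError, read_newick

__all__ = [
    "AMINO_ACIDS",
    "SimulationParams",
    "random_paralog_topology",
    "birth_death_species_tree",
    "graft_and_scale",
    "evolve_sequences",
    "perturbed_ensemble",
    "simulate_family",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_N_AA = len(AMINO_ACIDS)


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


@dataclass
class SimulationParams:
    """Knobs of the family generator.

    Defaults follow the benchmark conditions: 15 paralogs, 66 species,
    paralog branch lengths drawn from an exponential with mean in the
    0.5-1.0 substitutions/site range, sequences of 269 residues (the
    median length of the seed alignment the benchmark emulates), and
    per-site substitution-rate classes spanning a five-fold range.  The
    species tree is height-normalized to 1.0 before grafting; each grafted
    copy is rescaled in total height by a uniform draw from
    ``height_rescale`` and every branch is further jittered by a uniform
    draw from ``segment_perturbation``.
    """

    n_paralogs: int = 15
    mean_branch_length: float = 0.75
    n_species: int = 66
    species_tree: Optional[Topology] = None
    height_rescale: tuple = (0.3, 0.9)
    segment_perturbation: tuple = (0.7, 1.3)
    sequence_length: int = 269
    rate_classes: Sequence[float] = (0.4, 0.7, 1.0, 1.4, 2.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_paralogs < 2:
            raise TreeError("need at least two paralogs")
        if self.mean_branch_length <= 0 or self.sequence_length < 1:
            raise TreeError("scales must be positive")


def random_paralog_topology(n: int, mean_bl: float, seed_or_rng=0) -> Topology:
    """Random rooted binary topology with exponential branch lengths.

    Uniform over rooted topologies via sequential random attachment: each
    new leaf is attached to a branch chosen uniformly among the 2k-1
    branches of the partial tree (the root branch included).
    """
    if n < 2:
        raise TreeError("need at least two leaves")
    rng = _as_rng(seed_or_rng)
    width = max(2, len(str(n)))
    labels = [f"P{i + 1:0{width}d}" for i in range(n)]

    root = Node(children=[Node(label=labels[0]), Node(label=labels[1])])
    for lab in labels[2:]:
        nodes = _all_nodes(root)
        target = nodes[int(rng.integers(len(nodes)))]
        new_leaf = Node(label=lab)
        if target is root:
            root = Node(children=[root, new_leaf])
        else:
            parent = _parent_of(root, target)
            idx = parent.children.index(target)
            parent.children[idx] = Node(children=[target, new_leaf])
    t = Topology(root)
    for node in _all_nodes(t.root):
        if node is not t.root:
            node.length = float(rng.exponential(mean_bl))
    return t


def _all_nodes(root: Node) -> list:
    out, stack = [], [root]
    while stack:
        n = stack.pop()
        out.append(n)
        stack.extend(reversed(n.children))
    return out


def _parent_of(root: Node, target: Node) -> Node:
    stack = [root]
    while stack:
        n = stack.pop()
        for c in n.children:
            if c is target:
                return n
            stack.append(c)
    raise TreeError("node not in tree")


def birth_death_species_tree(n_tips: int = 66, birth_rate: float = 1.0,
                             death_rate: float = 0.5, seed: int = 0) -> Topology:
    """Seedable birth-death species tree, height-normalized to 1.

    Tips are relabelled s01..sNN; a user-supplied species tree (any Newick
    with branch lengths) can be used instead wherever one is accepted.
    """
    from dendropy.simulate import treesim

    tree = treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=death_rate,
        num_extant_tips=n_tips,
        rng=_random.Random(seed),
    )
    topo = read_newick(tree.as_string(schema="newick", suppress_rooting=True))
    width = max(2, len(str(n_tips)))
    # deterministic relabelling in canonical (sorted) label order
    mapping = {
        old: f"s{i + 1:0{width}d}"
        for i, old in enumerate(sorted(topo.leaves))
    }
    for node in topo.iter_nodes():
        if node.is_leaf:
            node.label = mapping[node.label]
    out = Topology(topo.root)
    _normalize_height(out)
    return out


def _tree_height(t: Topology) -> float:
    def walk(node: Node) -> float:
        own = node.length or 0.0
        if node.is_leaf:
            return own
        return own + max(walk(c) for c in node.children)

    return max(walk(c) for c in t.root.children)


def _normalize_height(t: Topology) -> None:
    h = _tree_height(t)
    if h <= 0:
        raise TreeError("species tree must have positive height")
    for node in t.iter_nodes():
        if node.length is not None:
            node.length /= h


def graft_and_scale(paralog_tree: Topology, species_tree: Topology,
                    p: SimulationParams, seed_or_rng=None):
    """Replace each paralog leaf by a rescaled, perturbed species-tree copy.

    Leaf labels become ``<paralog>_<species>``.  Returns the full true
    phylogeny and the orthoset map assigning every sequence to its paralog;
    pruning the result back to orthoset ancestors recovers the paralog
    topology exactly.
    """
    from .trees import OrthosetMap

    rng = _as_rng(p.seed if seed_or_rng is None else seed_or_rng)
    assignment = {}

    def copy_species(paralog: str) -> Node:
        scale = float(rng.uniform(*p.height_rescale))

        def dup(node: Node) -> Node:
            length = None
            if node.length is not None:
                length = node.length * scale * float(
                    rng.uniform(*p.segment_perturbation)
                )
            if node.is_leaf:
                label = f"{paralog}_{node.label}"
                assignment[label] = paralog
                return Node(label=label, length=length)
            return Node(children=[dup(c) for c in _in_order(node)], length=length)

        return dup(species_tree.root)

    def _in_order(node: Node) -> list:
        return sorted(node.children, key=lambda c: min(
            x.label for x in _all_nodes(c) if x.is_leaf
        ))

    def graft(node: Node) -> Node:
        if node.is_leaf:
            sub = copy_species(node.label)
            sub.length = node.length
            return sub
        return Node(
            children=[graft(c) for c in _in_order(node)], length=node.length
        )

    full = Topology(graft(paralog_tree.root))
    return full, OrthosetMap(assignment)


def evolve_sequences(tree: Topology, p: SimulationParams, seed_or_rng=None) -> dict:
    """Evolve amino-acid sequences along a phylogeny, root to tips.

    Poisson model: the root sequence is uniform over the 20 residues and
    each site substitutes independently along a branch of length t
    (expected substitutions/site) scaled by its site-rate class; a
    substituting site moves to one of the other 19 residues uniformly.
    Branch lengths of zero reproduce the parent sequence exactly.
    """
    rng = _as_rng(p.seed if seed_or_rng is None else seed_or_rng)
    L = p.sequence_length
    site_rates = np.asarray(p.rate_classes, dtype=float)[
        rng.integers(len(p.rate_classes), size=L)
    ]
    root_state = rng.integers(_N_AA, size=L)
    out = {}

    def descend(node: Node, state: np.ndarray) -> None:
        if node is not tree.root:
            t = float(node.length or 0.0)
            # P(site unchanged) under the 20-state equal-rates chain,
            # normalized so t is in expected substitutions per site
            p_change = (1 - 1 / _N_AA) * (
                1 - np.exp(-(_N_AA / (_N_AA - 1)) * t * site_rates)
            )
            hit = rng.random(L) < p_change
            state = state.copy()
            state[hit] = (
                state[hit] + 1 + rng.integers(_N_AA - 1, size=int(hit.sum()))
            ) % _N_AA
        if node.is_leaf:
            out[node.label] = "".join(AMINO_ACIDS[i] for i in state)
            return
        for child in sorted(node.children, key=lambda c: min(
            x.label for x in _all_nodes(c) if x.is_leaf
        )):
            descend(child, state)

    descend(tree.root, root_state)
    return dict(sorted(out.items()))


def perturbed_ensemble(truth: Topology, k: int, intensity: int,
                       seed_or_rng=0) -> list:
    """k copies of ``truth``, each scrambled by random NNI moves.

    A fast fixture standing in for inference noise: intensity 0 reproduces
    the truth exactly; each move picks a random internal non-root node and
    swaps one of its children with its sibling.
    """
    if k < 1 or intensity < 0:
        raise TreeError("k >= 1 and intensity >= 0 required")
    rng = _as_rng(seed_or_rng)
    members = []
    for _ in range(k):
        t = truth.copy()
        for _ in range(intensity):
            _random_nni(t, rng)
        members.append(PrunedTopology.from_topology(t))
    return members


def _random_nni(t: Topology, rng: np.random.Generator) -> None:
    candidates = [
        n for n in _all_nodes(t.root)
        if not n.is_leaf and n is not t.root
    ]
    if not candidates:
        return
    v = candidates[int(rng.integers(len(candidates)))]
    u = _parent_of(t.root, v)
    sibling = next(c for c in u.children if c is not v)
    child = v.children[int(rng.integers(2))]
    u.children[u.children.index(sibling)] = child
    v.children[v.children.index(child)] = sibling


def simulate_family(p: SimulationParams):
    """Generate one complete synthetic family.

    Returns a :class:`~aspen.pipeline.FamilyDataset` whose true topology is
    the generating paralog divergence topology, plus the full phylogeny.
    """
    from .pipeline import FamilyDataset

    rng = np.random.default_rng(p.seed)
    paralog = random_paralog_topology(p.n_paralogs, p.mean_branch_length, rng)
    species = p.species_tree or birth_death_species_tree(
        p.n_species, seed=int(p.seed) + 1
    )
    full, omap = graft_and_scale(paralog, species, p, rng)
    seqs = evolve_sequences(full, p, rng)
    bare = Topology.from_nested(_strip(paralog.root))
    dataset = FamilyDataset(sequences=seqs, orthosets=omap, true_topology=bare)
    return dataset, full


def _strip(node: Node):
    if node.is_leaf:
        return node.label
    return tuple(_strip(c) for c in node.children)
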