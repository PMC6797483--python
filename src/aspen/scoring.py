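"""Log-frequency scoring of topologies against ensemble observations.

score(T) = sum over unordered leaf pairs of log f_pair,L(T), where
f_pair,L is the empirical frequency with which the ensemble realized the
path length L that T assigns to the pair.  The score is 0 exactly when
every path length of T was observed in every valid ensemble member, and
strictly negative otherwise; it rewards frequently observed path lengths
and penalizes rare ones.

A length never observed for a pair receives the finite floor frequency
1/(2E+1) (E = the pair's valid observations) so that even topologies
outside the ensemble's support — e.g. an all-sequence reconstruction being
compared against a subsampling ensemble — obtain a finite, ranked score.
Natural log throughout; the ranking is base-invariant.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

from .pathlengths import PathLengthDistribution, to_path_matrix
from .trees import Topology, TreeError

__all__ = ["TopologyScore", "log_frequency_score", "projected_score"]


@dataclass(frozen=True)
class TopologyScore:
    """A topology's ensemble-consistency score (<= 0).

    ``floored`` is set when any pair had to fall back to the
    unobserved-length floor frequency.
    """

    value: float
    floored: bool = False

    def __lt__(self, other):
        return self.value < other.value


def pair_log_frequency(d: PathLengthDistribution, pair, length: int) -> tuple:
    """(log frequency, floored flag) for one pair/length observation."""
    total = d.valid_total(pair)
    if total == 0:
        raise TreeError(f"pair {pair} has no valid observations in the ensemble")
    count = d.observed_lengths(pair).get(length, 0)
    if count:
        return math.log(count / total), False
    return math.log(d.floor_frequency(pair)), True


def log_frequency_score(t: Topology, d: PathLengthDistribution) -> TopologyScore:
    """Score a complete topology against a path-length distribution."""
    if not t.leaves <= set(d.universe):
        raise TreeError("topology leaves outside the distribution's universe")
    pm = to_path_matrix(t)
    value, floored = 0.0, False
    for pair, length in pm.pairs():
        lf, fl = pair_log_frequency(d, pair, length)
        value += lf
        floored = floored or fl
    return TopologyScore(value, floored)


def projected_score(assembly, d: PathLengthDistribution) -> float:
    """Optimistic bound on any completion of a partial assembly.

    The score of already-incorporated paths plus, for every pair not yet
    connected, the best (most frequent) log frequency it could still
    achieve.  Because every pair's eventual contribution is at most its
    best observed log frequency, no completion can exceed this value —
    the admissibility that makes branch-and-bound bounding safe.
    """
    value = assembly.score
    for pair in assembly.remaining_pairs():
        value += math.log(d.best_frequency(pair))
    return value


def score_report(ranked, d: PathLengthDistribution) -> str:
    """JSON report for a ranked list of (Topology, TopologyScore)."""
    from .trees import write_newick

    rows = []
    for t, s in ranked:
        rows.append(
            {"topology": write_newick(t), "score": s.value, "floored": s.floored}
        )
    return json.dumps(rows, indent=1)
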