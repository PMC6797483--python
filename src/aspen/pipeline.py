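"""End-to-end orchestration: subsample, infer, prune, aggregate, search.

The pipeline realizes the full ensemble workflow: (1) infer and prune an
all-sequence topology, (2) measure its reproducibility (precision) against
an ensemble of high-fraction subsamples, (3) aggregate a larger
low-fraction ensemble into path-length frequency distributions, (4) run
the branch-and-bound search for the N best-scoring topologies, (5)
annotate them with clade frequencies, and (6), when a true topology is
known (simulated benchmarks), report accuracies.

Tree inference is delegated to an :class:`InferenceAdapter`.  The built-in
adapter is neighbor joining on uncorrected p-distances — model-free, fast
and dependency-light, suitable for the gap-free simulated families; real
protein families should use the command adapter with an external
align-then-infer pipeline (e.g. ``mafft --auto {fasta} | fasttree``).
"""

from __future__ import annotations

import json
import math
import os
import subprocess
import tempfile
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .pathlengths import PathLengthDistribution, aggregate_ensemble
from .search import ReconstructionResult, SearchBudget, clade_frequencies, \
    reconstruct_n_best, write_annotated_newick, write_clade_tsv
from .trees import OrthosetMap, PrunedTopology, Topology, TreeError, \
    UnprunableError, accuracy, precision, prune_to_ancestors, read_newick, \
    write_newick

__all__ = [
    "FamilyDataset",
    "SubsampleSpec",
    "InferenceAdapter",
    "NeighborJoiningAdapter",
    "CommandLineAdapter",
    "AdapterError",
    "EnsembleResult",
    "PipelineReport",
    "subsample_family",
    "build_ensemble",
    "run_pipeline",
]


@dataclass
class FamilyDataset:
    """Sequences plus their orthoset assignment (and optional truth)."""

    sequences: dict  # label -> amino-acid string
    orthosets: OrthosetMap
    true_topology: Optional[Topology] = None

    def __post_init__(self):
        missing = set(self.sequences) - set(self.orthosets.assignment)
        if missing:
            raise TreeError(f"sequences without orthoset: {sorted(missing)[:5]}")

    def orthoset_members(self) -> dict:
        out: dict = {}
        for label in self.sequences:
            out.setdefault(self.orthosets.assignment[label], []).append(label)
        return {k: sorted(v) for k, v in sorted(out.items())}

    @classmethod
    def from_files(cls, fasta_path, orthosets_tsv, true_newick=None):
        from Bio import SeqIO

        seqs = {
            rec.id: str(rec.seq)
            for rec in SeqIO.parse(str(fasta_path), "fasta")
        }
        omap = OrthosetMap.read_tsv(orthosets_tsv)
        truth = None
        if true_newick is not None:
            with open(true_newick) as fh:
                truth = read_newick(fh.read())
        return cls(seqs, omap, truth)

    def write_fasta(self, path, labels: Optional[Sequence[str]] = None) -> None:
        labels = sorted(self.sequences) if labels is None else labels
        with open(path, "w") as fh:
            for lab in labels:
                fh.write(f">{lab}\n{self.sequences[lab]}\n")


@dataclass
class SubsampleSpec:
    """How to draw replicate sequence subsets from each orthoset.

    Either a ``fraction`` of each orthoset (about 90% for precision
    ensembles, about 50% for reconstruction ensembles) or a fixed
    per-orthoset ``count`` (e.g. 30 of 66).  The fractional size is
    ceil(fraction*n), clamped to n-1 when the ceiling would return the
    whole orthoset, so a strict fraction always actually subsamples.
    """

    fraction: Optional[float] = None
    count: Optional[int] = None
    replicates: int = 1
    seed: int = 0

    def __post_init__(self):
        if (self.fraction is None) == (self.count is None):
            raise TreeError("specify exactly one of fraction or count")
        if self.fraction is not None and not 0 < self.fraction <= 1:
            raise TreeError("fraction must be in (0, 1]")
        if self.count is not None and self.count < 1:
            raise TreeError("count must be >= 1")
        if self.replicates < 1:
            raise TreeError("replicates must be >= 1")

    def size_for(self, n: int) -> int:
        if self.count is not None:
            if self.count > n:
                raise TreeError(f"count {self.count} exceeds orthoset size {n}")
            return self.count
        size = math.ceil(self.fraction * n)
        if self.fraction < 1 and size >= n:
            size = n - 1
        return max(1, size)


def subsample_family(f: FamilyDataset, s: SubsampleSpec) -> list:
    """Replicate subsets: each orthoset contributes its target count.

    Sampling is without replacement and fully reproducible from the spec's
    seed; replicates are mutually independent draws.
    """
    rng = np.random.default_rng(s.seed)
    members = f.orthoset_members()
    for oset, labels in members.items():
        if len(labels) < 2:
            raise TreeError(f"orthoset {oset!r} has fewer than 2 sequences")
        s.size_for(len(labels))  # validates fixed counts up front
    out = []
    for _ in range(s.replicates):
        chosen = []
        for oset, labels in members.items():
            k = s.size_for(len(labels))
            idx = rng.choice(len(labels), size=k, replace=False)
            chosen.extend(labels[i] for i in sorted(idx))
        out.append(chosen)
    return out


# ---------------------------------------------------------------------------
# Inference adapters
# ---------------------------------------------------------------------------


class AdapterError(RuntimeError):
    """External or built-in inference failed."""


class InferenceAdapter:
    """Contract: a set of sequences in, a topology over their labels out."""

    def infer(self, sequences: dict) -> Topology:  # pragma: no cover
        raise NotImplementedError

    def _check(self, t: Topology, sequences: dict) -> Topology:
        if t.leaves != set(sequences):
            raise AdapterError("inferred tree leaves differ from input labels")
        return t


class NeighborJoiningAdapter(InferenceAdapter):
    """Neighbor joining on Poisson-corrected distances (built-in).

    Pairwise p-distances are corrected for multiple hits under the 20-state
    equal-rates model, d = -(19/20) ln(1 - 20p/19), capped where the
    correction diverges; raw p-distances are statistically inconsistent at
    the saturating divergences typical of deep paralog families.  The
    correction deliberately ignores rate heterogeneity across sites and
    heterotachy, so inference never matches the generating process exactly.
    Requires equal-length, implicitly aligned sequences, as produced by the
    substitution-only simulator.
    """

    def __init__(self, correction: str = "poisson"):
        if correction not in ("poisson", "none"):
            raise TreeError(f"unknown distance correction {correction!r}")
        self.correction = correction

    def infer(self, sequences: dict) -> Topology:
        from skbio import DistanceMatrix
        from skbio.tree import nj

        labels = sorted(sequences)
        if len(labels) < 3:
            raise AdapterError("neighbor joining needs at least 3 sequences")
        lengths = {len(sequences[lab]) for lab in labels}
        if len(lengths) != 1:
            raise AdapterError("sequences must be aligned (equal length)")
        arr = np.array(
            [np.frombuffer(sequences[lab].encode(), dtype=np.uint8)
             for lab in labels]
        )
        n = len(labels)
        dm = np.zeros((n, n))
        for i in range(n):
            dm[i, i + 1:] = (arr[i + 1:] != arr[i]).mean(axis=1)
        dm = dm + dm.T
        if self.correction == "poisson":
            b = 19 / 20
            dm = -b * np.log(np.maximum(1 - dm / b, 1e-3))
            np.fill_diagonal(dm, 0.0)
        tree = nj(DistanceMatrix(dm, ids=labels))
        return self._check(read_newick(str(tree), rooting="midpoint"), sequences)


class CommandLineAdapter(InferenceAdapter):
    """Wrap an external align-then-infer command.

    ``template`` is a shell command with a ``{fasta}`` placeholder; it must
    print a Newick tree over the input labels on stdout, e.g.
    ``"mafft --auto {fasta} 2>/dev/null | fasttree -nosupport"``.
    """

    def __init__(self, template: str):
        if "{fasta}" not in template:
            raise TreeError("command template must contain {fasta}")
        self.template = template

    def infer(self, sequences: dict) -> Topology:
        with tempfile.TemporaryDirectory(prefix="aspen_") as tmp:
            fasta = os.path.join(tmp, "input.fasta")
            with open(fasta, "w") as fh:
                for lab in sorted(sequences):
                    fh.write(f">{lab}\n{sequences[lab]}\n")
            proc = subprocess.run(
                self.template.format(fasta=fasta),
                shell=True, capture_output=True, text=True,
            )
        if proc.returncode != 0 or not proc.stdout.strip():
            raise AdapterError(
                f"inference command failed (exit {proc.returncode}): "
                f"{proc.stderr.strip()[:500]}"
            )
        return self._check(read_newick(proc.stdout, rooting="midpoint"), sequences)


# ---------------------------------------------------------------------------
# Ensemble construction
# ---------------------------------------------------------------------------


@dataclass
class EnsembleResult:
    """Pruned subsampled topologies plus per-orthoset monophyly summary."""

    members: list  # PrunedTopology per successful replicate
    monophyly_fractions: dict  # orthoset -> fraction of replicates monophyletic
    skipped: list = field(default_factory=list)  # replicate indices unprunable
    warnings: list = field(default_factory=list)


def build_ensemble(f: FamilyDataset, s: SubsampleSpec, a: InferenceAdapter,
                   monophyly_threshold: float = 0.95) -> EnsembleResult:
    """Infer and prune one topology per subsample replicate.

    Replicates whose pruning fails (fewer than two monophyletic orthosets)
    are skipped and recorded.  An orthoset monophyletic in fewer than
    ``monophyly_threshold`` of replicates triggers a warning: its ancestor
    cannot be considered confidently inferred.
    """
    subsets = subsample_family(f, s)
    members, skipped = [], []
    mono_counts: dict = {o: 0 for o in f.orthosets.orthosets}
    for idx, labels in enumerate(subsets):
        seqs = {lab: f.sequences[lab] for lab in labels}
        try:
            tree = a.infer(seqs)
            pruned = prune_to_ancestors(tree, f.orthosets)
        except UnprunableError:
            skipped.append(idx)
            continue
        except AdapterError as exc:
            raise AdapterError(f"replicate {idx}: {exc}") from exc
        members.append(pruned)
        for oset, rec in pruned.monophyly.items():
            mono_counts[oset] += int(rec.monophyletic)
    if not members:
        raise TreeError("every replicate was unprunable")
    total = len(subsets)
    fractions = {o: c / total for o, c in mono_counts.items()}
    warnings_ = [
        f"orthoset {o!r} monophyletic in only {frac:.0%} of replicates; "
        "its ancestor is not confidently inferred"
        for o, frac in sorted(fractions.items())
        if frac < monophyly_threshold
    ]
    return EnsembleResult(members, fractions, skipped, warnings_)


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineReport:
    """Everything one run produces, serializable to a single JSON object."""

    all_sequence: PrunedTopology
    precision: float
    precision_ensemble: EnsembleResult
    reconstruction_ensemble: EnsembleResult
    distribution: PathLengthDistribution
    reconstruction: ReconstructionResult
    clade_freqs: dict
    accuracy_all_sequence: Optional[float] = None
    aspen_accuracies: Optional[list] = None

    def to_dict(self) -> dict:
        out = {
            "all_sequence_topology": write_newick(self.all_sequence.topology),
            "precision": self.precision,
            "precision_replicates": len(self.precision_ensemble.members),
            "ensemble_replicates": len(self.reconstruction_ensemble.members),
            "monophyly": self.reconstruction_ensemble.monophyly_fractions,
            "warnings": (self.precision_ensemble.warnings
                         + self.reconstruction_ensemble.warnings),
            "search_complete": self.reconstruction.complete,
            "search_statistics": self.reconstruction.statistics,
            "topologies": [
                {"rank": k + 1, "newick": write_newick(t),
                 "score": s.value, "floored": s.floored}
                for k, (t, s) in enumerate(self.reconstruction.topologies)
            ],
            "clade_frequencies": {
                ",".join(sorted(c)): f for c, f in sorted(
                    self.clade_freqs.items(), key=lambda kv: (-kv[1], sorted(kv[0]))
                )
            },
        }
        if self.accuracy_all_sequence is not None:
            out["accuracy_all_sequence"] = self.accuracy_all_sequence
            out["aspen_accuracies"] = self.aspen_accuracies
        return out

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)


def run_pipeline(
    f: FamilyDataset,
    precision_spec: SubsampleSpec,
    ensemble_spec: SubsampleSpec,
    a: InferenceAdapter,
    n: int = 50,
    budget: Optional[SearchBudget | int] = None,
    out_dir=None,
    allow_unobserved: bool = True,
) -> PipelineReport:
    """Run the complete workflow on one family; see the module docstring."""
    all_seq_tree = a.infer(dict(f.sequences))
    all_sequence = prune_to_ancestors(all_seq_tree, f.orthosets)

    prec_ens = build_ensemble(f, precision_spec, a)
    prec = precision(all_sequence, prec_ens.members)

    recon_ens = build_ensemble(f, ensemble_spec, a)
    dist = aggregate_ensemble(recon_ens.members, rescue_uncovered=True)
    result = reconstruct_n_best(dist, n, budget, allow_unobserved=allow_unobserved)
    freqs = clade_frequencies([t for t, _ in result.topologies])

    acc_all, acc_aspen = None, None
    if f.true_topology is not None:
        truth = PrunedTopology.from_topology(f.true_topology)
        acc_all = accuracy(truth, all_sequence)
        acc_aspen = [
            accuracy(truth, PrunedTopology.from_topology(t))
            for t, _ in result.topologies
        ]

    report = PipelineReport(
        all_sequence, prec, prec_ens, recon_ens, dist, result, freqs,
        acc_all, acc_aspen,
    )
    if out_dir is not None:
        _write_run_dir(out_dir, f, report)
    return report


def _write_run_dir(out_dir, f: FamilyDataset, report: PipelineReport) -> None:
    os.makedirs(out_dir, exist_ok=True)

    def path(name):
        return os.path.join(out_dir, name)

    with open(path("all_sequence.nwk"), "w") as fh:
        fh.write(write_newick(report.all_sequence.topology) + "\n")
    for name, ens in (("precision_ensemble.nwk", report.precision_ensemble),
                      ("reconstruction_ensemble.nwk", report.reconstruction_ensemble)):
        with open(path(name), "w") as fh:
            for m in ens.members:
                fh.write(write_newick(m.topology) + "\n")
    with open(path("distribution.json"), "w") as fh:
        fh.write(report.distribution.to_json())
    report.reconstruction.write_trees(path("topologies.nwk"))
    write_clade_tsv(report.clade_freqs, path("clade_frequencies.tsv"))
    if report.reconstruction.topologies:
        top, _ = report.reconstruction.topologies[0]
        with open(path("top_annotated.nwk"), "w") as fh:
            fh.write(write_annotated_newick(top, report.clade_freqs) + "\n")
    with open(path("report.json"), "w") as fh:
        fh.write(report.to_json())
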