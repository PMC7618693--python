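"""Synthetic inputs for end-to-end testing.

Two generators:

* :func:`simulate_family` — a gene family of paralogs evolved down a known
  (given or random) rooted tree from a random root CDS, with i.i.d. per-site
  substitutions on every branch.  Closely related leaves therefore share
  conserved 21-nt windows, which is exactly the structure the design
  exploits.  No indels, no codon model, no selection: windows stay
  alignable and brute-force oracles stay simple.
* :func:`simulate_reads` — an amplicon read pool over an assembled library,
  with uniform, lognormal, or custom per-member depths and random read
  orientation.

Both are pure functions of (spec, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .assembly import LibraryEntry
from .phylo import FamilyTree
from .seqio import CLASS_LABELS, GeneRecord, ValidationError, revcomp

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS
]


@dataclass
class FamilySimSpec:
    """Parameters of one simulated gene family.

    ``per_branch_sub_prob`` is the probability that a site substitutes on
    one branch; with the default 0.02 and 600-nt CDS, sibling genes share
    hundreds of exact 21-mers in expectation.
    """

    n_genes: int = 8
    cds_length: int = 600
    tree: str = "random"  # Newick string or "random"
    per_branch_sub_prob: float = 0.02
    seed: int = 0
    class_label: str = "MFS"
    family_id: str = "FAM1"

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValidationError("n_genes must be >= 2")
        if self.cds_length < 21 or self.cds_length % 3:
            raise ValidationError("cds_length must be a multiple of 3, >= 21")
        if not (0.0 <= self.per_branch_sub_prob <= 0.3):
            raise ValidationError("per_branch_sub_prob must be in [0, 0.3]")
        if self.class_label not in CLASS_LABELS:
            raise ValidationError(f"unknown class {self.class_label!r}")
        # expected number of sibling-shared 21-mers: two branches of
        # substitutions between siblings, (1-p)^(2*21) per window
        p = self.per_branch_sub_prob
        n_windows = self.cds_length - 20
        expected_shared = n_windows * (1 - p) ** 42
        if expected_shared < 1:
            logger.warning(
                "per_branch_sub_prob=%.3f leaves < 1 shared 21-mer between "
                "siblings in expectation (%.2f)", p, expected_shared,
            )


def _random_bifurcation(labels: list[str], rng: np.random.Generator) -> str:
    """Random rooted binary tree over ``labels`` by recursive splitting."""
    if len(labels) == 1:
        return labels[0]
    k = int(rng.integers(1, len(labels)))
    idx = rng.permutation(len(labels))
    left = [labels[i] for i in sorted(idx[:k])]
    right = [labels[i] for i in sorted(idx[k:])]
    return f"({_random_bifurcation(left, rng)},{_random_bifurcation(right, rng)})"


def _mutate(seq: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    hits = np.nonzero(rng.random(seq.size) < p)[0]
    for i in hits:
        # uniform over the 3 alternative bases
        out[i] = (out[i] + 1 + rng.integers(0, 3)) % 4
    return out


def simulate_family(spec: FamilySimSpec) -> tuple[list[GeneRecord], FamilyTree]:
    """Generate one gene family's leaf CDSs plus its true tree."""
    rng = np.random.default_rng(spec.seed)
    labels = [
        f"{spec.family_id}_G{i + 1:02d}" for i in range(spec.n_genes)
    ]
    if spec.tree == "random":
        newick = _random_bifurcation(labels, rng) + ";"
    else:
        newick = spec.tree
    tree = FamilyTree.from_newick(newick)
    if set(tree.leaf_labels) != set(labels):
        raise ValidationError(
            "provided tree leaves do not match the generated gene IDs"
        )
    n_codons = spec.cds_length // 3
    codon_idx = rng.integers(0, len(_SENSE_CODONS), size=n_codons)
    root_seq = "".join(_SENSE_CODONS[i] for i in codon_idx)
    root_codes = np.array([{"A": 0, "C": 1, "G": 2, "T": 3}[b] for b in root_seq])

    seqs: dict[str, np.ndarray] = {}

    def walk(node, seq_codes: np.ndarray) -> None:
        # children in stored order so output is a pure function of the seed
        for child in (node.children or []):
            child_seq = _mutate(seq_codes, spec.per_branch_sub_prob, rng)
            if child.is_leaf:
                seqs[child.label] = child_seq
            else:
                walk(child, child_seq)

    walk(tree.root, root_codes)
    records = [
        GeneRecord(
            gene_id=lab,
            family_id=spec.family_id,
            class_label=spec.class_label,
            cds="".join("ACGT"[c] for c in seqs[lab]),
        )
        for lab in labels
    ]
    return records, tree


def simulate_panel(
    seed: int = 42,
    n_families: int = 5,
    family_sizes: Sequence[int] = (8, 10, 12, 14, 16),
    cds_length: int = 600,
    per_branch_sub_prob: float = 0.02,
) -> list[tuple[list[GeneRecord], FamilyTree]]:
    """Standard end-to-end test panel: several families spanning 8-16
    paralogs, one functional class each, seeded reproducibly."""
    ss = np.random.SeedSequence(seed)
    panel = []
    for i, child in enumerate(ss.spawn(n_families)):
        spec = FamilySimSpec(
            n_genes=family_sizes[i % len(family_sizes)],
            cds_length=cds_length,
            per_branch_sub_prob=per_branch_sub_prob,
            seed=int(child.generate_state(1)[0] % 2**31),
            family_id=f"FAM{i + 1}",
            class_label=CLASS_LABELS[i % len(CLASS_LABELS)],
        )
        panel.append(simulate_family(spec))
    return panel


def simulate_reads(
    library: Sequence[LibraryEntry],
    depth_spec,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Amplicon reads over a library: one full-oligo read per sampled copy.

    ``depth_spec`` is ``("uniform", k)`` (exactly k reads per member),
    ``("lognormal", mu, sigma)`` (depth ceil of a lognormal draw per
    member), or a per-member integer vector.  Read orientation is random;
    output order is interleaved deterministically from the seed.
    """
    if not library:
        raise ValidationError("simulate_reads needs a non-empty library")
    rng = np.random.default_rng(seed)
    if isinstance(depth_spec, tuple) and depth_spec[0] == "uniform":
        depths = [int(depth_spec[1])] * len(library)
    elif isinstance(depth_spec, tuple) and depth_spec[0] == "lognormal":
        _, mu, sigma = depth_spec
        depths = np.ceil(rng.lognormal(mu, sigma, size=len(library))).astype(int)
        depths = list(depths)
    else:
        depths = [int(d) for d in depth_spec]
        if len(depths) != len(library):
            raise ValidationError("custom depth vector length mismatch")
    reads: list[tuple[str, str]] = []
    for entry, depth in zip(library, depths):
        for i in range(depth):
            seq = entry.oligo
            if rng.random() < 0.5:
                seq = revcomp(seq)
            reads.append((f"{entry.amirna_id}_read{i + 1}", seq))
    order = rng.permutation(len(reads))
    return [reads[i] for i in order]


def write_reads_fasta(reads: Sequence[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f">{rid}\n{seq}\n")


def write_reads_fastq(reads: Sequence[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
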