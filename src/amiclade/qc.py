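"""Library representation QC from amplicon sequencing, plus design summaries.

After pooled synthesis and cloning, the library is amplicon-sequenced to
verify that every member is present (*coverage*: percent of members seen in
at least one read) and evenly represented (*skew*: adjusted Fisher-Pearson
sample skewness of per-member read fractions — 0 for a perfectly uniform
pool, positive when a few members soak up most reads).

Read assignment is exact-substring: a read counts for a member iff it
contains that member's identifying 21-mer (the mature antisense arm by
default) in either orientation; reads matching zero or several members are
left unassigned.  A Hamming-distance-1 rescue exists behind a flag.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .assembly import LibraryEntry
from .phylo import FamilyTree
from .seqio import ValidationError, revcomp

logger = logging.getLogger(__name__)


@dataclass
class ReadCountTable:
    """Per-library-member amplicon read counts."""

    counts: dict[str, int]
    total_reads: int
    unassigned: int

    def __post_init__(self) -> None:
        if sum(self.counts.values()) + self.unassigned != self.total_reads:
            raise ValidationError("read counts do not partition total_reads")


def _iter_reads(reads) -> Iterable[str]:
    """Accept a FASTA/FASTQ path or an iterable of (id, seq) / seq strings."""
    if isinstance(reads, (str, Path)):
        fmt = "fastq" if str(reads).endswith(("fastq", "fq")) else "fasta"
        for rec in SeqIO.parse(str(reads), fmt):
            yield str(rec.seq).upper()
        return
    for r in reads:
        if isinstance(r, str):
            yield r.upper()
        else:
            yield str(r[1]).upper()


def _member_keys(
    library: Sequence[LibraryEntry], match_region: str
) -> dict[str, str]:
    if match_region == "mature":
        return {e.amirna_id: e.candidate.mature for e in library}
    if match_region == "precursor":
        return {e.amirna_id: e.precursor for e in library}
    if match_region == "oligo":
        return {e.amirna_id: e.oligo for e in library}
    raise ValidationError(f"unknown match region {match_region!r}")


def _neighbors1(kmer: str) -> Iterable[str]:
    for i, orig in enumerate(kmer):
        for b in "ACGT":
            if b != orig:
                yield kmer[:i] + b + kmer[i + 1 :]


def count_reads(
    reads,
    library: Sequence[LibraryEntry],
    match_region: str = "mature",
    hamming1_rescue: bool = False,
) -> ReadCountTable:
    """Assign reads to library members by exact k-mer containment.

    A read is assigned iff exactly one member's identifying k-mer occurs in
    the read or its reverse complement; ambiguous and unmatched reads are
    counted as unassigned.
    """
    if not library:
        raise ValidationError("count_reads needs a non-empty library")
    keys = _member_keys(library, match_region)
    k = len(next(iter(keys.values())))
    lookup: dict[str, set[str]] = {}
    for member, kmer in keys.items():
        lookup.setdefault(kmer, set()).add(member)
        if hamming1_rescue:
            for nb in _neighbors1(kmer):
                lookup.setdefault(nb, set()).add(member)
    counts = {m: 0 for m in keys}
    total = 0
    unassigned = 0
    for seq in _iter_reads(reads):
        total += 1
        hits: set[str] = set()
        for s in (seq, revcomp(seq)):
            for i in range(len(s) - k + 1):
                members = lookup.get(s[i : i + k])
                if members:
                    hits |= members
        if len(hits) == 1:
            counts[hits.pop()] += 1
        else:
            unassigned += 1
    if total == 0:
        logger.warning("no reads supplied; returning an all-zero table")
    return ReadCountTable(counts=counts, total_reads=total, unassigned=unassigned)


def coverage(table: ReadCountTable, library: Sequence[LibraryEntry]) -> float:
    """Percent of library members detected with at least one read."""
    if not library:
        raise ValidationError("coverage needs a non-empty library")
    detected = sum(
        1 for e in library if table.counts.get(e.amirna_id, 0) >= 1
    )
    return 100.0 * detected / len(library)


def skew(table: ReadCountTable) -> float:
    """Adjusted Fisher-Pearson sample skewness of per-member read fractions.

    Exactly 0 for a perfectly uniform pool; positive when reads pile onto a
    right tail of members.  Undefined (error) with no assigned reads or
    fewer than 3 members.
    """
    x = np.array(list(table.counts.values()), dtype=float)
    n = x.size
    if n < 3:
        raise ValidationError("skew needs at least 3 library members")
    assigned = x.sum()
    if assigned == 0:
        raise ValidationError("skew undefined: no assigned reads")
    if x.max() == x.min():  # exactly uniform: skew is 0 by symmetry
        return 0.0
    f = x / assigned
    m = f.mean()
    m2 = ((f - m) ** 2).mean()
    if m2 == 0.0:
        return 0.0
    m3 = ((f - m) ** 3).mean()
    g1 = m3 / m2**1.5
    return float(g1 * math.sqrt(n * (n - 1)) / (n - 2))


def summary_stats(
    library: Sequence[LibraryEntry],
    trees: Mapping[str, FamilyTree] | None = None,
) -> dict[str, pd.DataFrame]:
    """Design-summary histograms for a built library.

    Returns TSV-ready DataFrames: targets per guide, guides per internal
    node (keyed family/node), guides per gene, and per-class totals.
    """
    tpa = pd.Series(
        [len(e.candidate.effective_targets) for e in library], name="n_targets"
    ).value_counts().sort_index()
    per_node = pd.Series(
        [
            (e.family_id, e.candidate.origin_node) for e in library
        ]
    ).value_counts().sort_index()
    per_gene: dict[str, int] = {}
    for e in library:
        for g in e.candidate.effective_targets:
            per_gene[g] = per_gene.get(g, 0) + 1
    per_class = pd.Series(
        [e.class_label for e in library], name="class_label"
    ).value_counts().sort_index()
    return {
        "targets_per_amirna": tpa.rename_axis("n_targets").reset_index(
            name="n_amirnas"
        ),
        "amirnas_per_node": pd.DataFrame(
            [
                {"family_id": f, "node_id": n, "n_amirnas": c}
                for (f, n), c in per_node.items()
            ]
        ),
        "amirnas_per_gene": pd.DataFrame(
            sorted(per_gene.items()), columns=["gene_id", "n_amirnas"]
        ),
        "per_class_totals": per_class.rename_axis("class_label").reset_index(
            name="n_amirnas"
        ),
    }


def write_summary(
    summaries: Mapping[str, pd.DataFrame], out_prefix: str | Path
) -> list[Path]:
    out_prefix = Path(out_prefix)
    paths = []
    for name, df in summaries.items():
        p = out_prefix.parent / f"{out_prefix.name}.{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths.append(p)
    return paths
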