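"""Reading and writing of all external formats, plus run configuration.

Conventions used throughout the package:

* every sequence is held internally in the DNA alphabet (``ACGT``, ``T``
  rather than ``U``); mature guide strands gain a parallel RNA spelling only
  at export,
* coordinates are 0-based half-open on the sense strand of the CDS,
* internal tree nodes carry stable integer IDs assigned by deterministic
  post-order numbering (see :mod:`amiclade.phylo`).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO

from . import phylo

logger = logging.getLogger(__name__)

#: Fixed functional-class vocabulary for transporter sub-libraries:
#: channels and porins; amino-acid/polyamine/organo-cation carriers; major
#: facilitator superfamily; drug/metabolite transporters; MATE and other
#: carriers; ABC family; primary active transporters; unknown function.
CLASS_LABELS = ("CP", "APC", "MFS", "DMT", "MATE", "ABC", "PA", "UF")

DNA_ALPHABET = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (uppercase ACGT)."""
    return seq.translate(_COMPLEMENT)[::-1]


def to_rna(seq: str) -> str:
    """RNA spelling of a DNA string (T -> U); used at export only."""
    return seq.replace("T", "U")


class ValidationError(ValueError):
    """Input violates a documented invariant."""


class FormatError(ValueError):
    """A file could not be parsed in its declared format."""


@dataclass(frozen=True)
class GeneRecord:
    """One gene: identifier, family membership, functional class, CDS."""

    gene_id: str
    family_id: str
    class_label: str
    cds: str

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValidationError(
                f"gene {self.gene_id!r}: class {self.class_label!r} not in "
                f"{CLASS_LABELS}"
            )
        if len(self.cds) < 21:
            raise ValidationError(
                f"gene {self.gene_id!r}: CDS shorter than 21 nt"
            )
        bad = set(self.cds) - DNA_ALPHABET
        if bad:
            raise ValidationError(
                f"gene {self.gene_id!r}: CDS contains non-ACGT characters "
                f"{sorted(bad)} (ambiguity codes are rejected)"
            )


def _default_score_weights() -> dict[str, float]:
    return {"w_frac": 1.0, "w_off": 1.0, "w_comp": 0.1}


def _default_forbidden() -> list[str]:
    # BsaI recognition site and its reverse complement; internal type IIS
    # sites would be cut during Golden Gate assembly.
    return ["GGTCTC", "GAGACC"]


# Synthetic stand-in for a miR159a-style precursor backbone: 5' arm, mature
# (antisense) arm, loop, star (sense) arm, 3' arm.  The true backbone arms
# are not modelled; any real template can be supplied through the config.
DEFAULT_BACKBONE_TEMPLATE = (
    "CTGCAAGTTCATCACTAACCTTCAA"
    "{MATURE}"
    "TCTCTTCTTGTATTCCT"
    "{STAR}"
    "ACAAGTTGAATGGAATCTTACAACA"
)


def default_adaptor_table() -> dict[str, tuple[str, str]]:
    """Packaged default class→(fwd, rev) adaptor table (synthetic)."""
    path = resources.files("amiclade.data").joinpath("adaptors.tsv")
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t", comment="#")
    return {r["class"]: (r["fwd"], r["rev"]) for _, r in df.iterrows()}


@dataclass
class DesignConfig:
    """All tunable parameters of the design pipeline.

    Defaults follow the published design constraints: an energy-fraction
    threshold omega = 0.75, at most ``node_budget_x`` = 8 guides per internal
    node, a minimum lineage Hamming distance ``min_diff_m`` = 2, candidate
    generation only for subfamilies of at most ``max_subfamily_n`` = 11
    genes, rescue-phase cluster distance at most ``cluster_dist_max`` = 3
    internal nodes, and at most ``max_targets`` = 8 effective targets per
    guide.
    """

    omega: float = 0.75
    node_budget_x: int = 8
    min_diff_m: int = 2
    max_subfamily_n: int = 11
    cluster_dist_max: int = 3
    mature_length: int = 21
    max_targets: int = 8
    gc_min: float = 0.30
    gc_max: float = 0.70
    max_homopolymer: int = 5  # runs of length >= 6 are rejected
    forbidden_sites: list[str] = field(default_factory=_default_forbidden)
    blacklist_path: str | None = None
    backbone_template: str = DEFAULT_BACKBONE_TEMPLATE
    adaptor_table: dict[str, tuple[str, str]] = field(
        default_factory=default_adaptor_table
    )
    star_mismatch_positions: tuple[int, ...] = ()
    score_weights: dict[str, float] = field(
        default_factory=_default_score_weights
    )
    replace_similar: bool = False
    enforce_unique_arms: bool = True
    allow_similar_better: bool = True  # rule (b); disable to enforce rule (a)
    exclude_off_targets: bool = True
    backfill_after_restriction_filter: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.omega <= 1.0):
            raise ValidationError(f"omega must be in (0, 1], got {self.omega}")
        for name in ("node_budget_x", "min_diff_m", "max_subfamily_n",
                     "mature_length", "max_targets"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if self.cluster_dist_max < 0:
            raise ValidationError("cluster_dist_max must be >= 0")
        sites = [s.upper() for s in self.forbidden_sites]
        for s in sites:
            if not set(s) <= DNA_ALPHABET:
                raise ValidationError(f"forbidden site {s!r} is not DNA")
        # every motif's reverse complement is screened too
        for s in list(sites):
            rc = revcomp(s)
            if rc not in sites:
                sites.append(rc)
        self.forbidden_sites = sites

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DesignConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "adaptor_table" in raw:
            raw["adaptor_table"] = {
                k: tuple(v) for k, v in raw["adaptor_table"].items()
            }
        if "star_mismatch_positions" in raw:
            raw["star_mismatch_positions"] = tuple(
                raw["star_mismatch_positions"]
            )
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["adaptor_table"] = {
            k: list(v) for k, v in self.adaptor_table.items()
        }
        data["star_mismatch_positions"] = list(self.star_mismatch_positions)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def read_gene_set(
    fasta_path: str | Path, annotation_tsv_path: str | Path
) -> list[GeneRecord]:
    """Load a gene set from FASTA plus a gene→family→class annotation TSV.

    Genes present in the FASTA but lacking an annotation row are reported to
    the log and dropped.  An empty intersection is fatal.
    """
    try:
        seqs = {
            rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(fasta_path), "fasta")
        }
    except ValueError as exc:  # Bio.SeqIO raises ValueError on bad FASTA
        raise FormatError(f"malformed FASTA {fasta_path}: {exc}") from exc
    if not seqs:
        raise FormatError(f"no sequences parsed from {fasta_path}")

    ann = pd.read_csv(annotation_tsv_path, sep="\t", dtype=str)
    for col in ("gene_id", "family_id", "class_label"):
        if col not in ann.columns:
            raise FormatError(
                f"annotation {annotation_tsv_path} lacks column {col!r}"
            )
    ann = ann.set_index("gene_id")
    if ann.index.has_duplicates:
        dups = ann.index[ann.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate gene_id in annotation: {dups}")

    dropped = sorted(set(seqs) - set(ann.index))
    if dropped:
        logger.warning(
            "%d gene(s) in FASTA lack annotation and were dropped: %s",
            len(dropped), ", ".join(dropped),
        )
    kept = [g for g in seqs if g in ann.index]
    if not kept:
        raise ValidationError(
            "no gene is present in both the FASTA and the annotation table"
        )
    return [
        GeneRecord(
            gene_id=g,
            family_id=ann.at[g, "family_id"],
            class_label=ann.at[g, "class_label"],
            cds=seqs[g],
        )
        for g in kept
    ]


def read_tree(
    newick_path: str | Path, expected_leaf_ids: Iterable[str]
) -> "phylo.FamilyTree":
    """Parse a rooted Newick gene tree and check its leaves against a gene set.

    An unrooted trifurcation at the root is accepted; the root is then simply
    an internal node with three children.  Leaf labels must equal
    ``expected_leaf_ids`` exactly.
    """
    with open(newick_path) as fh:
        newick = fh.read()
    tree = phylo.FamilyTree.from_newick(newick)
    expected = set(expected_leaf_ids)
    got = set(tree.leaf_labels)
    if got != expected:
        missing = sorted(expected - got)
        extra = sorted(got - expected)
        raise ValidationError(
            f"tree/gene set mismatch for {newick_path}: "
            f"missing from tree {missing}, extra in tree {extra}"
        )
    return tree


#: Fixed column order of the library TSV; documented part of the interface.
LIBRARY_COLUMNS = [
    "amirna_id",
    "mature",
    "mature_rna",
    "star",
    "targets",
    "fractions",
    "origin_node",
    "phase",
    "class_label",
    "family_id",
    "oligo",
]


def write_library(entries: Sequence, out_prefix: str | Path) -> tuple[Path, Path]:
    """Write library entries as ``<prefix>.tsv`` plus ``<prefix>.fasta``.

    The TSV carries one row per entry in :data:`LIBRARY_COLUMNS` order;
    the FASTA holds the full synthesis oligos keyed by amiRNA ID.  Target
    gene IDs and their energy fractions are comma-joined in matching order.
    """
    if not entries:
        raise ValidationError("refusing to write an empty library")
    out_prefix = Path(out_prefix)
    rows = []
    for e in entries:
        genes = sorted(e.candidate.effective_targets)
        rows.append(
            {
                "amirna_id": e.amirna_id,
                "mature": e.candidate.mature,
                "mature_rna": to_rna(e.candidate.mature),
                "star": e.star,
                "targets": ",".join(genes),
                "fractions": ",".join(
                    f"{e.candidate.effective_targets[g]:.6f}" for g in genes
                ),
                "origin_node": e.candidate.origin_node,
                "phase": e.candidate.phase,
                "class_label": e.class_label,
                "family_id": e.family_id,
                "oligo": e.oligo,
            }
        )
    df = pd.DataFrame(rows, columns=LIBRARY_COLUMNS)
    tsv_path = out_prefix.with_suffix(".tsv")
    fasta_path = out_prefix.with_suffix(".fasta")
    df.to_csv(tsv_path, sep="\t", index=False)
    with open(fasta_path, "w") as fh:
        for e in entries:
            fh.write(f">{e.amirna_id}\n{e.oligo}\n")
    return tsv_path, fasta_path


def read_library(tsv_path: str | Path) -> pd.DataFrame:
    """Read a library TSV back into a DataFrame (lossless round-trip)."""
    df = pd.read_csv(
        tsv_path, sep="\t", dtype={c: str for c in LIBRARY_COLUMNS}
    )
    missing = [c for c in LIBRARY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"library TSV lacks columns {missing}")
    df["origin_node"] = df["origin_node"].astype(int)
    return df


def read_blacklist(path: str | Path, mature_length: int = 21) -> set[str]:
    """Load a guide blacklist: one 21-mer per line; wrong-length entries are
    ignored with a warning."""
    out: set[str] = set()
    with open(path) as fh:
        for line in fh:
            s = line.strip().upper().split("\t")[0]
            if not s or s.startswith("#"):
                continue
            if len(s) != mature_length or not set(s) <= DNA_ALPHABET:
                logger.warning("ignoring malformed blacklist entry %r", s)
                continue
            out.add(s)
    return out
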