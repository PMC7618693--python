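"""Oligo assembly: backbone insertion, star strand, class adaptors, and the
post-assembly restriction-site screen.

Each selected guide is turned into an orderable synthesis oligo:

    fwd_adaptor + 5'arm + MATURE + loop + STAR + 3'arm + rev_adaptor

where the star (passenger) strand is the reverse complement of the mature
guide, optionally with backbone-specified mismatch substitutions, and the
adaptor pair is unique per functional class so any sub-library can be
amplified from the pooled synthesis.  Oligos containing a type IIS (BsaI)
recognition site on either strand would self-destruct in Golden Gate
cloning and are removed (the cloning flanks themselves are assumed to live
outside the modelled oligo).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .design import Candidate, SelectionState
from .phylo import FamilyTree
from .seqio import CLASS_LABELS, DesignConfig, ValidationError, revcomp

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid backbone template or adaptor table."""


@dataclass(frozen=True)
class LibraryEntry:
    """One assembled library member."""

    amirna_id: str
    candidate: Candidate
    star: str
    precursor: str
    fwd_adaptor: str
    rev_adaptor: str
    oligo: str
    class_label: str
    family_id: str


# substitution used to engineer a star mismatch: deterministic transversion
_STAR_SUB = str.maketrans("ACGT", "CATG")


def make_star(mature: str, mismatch_positions: Sequence[int] = ()) -> str:
    """Star (passenger) strand: reverse complement of the mature guide, with
    a deterministic transversion at each backbone-specified 1-based
    position.  With no positions (the default) this is an involution."""
    star = list(revcomp(mature))
    for pos in mismatch_positions:
        if not 1 <= pos <= len(star):
            raise ConfigError(f"star mismatch position {pos} out of range")
        star[pos - 1] = star[pos - 1].translate(_STAR_SUB)
    return "".join(star)


def assemble_precursor(mature: str, star: str, backbone_template: str) -> str:
    """Substitute the mature and star arms into the backbone template.

    The template must contain exactly one ``{MATURE}`` and one ``{STAR}``
    placeholder."""
    for ph in ("{MATURE}", "{STAR}"):
        n = backbone_template.count(ph)
        if n != 1:
            raise ConfigError(
                f"backbone template must contain exactly one {ph} "
                f"placeholder (found {n})"
            )
    return backbone_template.replace("{MATURE}", mature).replace(
        "{STAR}", star
    )


def validate_adaptor_table(
    adaptor_table: Mapping[str, tuple[str, str]], backbone_template: str
) -> None:
    """Load-time checks: no adaptor is a substring of another class's
    adaptors or of the backbone constant regions."""
    flat: list[tuple[str, str]] = []
    for cls, (fwd, rev) in adaptor_table.items():
        if cls not in CLASS_LABELS:
            raise ConfigError(f"unknown class {cls!r} in adaptor table")
        flat.append((cls, fwd.upper()))
        flat.append((cls, rev.upper()))
    backbone = backbone_template.replace("{MATURE}", " ").replace("{STAR}", " ")
    for i, (cls_a, a) in enumerate(flat):
        if a in backbone:
            raise ConfigError(
                f"adaptor {a} of class {cls_a} occurs in the backbone"
            )
        for cls_b, b in flat[i + 1 :]:
            if cls_a == cls_b:
                continue
            if a in b or b in a:
                raise ConfigError(
                    f"adaptor collision between classes {cls_a} and {cls_b}: "
                    f"{a} / {b}"
                )


def attach_adaptors(
    precursor: str,
    class_label: str,
    adaptor_table: Mapping[str, tuple[str, str]],
) -> str:
    """Flank a precursor with its class's forward and reverse adaptors."""
    try:
        fwd, rev = adaptor_table[class_label]
    except KeyError:
        raise ConfigError(
            f"class {class_label!r} missing from adaptor table"
        ) from None
    return fwd + precursor + rev


def assemble_library(
    selected: Sequence[tuple[int, int, Candidate]],
    genes_by_id: Mapping[str, "object"],
    family_id: str,
    config: DesignConfig,
) -> list[LibraryEntry]:
    """Assemble every selected candidate of one family into a LibraryEntry.

    The class label is taken from the family's genes (one family maps to a
    single functional class).  Entry IDs are deterministic:
    ``<family>.n<node>.<rank>``.
    """
    if not selected:
        return []
    validate_adaptor_table(config.adaptor_table, config.backbone_template)
    classes = {genes_by_id[g].class_label
               for _, _, c in selected for g in c.effective_targets}
    if len(classes) != 1:
        raise ValidationError(
            f"family {family_id}: targets span classes {sorted(classes)}"
        )
    class_label = classes.pop()
    entries = []
    for node_id, rank, cand in selected:
        star = make_star(cand.mature, config.star_mismatch_positions)
        precursor = assemble_precursor(
            cand.mature, star, config.backbone_template
        )
        oligo = attach_adaptors(precursor, class_label, config.adaptor_table)
        if oligo.count(cand.mature) != 1:
            logger.warning(
                "dropping %s.n%02d.%02d: mature arm not unique in oligo",
                family_id, node_id, rank,
            )
            continue
        entries.append(
            LibraryEntry(
                amirna_id=f"{family_id}.n{node_id:02d}.{rank:02d}",
                candidate=cand,
                star=star,
                precursor=precursor,
                fwd_adaptor=config.adaptor_table[class_label][0],
                rev_adaptor=config.adaptor_table[class_label][1],
                oligo=oligo,
                class_label=class_label,
                family_id=family_id,
            )
        )
    return entries


def filter_restriction_sites(
    entries: Sequence[LibraryEntry], forbidden_sites: Iterable[str]
) -> list[LibraryEntry]:
    """Remove entries whose full oligo contains any forbidden motif.

    Motifs are matched in forward orientation only; the config guarantees
    every motif's reverse complement is itself in the list, which covers
    the other strand."""
    motifs = [m.upper() for m in forbidden_sites]
    kept = []
    for e in entries:
        hit = None
        for m in motifs:
            pos = e.oligo.find(m)
            if pos != -1:
                hit = (m, pos)
                break
        if hit:
            logger.info(
                "restriction filter removed %s: motif %s at %d",
                e.amirna_id, hit[0], hit[1],
            )
        else:
            kept.append(e)
    return kept


def enforce_unique_arms(entries: Sequence[LibraryEntry]) -> list[LibraryEntry]:
    """Keep only entries whose identifying mature arm is unique library-wide.

    Exact-substring read assignment needs each member's 21-nt arm to occur
    in no other member's oligo (either orientation).  Overlapping CDS-window
    guides can collide when a backbone junction recreates a shifted arm;
    entries are scanned in order and a later entry is dropped if its arm
    occurs in an earlier oligo or an earlier arm occurs in its oligo.
    """
    kept: list[LibraryEntry] = []
    kept_kmers: set[str] = set()  # all arm-length k-mers of kept oligos
    kept_arms: set[str] = set()

    def oligo_kmers(oligo: str, k: int) -> set[str]:
        rc = revcomp(oligo)
        return {
            s[i : i + k]
            for s in (oligo, rc)
            for i in range(len(s) - k + 1)
        }

    for e in entries:
        k = len(e.candidate.mature)
        kmers = oligo_kmers(e.oligo, k)
        if e.candidate.mature in kept_kmers or kmers & kept_arms:
            logger.info(
                "dropping %s: mature arm collides with an earlier entry",
                e.amirna_id,
            )
            continue
        kept.append(e)
        kept_kmers |= kmers
        kept_arms.add(e.candidate.mature)
    return kept


def export_network(entries: Sequence[LibraryEntry], out_path: str | Path) -> Path:
    """Write the guide→target bipartite graph as a SIF-compatible TSV:
    one ``amirna_id<TAB>targets<TAB>gene_id`` row per edge."""
    if not entries:
        raise ValidationError("refusing to export an empty network")
    out_path = Path(out_path)
    with open(out_path, "w") as fh:
        for e in entries:
            for g in sorted(e.candidate.effective_targets):
                fh.write(f"{e.amirna_id}\ttargets\t{g}\n")
    return out_path
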