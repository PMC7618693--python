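"""End-to-end orchestration: design + assembly over one or many families."""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

from . import assembly, design, thermo
from .assembly import LibraryEntry, enforce_unique_arms, filter_restriction_sites
from .phylo import FamilyTree
from .seqio import DesignConfig, GeneRecord

logger = logging.getLogger(__name__)


def design_and_assemble_family(
    genes: Sequence[GeneRecord],
    tree: FamilyTree,
    config: DesignConfig,
    model: thermo.DuplexModel | None = None,
    background: Mapping[str, str] | None = None,
    blacklist: set[str] | None = None,
) -> list[LibraryEntry]:
    """Design guides for one family, assemble oligos, apply the
    restriction-site screen, optionally back-fill nodes that lost entries."""
    model = model or thermo.load_model()
    family_id = genes[0].family_id
    genes_by_id = {g.gene_id: g for g in genes}
    state, selected = design.design_family(
        genes, tree, config, model=model,
        background=background, blacklist=blacklist,
    )
    entries = assembly.assemble_library(selected, genes_by_id, family_id, config)
    kept = filter_restriction_sites(entries, config.forbidden_sites)
    if config.backfill_after_restriction_filter and len(kept) < len(entries):
        kept = _backfill(
            kept, entries, genes, tree, state, config, model,
            background, blacklist, genes_by_id, family_id,
        )
    if config.enforce_unique_arms:
        kept = enforce_unique_arms(kept)
    return kept


def _backfill(
    kept: list[LibraryEntry],
    entries: list[LibraryEntry],
    genes: Sequence[GeneRecord],
    tree: FamilyTree,
    state: design.SelectionState,
    config: DesignConfig,
    model: thermo.DuplexModel,
    background: Mapping[str, str] | None,
    blacklist: set[str] | None,
    genes_by_id,
    family_id: str,
) -> list[LibraryEntry]:
    """Re-open selection for nodes that lost entries to the restriction
    screen, admitting alternatives whose assembled oligos are clean."""
    lost = {e.amirna_id for e in entries} - {e.amirna_id for e in kept}
    affected = {e.candidate.origin_node for e in entries if e.amirna_id in lost}
    # drop the filtered candidates from the state, then retry admission
    removed_matures = {
        e.candidate.mature for e in entries if e.amirna_id in lost
    }
    for nid, lst in state.chosen.items():
        lst[:] = [c for c in lst if c.mature not in removed_matures]
    evaluation = design.FamilyEvaluation(genes, config, model, background)
    refill_rank = {nid: 0 for nid in affected}
    new_entries: list[LibraryEntry] = []
    for node in tree.preorder_internal():
        nid = node.node_id
        if nid not in affected:
            continue
        pool = design.generate_candidates(
            tree, genes, node, background, config,
            model=model, evaluation=evaluation,
        )
        pool = design.apply_blacklist(pool, blacklist)
        chosen_matures = {c.mature for c in state.all_chosen()}
        for cand in design.rank_candidates(pool):
            if len(state.node_chosen(nid)) >= config.node_budget_x:
                break
            if cand.mature in chosen_matures or cand.mature in removed_matures:
                continue
            # tentative assembly: only admit if the oligo is clean
            trial = assembly.assemble_library(
                [(nid, 90 + refill_rank[nid], cand)],
                genes_by_id, family_id, config,
            )
            trial = filter_restriction_sites(trial, config.forbidden_sites)
            if not trial:
                continue
            if design._try_admit(state, nid, cand, config):
                refill_rank[nid] += 1
                new_entries.extend(trial)
                chosen_matures.add(cand.mature)
    if new_entries:
        logger.info("back-fill restored %d entr(ies)", len(new_entries))
    return kept + new_entries


def build_library(
    families: Sequence[tuple[Sequence[GeneRecord], FamilyTree]],
    config: DesignConfig,
    model: thermo.DuplexModel | None = None,
    background: Mapping[str, str] | None = None,
    blacklist: set[str] | None = None,
) -> list[LibraryEntry]:
    """Design and assemble all families; concatenated in input order."""
    model = model or thermo.load_model()
    out: list[LibraryEntry] = []
    for genes, tree in families:
        entries = design_and_assemble_family(
            genes, tree, config, model=model,
            background=background, blacklist=blacklist,
        )
        logger.info(
            "family %s: %d library entries", genes[0].family_id, len(entries)
        )
        out.extend(entries)
    if config.enforce_unique_arms:
        out = enforce_unique_arms(out)  # cross-family arm collisions
    return out
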