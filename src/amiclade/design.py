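"""Candidate guide generation and the node-budgeted selection algorithm.

The design walks a gene family's tree.  Every internal node induces a
subfamily; for each subfamily of 2..``max_subfamily_n`` genes, candidate
21-nt guides are derived from the subfamily members' own CDS windows
(reverse complement of each window, with the 5'-terminal base forced to T —
the canonical 5'-U of plant miRNAs — recorded as an engineered mismatch
when it differs).  A gene is an *effective target* of a candidate when its
best site is admissible and has energy fraction >= omega; candidates need
at least two effective targets (step 1).

Selection (step 2) visits nodes root->leaves and admits ranked candidates
until each node holds ``node_budget_x`` guides.  A candidate is admitted if
(a) its sequence differs by >= ``min_diff_m`` substitutions from every guide
already chosen at the node or any ancestor, or (b) it is similar to such a
guide but strictly out-scores every similar one.  A rescue phase (step 3)
then generates candidates over the whole family, ascribes each to the MRCA
of its effective targets, and admits it into under-filled nodes provided
the targets' maximal monophyletic clusters are pairwise within
``cluster_dist_max`` internal nodes of each other.  Finally a guide
blacklist is applied (step 4); restriction-site screening (step 5) happens
after oligo assembly in :mod:`amiclade.assembly`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from . import phylo, thermo
from .phylo import FamilyTree, Node
from .seqio import DesignConfig, GeneRecord, revcomp

logger = logging.getLogger(__name__)

NODE_PHASE = "node_phase"
MRCA_PHASE = "mrca_phase"


@dataclass
class Candidate:
    """A 21-nt mature guide with its evaluated target set."""

    mature: str
    origin_node: int
    phase: str
    effective_targets: dict[str, float]  # gene_id -> energy fraction
    score: float
    off_target_count: int = 0


@dataclass
class SelectionState:
    """Per-node chosen guides accumulated over both selection phases."""

    tree: FamilyTree
    chosen: dict[int, list[Candidate]] = field(default_factory=dict)

    def node_chosen(self, node_id: int) -> list[Candidate]:
        return self.chosen.setdefault(node_id, [])

    def lineage_chosen(self, node_id: int) -> list[Candidate]:
        """Guides chosen at ``node_id`` or any of its ancestors."""
        node = self.tree.node(node_id)
        out = list(self.chosen.get(node_id, ()))
        for anc in self.tree.ancestors(node):
            out.extend(self.chosen.get(anc.node_id, ()))
        return out

    def comparable_chosen(self, node_id: int) -> list[Candidate]:
        """Guides chosen at any node on a root-to-leaf path through
        ``node_id``: the node itself, its ancestors, and its descendants.

        During the top-down node phase descendants are still empty, so this
        coincides with :meth:`lineage_chosen`; the rescue phase fills nodes
        out of top-down order and must also stay dissimilar from picks
        already made below."""
        node = self.tree.node(node_id)
        out = self.lineage_chosen(node_id)
        stack = list(node.children)
        while stack:
            n = stack.pop()
            if n.is_leaf:
                continue
            out.extend(self.chosen.get(n.node_id, ()))
            stack.extend(n.children)
        return out

    def all_chosen(self) -> list[Candidate]:
        return [c for lst in self.chosen.values() for c in lst]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance needs equal-length strings")
    return sum(x != y for x, y in zip(a, b))


# ---------------------------------------------------------------------------
# candidate sequence derivation and composition screening


def gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def max_run(seq: str) -> int:
    best = run = 1
    for prev, cur in zip(seq, seq[1:]):
        run = run + 1 if cur == prev else 1
        best = max(best, run)
    return best


def passes_composition(mature: str, config: DesignConfig) -> bool:
    gc = gc_fraction(mature)
    if not (config.gc_min <= gc <= config.gc_max):
        return False
    return max_run(mature) <= config.max_homopolymer


def matures_from_cds(cds: str, config: DesignConfig) -> list[str]:
    """Candidate guides from every window of a CDS: reverse complement with
    the 5'-terminal base forced to T; composition-filtered, deduplicated,
    sorted."""
    L = config.mature_length
    out = set()
    for start in range(len(cds) - L + 1):
        m = revcomp(cds[start : start + L])
        if m[0] != "T":
            m = "T" + m[1:]
        if passes_composition(m, config):
            out.add(m)
    return sorted(out)


# ---------------------------------------------------------------------------
# family-wide evaluation cache


class FamilyEvaluation:
    """Best-site evaluations of every candidate guide against every family
    gene (and background transcripts), computed once per family.

    Node- and rescue-phase candidate generation both draw on CDS-window
    guides, so the (guide, gene) evaluation matrix is shared.
    """

    def __init__(
        self,
        genes: Sequence[GeneRecord],
        config: DesignConfig,
        model: thermo.DuplexModel,
        background: Mapping[str, str] | None = None,
    ):
        self.genes = list(genes)
        self.config = config
        self.model = model
        self.matures_by_gene: dict[str, list[str]] = {
            g.gene_id: matures_from_cds(g.cds, config) for g in self.genes
        }
        self.all_matures: list[str] = sorted(
            set().union(*self.matures_by_gene.values())
        ) if self.genes else []
        # fraction+admissibility of each guide's best site on each gene
        self.site: dict[str, dict[str, thermo.HybridEvaluation]] = {
            m: {} for m in self.all_matures
        }
        for g in self.genes:
            evals = thermo.best_sites_batch(model, self.all_matures, g.cds)
            for m, (ev, _coords) in zip(self.all_matures, evals):
                self.site[m][g.gene_id] = ev
        # off-target screen against background transcriptome
        self.off_targets: dict[str, int] = {m: 0 for m in self.all_matures}
        if background:
            family_ids = {g.gene_id for g in self.genes}
            for tid, seq in background.items():
                if tid in family_ids:
                    continue
                evals = thermo.best_sites_batch(model, self.all_matures, seq)
                for m, (ev, _coords) in zip(self.all_matures, evals):
                    if ev.admissible and ev.fraction >= config.omega:
                        self.off_targets[m] += 1
        elif background is None:
            logger.warning(
                "no background transcriptome supplied: off-target screening "
                "is skipped"
            )

    def effective_targets(
        self, mature: str, gene_ids: Iterable[str]
    ) -> dict[str, float]:
        """Genes among ``gene_ids`` whose best site is admissible with
        fraction >= omega."""
        out = {}
        for g in gene_ids:
            ev = self.site[mature][g]
            if ev.admissible and ev.fraction >= self.config.omega:
                out[g] = ev.fraction
        return out


# ---------------------------------------------------------------------------
# scoring and ranking


def score_candidate(candidate: Candidate, config: DesignConfig) -> float:
    """w_frac * mean effective fraction - w_off * off-targets - w_comp *
    composition penalty (|GC - 0.5|)."""
    w = config.score_weights
    fracs = list(candidate.effective_targets.values())
    mean_frac = sum(fracs) / len(fracs) if fracs else 0.0
    comp_penalty = abs(gc_fraction(candidate.mature) - 0.5)
    return (
        w["w_frac"] * mean_frac
        - w["w_off"] * candidate.off_target_count
        - w["w_comp"] * comp_penalty
    )


def rank_candidates(candidates: Iterable[Candidate]) -> list[Candidate]:
    """Sort by effective-target count desc, then score desc, then mature
    ascending (deterministic tie-break)."""
    return sorted(
        candidates,
        key=lambda c: (-len(c.effective_targets), -c.score, c.mature),
    )


# ---------------------------------------------------------------------------
# candidate generation


def _build_candidates(
    evaluation: FamilyEvaluation,
    matures: Iterable[str],
    target_pool: set[str],
    origin_node: int,
    phase: str,
    config: DesignConfig,
) -> list[Candidate]:
    out = []
    for m in matures:
        off = evaluation.off_targets[m]
        if config.exclude_off_targets and off > 0:
            continue
        targets = evaluation.effective_targets(m, target_pool)
        if not (2 <= len(targets) <= config.max_targets):
            continue
        cand = Candidate(
            mature=m,
            origin_node=origin_node,
            phase=phase,
            effective_targets=targets,
            score=0.0,
            off_target_count=off,
        )
        cand.score = score_candidate(cand, config)
        out.append(cand)
    return out


def generate_candidates(
    tree: FamilyTree,
    genes: Sequence[GeneRecord],
    node: Node | int,
    background: Mapping[str, str] | None,
    config: DesignConfig,
    model: thermo.DuplexModel | None = None,
    evaluation: FamilyEvaluation | None = None,
) -> list[Candidate]:
    """Node-phase candidates for one internal node's subfamily.

    Subfamilies larger than ``max_subfamily_n`` are skipped (logged, empty
    result).  Effective targets are restricted to the subfamily.
    """
    if isinstance(node, int):
        node = tree.node(node)
    fam = phylo.subfamily(tree, node)
    if len(fam) > config.max_subfamily_n:
        logger.info(
            "node %d: subfamily of %d genes exceeds max %d; skipped",
            node.node_id, len(fam), config.max_subfamily_n,
        )
        return []
    if evaluation is None:
        model = model or thermo.load_model()
        evaluation = FamilyEvaluation(genes, config, model, background)
    matures = sorted(
        set().union(
            *(evaluation.matures_by_gene[g] for g in fam)
        )
    )
    return _build_candidates(
        evaluation, matures, fam, node.node_id, NODE_PHASE, config
    )


# ---------------------------------------------------------------------------
# selection


def _try_admit(
    state: SelectionState,
    node_id: int,
    candidate: Candidate,
    config: DesignConfig,
) -> bool:
    """Apply admission rules (a)/(b) for one candidate at one node."""
    if any(c.mature == candidate.mature for c in state.all_chosen()):
        return False  # one sequence, one library member: never admit twice
    lineage = state.comparable_chosen(node_id)
    similar = [
        c for c in lineage
        if hamming(c.mature, candidate.mature) < config.min_diff_m
    ]
    if not similar:
        state.node_chosen(node_id).append(candidate)
        return True
    if config.allow_similar_better and all(
        candidate.score > c.score for c in similar
    ):
        if config.replace_similar:
            for lst in state.chosen.values():
                lst[:] = [c for c in lst if c not in similar]
        state.node_chosen(node_id).append(candidate)
        return True
    return False


def select_node_phase(
    tree: FamilyTree,
    candidates_by_node: Mapping[int, Sequence[Candidate]],
    config: DesignConfig,
    state: SelectionState | None = None,
) -> SelectionState:
    """Top-down admission of ranked node-phase candidates under the per-node
    budget and the lineage similarity rules."""
    state = state or SelectionState(tree=tree)
    for node in tree.preorder_internal():
        nid = node.node_id
        for cand in rank_candidates(candidates_by_node.get(nid, ())):
            if len(state.node_chosen(nid)) >= config.node_budget_x:
                break
            _try_admit(state, nid, cand, config)
    return state


def select_mrca_phase(
    tree: FamilyTree,
    family_genes: Sequence[GeneRecord],
    background: Mapping[str, str] | None,
    state: SelectionState,
    config: DesignConfig,
    model: thermo.DuplexModel | None = None,
    evaluation: FamilyEvaluation | None = None,
) -> SelectionState:
    """Rescue phase: whole-family candidates ascribed to the MRCA of their
    effective targets, admitted into under-filled nodes when the targets'
    monophyletic clusters are pairwise within ``cluster_dist_max``."""
    if evaluation is None:
        model = model or thermo.load_model()
        evaluation = FamilyEvaluation(family_genes, config, model, background)
    gene_ids = {g.gene_id for g in family_genes}
    already = {c.mature for c in state.all_chosen()}
    by_node: dict[int, list[Candidate]] = {}
    for cand in _build_candidates(
        evaluation, evaluation.all_matures, gene_ids, -1, MRCA_PHASE, config
    ):
        if cand.mature in already:
            continue
        node = phylo.mrca(tree, cand.effective_targets)
        clusters = phylo.monophyletic_partition(tree, cand.effective_targets)
        ok = all(
            phylo.cluster_distance(tree, a, b) <= config.cluster_dist_max
            for i, a in enumerate(clusters)
            for b in clusters[i + 1 :]
        )
        if not ok:
            continue
        cand.origin_node = node.node_id
        by_node.setdefault(node.node_id, []).append(cand)
    for node in tree.preorder_internal():
        nid = node.node_id
        if len(state.node_chosen(nid)) >= config.node_budget_x:
            continue
        for cand in rank_candidates(by_node.get(nid, ())):
            if len(state.node_chosen(nid)) >= config.node_budget_x:
                break
            _try_admit(state, nid, cand, config)
    return state


def apply_blacklist(
    candidates: Sequence[Candidate], blacklist: set[str] | None
) -> list[Candidate]:
    """Drop candidates whose mature exactly matches a blacklist entry."""
    if not blacklist:
        return list(candidates)
    kept = [c for c in candidates if c.mature not in blacklist]
    removed = len(candidates) - len(kept)
    if removed:
        logger.info("blacklist removed %d candidate(s)", removed)
    return kept


def _prune_blacklisted(state: SelectionState, blacklist: set[str] | None) -> None:
    if not blacklist:
        return
    for nid, lst in state.chosen.items():
        lst[:] = apply_blacklist(lst, blacklist)


# ---------------------------------------------------------------------------
# orchestration


def design_family(
    genes: Sequence[GeneRecord],
    tree: FamilyTree,
    config: DesignConfig,
    model: thermo.DuplexModel | None = None,
    background: Mapping[str, str] | None = None,
    blacklist: set[str] | None = None,
) -> tuple[SelectionState, list[tuple[int, int, Candidate]]]:
    """Run candidate generation, both selection phases and the blacklist for
    one family.

    Returns the selection state plus a flat, deterministically ordered list
    of ``(node_id, rank, candidate)`` (nodes in pre-order, ranks in the
    order of admission).
    """
    model = model or thermo.load_model()
    evaluation = FamilyEvaluation(genes, config, model, background)
    candidates_by_node: dict[int, list[Candidate]] = {}
    for node in tree.internal_nodes:
        fam = phylo.subfamily(tree, node)
        if 2 <= len(fam) <= config.max_subfamily_n:
            candidates_by_node[node.node_id] = generate_candidates(
                tree, genes, node, background, config,
                model=model, evaluation=evaluation,
            )
        elif len(fam) > config.max_subfamily_n:
            logger.info(
                "node %d: subfamily of %d genes exceeds max %d; skipped",
                node.node_id, len(fam), config.max_subfamily_n,
            )
    state = select_node_phase(tree, candidates_by_node, config)
    state = select_mrca_phase(
        tree, genes, background, state, config,
        model=model, evaluation=evaluation,
    )
    _prune_blacklisted(state, blacklist)
    selected = []
    for node in tree.preorder_internal():
        for rank, cand in enumerate(state.chosen.get(node.node_id, ()), 1):
            selected.append((node.node_id, rank, cand))
    logger.info(
        "family design: %d guides across %d nodes",
        len(selected), sum(1 for _ in state.chosen.values() if _),
    )
    return state, selected
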