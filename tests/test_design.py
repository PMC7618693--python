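"""Candidate generation, ranking, node-budgeted selection — including an
independent exhaustive re-implementation of the selection steps as oracle."""

import numpy as np
import pytest

from amiclade import design, phylo, simulate, thermo
from amiclade.design import (
    Candidate,
    SelectionState,
    apply_blacklist,
    generate_candidates,
    hamming,
    matures_from_cds,
    rank_candidates,
    score_candidate,
    select_node_phase,
)
from amiclade.phylo import FamilyTree
from amiclade.seqio import DesignConfig, GeneRecord, revcomp


def _gene(gid, cds, fam="FAM1", cls="ABC"):
    return GeneRecord(gid, fam, cls, cds)


def _cand(mature, targets, score, node=0, phase="node_phase"):
    return Candidate(
        mature=mature, origin_node=node, phase=phase,
        effective_targets=targets, score=score,
    )


# ---------------------------------------------------------------------------
# candidate sequence derivation


def test_matures_are_t_forced_window_revcomps(config):
    rng = np.random.default_rng(0)
    cds = "".join(rng.choice(list("ACGT"), 60))
    matures = matures_from_cds(cds, config)
    assert all(m[0] == "T" for m in matures)
    assert all(len(m) == 21 for m in matures)
    expected = set()
    for i in range(len(cds) - 20):
        m = revcomp(cds[i : i + 21])
        m = m if m[0] == "T" else "T" + m[1:]
        if design.passes_composition(m, config):
            expected.add(m)
    assert set(matures) == expected


def test_composition_filter(config):
    assert not design.passes_composition("T" + "G" * 20, config)  # GC too high
    assert not design.passes_composition("T" + "A" * 20, config)  # homopolymer
    assert design.passes_composition("TACGATCGATCGATCGATCGA", config)


# ---------------------------------------------------------------------------
# two identical paralogs: every window targets both at fraction 1


def test_identical_paralogs_all_windows_effective(model, config):
    rng = np.random.default_rng(3)
    cds = "".join(rng.choice(list("ACGT"), 60))
    genes = [_gene("A", cds), _gene("B", cds)]
    tree = FamilyTree.from_newick("(A,B);")
    cands = generate_candidates(tree, genes, tree.root, {}, config, model=model)
    assert cands, "identical paralogs must yield candidates"
    for c in cands:
        assert set(c.effective_targets) == {"A", "B"}
        # the T-forced 5' edit may cost a little; un-edited windows hit 1.0
    assert any(
        c.effective_targets["A"] == 1.0 and c.effective_targets["B"] == 1.0
        for c in cands
    )


def test_oversized_subfamily_skipped(model, config):
    rng = np.random.default_rng(4)
    cds = "".join(rng.choice(list("ACGT"), 60))
    genes = [_gene(f"G{i}", cds) for i in range(12)]
    newick = "(" * 11 + "G0" + "".join(f",G{i})" for i in range(1, 12)) + ";"
    tree = FamilyTree.from_newick(newick)
    assert len(phylo.subfamily(tree, tree.root)) == 12
    assert generate_candidates(tree, genes, tree.root, {}, config, model=model) == []


def test_effective_targets_subset_of_subfamily(small_family, model, config):
    genes, tree = small_family
    for node in tree.internal_nodes:
        fam = phylo.subfamily(tree, node)
        for c in generate_candidates(
            tree, genes, node, {}, config, model=model
        ):
            assert set(c.effective_targets) <= fam
            assert len(c.effective_targets) >= 2
            assert all(f >= config.omega
                       for f in c.effective_targets.values())


# ---------------------------------------------------------------------------
# scoring and ranking


def test_score_hand_computation(config):
    c = _cand("TACGATCGATCGATCGATCGA", {"A": 0.9, "B": 0.8}, 0.0)
    c.off_target_count = 1
    gc = (c.mature.count("G") + c.mature.count("C")) / 21
    expected = 1.0 * 0.85 - 1.0 * 1 - 0.1 * abs(gc - 0.5)
    assert score_candidate(c, config) == pytest.approx(expected)


def test_score_monotonic_in_fraction_and_offtargets(config):
    lo = _cand("T" + "A" * 20, {"A": 0.8, "B": 0.8}, 0.0)
    hi = _cand("T" + "A" * 20, {"A": 0.9, "B": 0.9}, 0.0)
    assert score_candidate(hi, config) > score_candidate(lo, config)
    off = _cand("T" + "A" * 20, {"A": 0.9, "B": 0.9}, 0.0)
    off.off_target_count = 1
    assert score_candidate(off, config) < score_candidate(hi, config)


def test_rank_order_and_tie_breaks():
    a = _cand("TCC" + "A" * 18, {"A": 0.9, "B": 0.9, "C": 0.9}, 1.0)
    b = _cand("TGG" + "A" * 18, {"A": 0.9, "B": 0.9}, 5.0)
    c = _cand("TTT" + "A" * 18, {"A": 0.9, "B": 0.9}, 2.0)
    assert rank_candidates([c, b, a]) == [a, b, c]
    # equal targets and scores: lexicographic mature ascending
    d = _cand("TAA" + "A" * 18, {"A": 0.9, "B": 0.9}, 2.0)
    assert rank_candidates([c, d]) == [d, c]
    # matches an independent stable sort
    rng = np.random.default_rng(8)
    pool = [
        _cand(
            "T" + "".join(rng.choice(list("ACGT"), 20)),
            {f"G{j}": 0.8 for j in range(int(rng.integers(2, 6)))},
            float(rng.integers(0, 4)),
        )
        for _ in range(30)
    ]
    expected = sorted(
        pool, key=lambda c: (-len(c.effective_targets), -c.score, c.mature)
    )
    assert rank_candidates(pool) == expected


# ---------------------------------------------------------------------------
# admission rules


def _chain_tree():
    return FamilyTree.from_newick("((A,B),(C,D));")


def test_node_budget_enforced(config):
    tree = _chain_tree()
    root_id = tree.root.node_id
    # 10 mutually dissimilar candidates at the root -> exactly 8 admitted
    cands = [
        _cand("T" + "ACGT"[i % 4] * 2 + f"{'ACGT'[(i//4) % 4]}" * 2 + "ACGATCGATCGATCGA"[:16], {"A": 0.9, "B": 0.9}, float(i))
        for i in range(10)
    ]
    # build guaranteed-dissimilar matures instead
    bases = ["TAAAA", "TCCCC", "TGGGG", "TTTTT", "TACGT", "TCAGT",
             "TGACT", "TTGCA", "TAGCT", "TCGAT"]
    cands = [
        _cand(b + "ACGATCGATCGATCGA", {"A": 0.9, "B": 0.9}, float(i))
        for i, b in enumerate(bases)
    ]
    state = select_node_phase(tree, {root_id: cands}, config)
    assert len(state.chosen[root_id]) == config.node_budget_x == 8


def test_similarity_rules(config):
    tree = _chain_tree()
    root_id = tree.root.node_id
    child_id = phylo.mrca(tree, {"A", "B"}).node_id
    base = "TACGATCGATCGATCGATCGA"
    near = base[:-1] + ("A" if base[-1] != "A" else "C")  # Hamming 1
    anchor = _cand(base, {"A": 0.9, "B": 0.9}, 5.0, node=root_id)
    state = SelectionState(tree=tree)
    state.node_chosen(root_id).append(anchor)
    # lower score, Hamming 1 from an ancestor pick: rejected
    low = _cand(near, {"A": 0.9, "B": 0.9}, 1.0, node=child_id)
    select_node_phase(tree, {child_id: [low]}, config, state=state)
    assert state.chosen.get(child_id, []) == []
    # strictly higher score than all similar picks: admitted (rule b)
    high = _cand(near, {"A": 0.9, "B": 0.9}, 9.0, node=child_id)
    select_node_phase(tree, {child_id: [high]}, config, state=state)
    assert state.chosen[child_id] == [high]
    # with rule (b) disabled it would have been rejected
    cfg_strict = DesignConfig(allow_similar_better=False)
    state2 = SelectionState(tree=tree)
    state2.node_chosen(root_id).append(anchor)
    select_node_phase(tree, {child_id: [high]}, cfg_strict, state=state2)
    assert state2.chosen.get(child_id, []) == []


def test_identical_mature_never_admitted_twice(config):
    tree = _chain_tree()
    root_id = tree.root.node_id
    child_id = phylo.mrca(tree, {"A", "B"}).node_id
    base = "TACGATCGATCGATCGATCGA"
    state = SelectionState(tree=tree)
    state.node_chosen(root_id).append(
        _cand(base, {"A": 0.9, "B": 0.9}, 1.0, node=root_id)
    )
    dup = _cand(base, {"A": 0.9, "B": 0.9}, 9.0, node=child_id)
    select_node_phase(tree, {child_id: [dup]}, config, state=state)
    assert state.chosen.get(child_id, []) == []


def test_blacklist():
    cands = [
        _cand("T" + "".join(np.random.default_rng(i).choice(list("ACGT"), 20)),
              {"A": 0.9, "B": 0.9}, 0.0)
        for i in range(100)
    ]
    assert apply_blacklist(cands, set()) == cands
    bl = {c.mature for c in cands[:7]}
    kept = apply_blacklist(cands, bl)
    assert len(kept) == 93
    assert not bl & {c.mature for c in kept}


# ---------------------------------------------------------------------------
# exhaustive oracle for the full selection (steps 1-3) on tiny families


def exhaustive_design(genes, tree, config, model):
    """Straightforward re-implementation: per-window scan with the scalar
    best-site routine, plain sorts, explicit admission loops."""
    gene_ids = [g.gene_id for g in genes]
    cds = {g.gene_id: g.cds for g in genes}

    def gen_matures(members):
        out = set()
        for g in members:
            s = cds[g]
            for i in range(len(s) - config.mature_length + 1):
                m = revcomp(s[i : i + config.mature_length])
                if m[0] != "T":
                    m = "T" + m[1:]
                gc = (m.count("G") + m.count("C")) / len(m)
                runs = max(
                    len(r) for r in
                    __import__("itertools").groupby(m)
                    for r in [list(r[1])]
                )
                if not (config.gc_min <= gc <= config.gc_max):
                    continue
                if runs > config.max_homopolymer:
                    continue
                out.add(m)
        return sorted(out)

    def targets_of(m, pool):
        out = {}
        for g in pool:
            ev, _ = thermo.best_site(model, m, cds[g])
            if ev.admissible and ev.fraction >= config.omega:
                out[g] = ev.fraction
        return out

    def score(m, targets):
        gc = (m.count("G") + m.count("C")) / len(m)
        fr = sum(targets.values()) / len(targets)
        w = config.score_weights
        return w["w_frac"] * fr - w["w_comp"] * abs(gc - 0.5)

    def candidates(members, pool):
        out = []
        for m in gen_matures(members):
            t = targets_of(m, pool)
            if 2 <= len(t) <= config.max_targets:
                out.append((m, t, score(m, t)))
        return out

    chosen = {}  # node_id -> list of (mature, targets, score)

    def lineage(nid):
        # every node on a root-to-leaf path through nid (self, ancestors,
        # descendants)
        node = tree.node(nid)
        out = list(chosen.get(nid, []))
        cur = node.parent
        while cur is not None:
            out.extend(chosen.get(cur.node_id, []))
            cur = cur.parent
        stack = list(node.children)
        while stack:
            n = stack.pop()
            if n.is_leaf:
                continue
            out.extend(chosen.get(n.node_id, []))
            stack.extend(n.children)
        return out

    def admit(nid, cand):
        m, t, sc = cand
        if any(c[0] == m for lst in chosen.values() for c in lst):
            return
        lin = lineage(nid)
        similar = [c for c in lin
                   if hamming(c[0], m) < config.min_diff_m]
        if similar and not (
            config.allow_similar_better
            and all(sc > c[2] for c in similar)
        ):
            return
        chosen.setdefault(nid, []).append(cand)

    pre = [n.node_id for n in tree.preorder_internal()]
    for nid in pre:
        members = sorted(phylo.subfamily(tree, tree.node(nid)))
        if not (2 <= len(members) <= config.max_subfamily_n):
            continue
        pool = candidates(members, members)
        pool.sort(key=lambda c: (-len(c[1]), -c[2], c[0]))
        for cand in pool:
            if len(chosen.get(nid, [])) >= config.node_budget_x:
                break
            admit(nid, cand)
    # rescue phase over the whole family
    rescue = {}
    for m, t, sc in candidates(gene_ids, gene_ids):
        if any(c[0] == m for lst in chosen.values() for c in lst):
            continue
        node = phylo.mrca(tree, set(t))
        blocks = phylo.monophyletic_partition(tree, set(t))
        if any(
            phylo.cluster_distance(tree, a, b) > config.cluster_dist_max
            for i, a in enumerate(blocks) for b in blocks[i + 1 :]
        ):
            continue
        rescue.setdefault(node.node_id, []).append((m, t, sc))
    for nid in pre:
        pool = sorted(
            rescue.get(nid, []), key=lambda c: (-len(c[1]), -c[2], c[0])
        )
        for cand in pool:
            if len(chosen.get(nid, [])) >= config.node_budget_x:
                break
            admit(nid, cand)
    return {
        nid: [(m, dict(t)) for m, t, _ in lst]
        for nid, lst in chosen.items() if lst
    }


def test_selection_equals_exhaustive_oracle(model, config):
    """On families of <= 4 genes with ~200-nt CDS, the pipeline's selected
    sets match an independent exhaustive implementation."""
    for seed in (7, 21):
        spec = simulate.FamilySimSpec(
            n_genes=4, cds_length=201, per_branch_sub_prob=0.02,
            seed=seed, family_id="FAM1", class_label="ABC",
        )
        genes, tree = simulate.simulate_family(spec)
        state, _sel = design.design_family(genes, tree, config, model=model,
                                           background={})
        got = {
            nid: [(c.mature, c.effective_targets) for c in lst]
            for nid, lst in state.chosen.items() if lst
        }
        expected = exhaustive_design(genes, tree, config, model)
        assert got == expected


def test_determinism_and_budget_invariants(small_family, model, config):
    genes, tree = small_family
    s1, sel1 = design.design_family(genes, tree, config, model=model,
                                    background={})
    s2, sel2 = design.design_family(genes, tree, config, model=model,
                                    background={})
    assert [(n, r, c.mature) for n, r, c in sel1] == [
        (n, r, c.mature) for n, r, c in sel2
    ]
    for nid, lst in s1.chosen.items():
        assert len(lst) <= config.node_budget_x
        for c in lst:
            assert len(c.effective_targets) >= 2
            assert all(f >= config.omega
                       for f in c.effective_targets.values())


def test_rule_a_distance_holds_when_rule_b_disabled(small_family, model):
    genes, tree = small_family
    cfg = DesignConfig(allow_similar_better=False)
    state, _ = design.design_family(genes, tree, cfg, model=model,
                                    background={})
    for node in tree.internal_nodes:
        lst = state.chosen.get(node.node_id, [])
        for c in lst:
            lineage = state.lineage_chosen(node.node_id)
            for other in lineage:
                if other is c:
                    continue
                assert hamming(c.mature, other.mature) >= cfg.min_diff_m


def test_off_target_exclusion(model, config):
    rng = np.random.default_rng(13)
    cds = "".join(rng.choice(list("ACGT"), 60))
    genes = [_gene("A", cds), _gene("B", cds)]
    tree = FamilyTree.from_newick("(A,B);")
    no_bg = generate_candidates(tree, genes, tree.root, {}, config, model=model)
    assert no_bg
    # background containing the family CDS itself: every candidate has a
    # perfect admissible off-target hit and is excluded
    bg = {"OFF1": cds}
    with_bg = generate_candidates(tree, genes, tree.root, bg, config,
                                  model=model)
    assert with_bg == []
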