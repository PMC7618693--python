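# Methods

## Problem and model

`amiclade` designs 21-nt artificial microRNA guides that each silence
several closely related paralogs of a gene family, under a budget of guides
per internal tree node. The inputs are the family's coding sequences and a
rooted gene tree; the tree is taken as given (how it was inferred is out of
scope), branch lengths are ignored, and all tree distances are counts of
internal nodes. An unrooted trifurcation at the root is accepted as a
multifurcating root; midpoint rooting is left to the user upstream.

### Duplex energy model

Guide efficacy is summarized by the **energy fraction**
f = ΔG(guide, site) / ΔG(guide, perfect complement), so f = 1 for a perfect
site and f decreases with every mismatch. ΔG is a simplified
nearest-neighbor model:

    ΔG = ΔG_init + Σ stacks over adjacent Watson-Crick pairs
       + n_mismatch · p_mm + n_wobble · p_gu

with the published RNA/RNA stacking free energies at 37 °C (ΔG_init =
+4.09 kcal/mol, stacks −0.93 … −3.42 kcal/mol), p_mm = +0.5 and
p_gu = +0.25 kcal/mol. A mismatch therefore costs its two broken stacks
plus the flat penalty — about 12–13 % of a typical 21-mer's perfect-match
ΔG for an interior mismatch and about 7 % at a terminus — so the Ω = 0.75
threshold tolerates roughly two mismatches. Dangling ends, terminal
mismatches and coaxial corrections are omitted as second-order relative to
a 25 % threshold; target-site accessibility and precursor folding are not
modeled. All parameters live in `src/amiclade/data/nn_rna.tsv` and can be
replaced wholesale.

Pairing geometry: the guide anneals antiparallel to the sense strand, guide
position 1 (5′) facing site position 21. Only the sense strand of each CDS
is scanned (the guide silences mRNA); the best site of a transcript is the
maximal-fraction window, ties resolved to the smallest start coordinate.
Fractions are clipped to [0, 1] (clips logged); a site with no mismatches
is assigned fraction 1.0 exactly, avoiding float summation-order noise.

### Admissibility rules

A hybrid is workable when (1-based guide positions): positions 10–11 pair
perfectly (no mismatch, no G:U) — the slicing site; ≤ 1 mismatch in 2–9;
≤ 3 mismatches in 12–21; ≤ 4 mismatch-equivalents total, a G:U wobble
counting one half (total rounded up). Position 1 is unconstrained beyond
the total because candidate guides are 5′-U-forced and routinely mismatch
there. These rules are configuration (`AdmissibilityRules`), not code.

### Candidate generation

Candidates derive only from observed target windows: reverse complement of
every 21-nt CDS window of the relevant genes, 5′ base forced to T, then
deduplicated, GC-filtered to 30–70 % and rejected if they carry a
homopolymer run of 6+. No free sequence optimization is attempted — a
window-derived guide is guaranteed at least one near-perfect site. A gene
is an effective target when its best site is admissible with f ≥ Ω = 0.75;
candidates need at least 2 and at most 8 effective targets (the upper
cut-off caps promiscuous guides from near-identical clades). With a
background transcriptome supplied, any admissible hit at f ≥ Ω on an
out-of-family transcript disqualifies the candidate outright; without one,
off-target screening is skipped with a prominent warning.

### Selection

Ranking is lexicographic: effective-target count (desc), then score
(desc), then guide sequence (asc) — the last key only to make ties
deterministic. The score is
`w_frac · mean(f over targets) − w_off · off_targets − w_comp · |GC − 0.5|`
with defaults (1.0, 1.0, 0.1): prefer strong average silencing, then
penalize composition drift.

Node phase: internal nodes are visited root → leaves (pre-order, children
in post-order-ID order), each admitting ranked candidates of its own
subfamily (2–11 genes; larger subfamilies are skipped) until it holds
x = 8. A candidate is admitted iff it differs by ≥ m = 2 substitutions
from every guide already chosen at any comparable node (ancestors *and*
descendants — equivalent to ancestors-only during this top-down phase), or
it strictly out-scores all similar (< m) chosen guides. The
similar-but-better rule *adds* without evicting; `replace_similar=True`
switches to the replace interpretation, and `allow_similar_better=False`
disables the exception entirely, guaranteeing pairwise distance ≥ m on
every lineage. An identical sequence is never admitted twice anywhere in a
family — one sequence, one library member.

Rescue phase: candidates are regenerated over the whole family (effective
targets unrestricted), deduplicated against everything already chosen, and
ascribed to the MRCA of their effective targets. A rescue candidate is
considered only for under-budget nodes and only if the maximal
monophyletic clusters of its target set are pairwise within 3 internal
nodes (cluster distance = minimum leaf-to-leaf internal-node count; the
leaf distance counts the MRCA, so siblings are at distance 1 — the
smallest sensible positive value). Because this phase fills nodes out of
top-down order, its similarity check must include descendant nodes'
picks; with ancestors only, an ancestor could receive a guide one
substitution away from a descendant's earlier pick, silently breaking the
lineage-distance guarantee.

The monophyletic partition is the *coarsest* one (maximal blocks that are
full subtree leaf sets; a multifurcating node counts only as a whole),
which makes the ≤ 3 test as permissive as possible; a finer clustering
would only reject more candidates.

### Assembly

Star strand = reverse complement of the mature guide, with optional
backbone-specified mismatch positions substituted by a fixed transversion.
Both arms are substituted into the backbone template
(`…{MATURE}…{STAR}…`), then flanked by the functional class's adaptor pair
(8 classes, validated at load: no adaptor may be a substring of another
class's adaptor or of the backbone). The shipped backbone and adaptor
table are **synthetic stand-ins** with the right shape (25-nt arms, 17-nt
loop, 12-nt adaptors); real designs should supply their precursor of
choice via the config. Entry IDs are `<family>.n<node>.<rank>` and stable
across runs.

Two post-assembly screens:

* **Restriction screen** — any oligo containing a forbidden motif
  (default BsaI `GGTCTC` plus auto-added reverse complement `GAGACC`) is
  removed; the cloning flanks are assumed to live outside the modeled
  oligo. An optional back-fill pass (default off) re-opens selection for
  nodes that lost entries.
* **Arm-uniqueness screen** (default on) — each member's mature arm must
  occur in no other member's oligo in either orientation. Overlapping
  window-derived guides can otherwise be recreated by a backbone junction
  (e.g. a loop starting with the same bases as the genomic continuation of
  a neighbor window), which would make exact-substring read assignment
  ambiguous. Later-ordered colliding entries are dropped.

### Sequencing QC

Reads are assigned by exact containment of a member's identifying 21-mer
(the mature arm by default) in the read or its reverse complement; reads
matching zero or several members are unassigned. Quality values are
ignored; a Hamming-1 rescue mode exists behind a flag. Coverage =
100 · detected/|library|. Skew = adjusted Fisher–Pearson sample skewness
G1 of per-member read fractions; an exactly uniform count vector returns
0.0 by construction (guarding against catastrophic cancellation in the
third moment of a constant vector). The statistic is scale-free and
symmetric-zero; no published value of it is treated as a reproduction
target.

## Synthetic data

`simulate_family` draws a root CDS uniformly over the 61 sense codons and
evolves it down a given or random (recursive random bifurcation) tree with
i.i.d. per-site substitutions, uniform over the three alternative bases, at
probability p per branch — no indels, no rate variation, no selection.
Defaults: 600-nt CDS, p = 0.02, which leaves sibling genes ~96 % identical
per site so conserved 21-mers are plentiful (the generator warns if the
expected shared-window count between siblings drops below 1). The standard
end-to-end panel (`simulate_panel`) is five families of 8, 10, 12, 14 and
16 paralogs, one functional class each. What passing tests on this panel
do **not** show: robustness to indel divergence, alternative splicing,
rate heterogeneity across sites, or sequencing error — real transcriptomes
will yield fewer shared windows and noisier counts than the simulator.

`simulate_reads` emits full-oligo amplicon reads at uniform, lognormal, or
custom per-member depth, in random orientation, deterministically from its
seed.

## Problem sizes and determinism

The test-suite and the acceptance script run the five-family panel
(~330–350 guides) end to end in well under a minute each on one CPU; the
exhaustive selection oracle is exercised on 4-gene families with 200-nt
CDSs, and tree oracles on trees of up to 8 leaves. Every source of
randomness is an explicit seed; two runs with identical inputs and config
produce byte-identical library files.

## Known limitations

* The duplex model is a deliberate simplification; it preserves the
  ordering properties the design needs (perfect = 1, monotone decrease per
  mismatch, wobble cheaper than mismatch) but its absolute ΔG values are
  not calibrated against folding software.
* The shipped backbone/adaptor sequences are placeholders, not a real
  precursor; star-arm mismatch patterns of natural precursors are not
  reproduced by default.
* Off-target screening is exact best-site evaluation against a supplied
  FASTA — there is no genome-scale index, so very large backgrounds are
  slow.
* Guides are not checked for precursor-hairpin foldability.
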