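# amiclade

Phylogeny-guided design of artificial microRNA (amiRNA) libraries that
silence **multiple closely related members of a gene family at once**.

Plant genomes are full of paralogs with redundant functions; knocking out one
gene often shows no phenotype. amiRNAs — 21-nt guides expressed from an
endogenous miRNA precursor backbone — can silence a chosen *set* of
transcripts, but picking guide sets that respect the family's internal
structure is the hard part: a guide that hits two distantly related family
members rarely uncovers a redundant function. `amiclade` designs guides
clade by clade, walking each family's gene tree so that every guide targets
a group of genes that actually share recent ancestry, then assembles the
guides into orderable synthesis oligos grouped into functional-class
sub-libraries, and finally verifies pooled-library representation from
amplicon sequencing.

## The design procedure

For a family with rooted gene tree *T* (leaves = genes, CDSs given):

1. **Candidates per clade.** Every internal node *v* of *T* induces a
   subfamily (its descendant genes). For subfamilies of 2–11 genes,
   candidate guides are the reverse complements of all 21-nt CDS windows of
   the subfamily members, with the 5′-terminal base forced to U (T), and
   composition-filtered (GC 30–70 %, no homopolymer ≥ 6).
2. **Energy fraction.** A guide's predicted efficacy against a site is the
   duplex free energy divided by the perfect-match free energy
   (nearest-neighbor stacking + flat mismatch/G:U penalties). A gene is an
   *effective target* when its best site is mismatch-admissible (positions
   10–11 perfectly paired, ≤ 1 mismatch in 2–9, ≤ 3 in 12–21, ≤ 4 total
   with G:U counting half) and has fraction ≥ Ω = 0.75. Candidates need
   2–8 effective targets.
3. **Node-budgeted selection.** Candidates are ranked (target count, then
   score) and admitted node by node, root → leaves, until each node holds
   *x* = 8 guides. A candidate must differ by ≥ *m* = 2 substitutions from
   every guide already chosen on its root-to-leaf lineage — unless it
   strictly out-scores all similar ones.
4. **Rescue phase.** Nodes still under budget receive whole-family
   candidates ascribed to the MRCA of their targets, provided the targets'
   maximal monophyletic clusters are pairwise within 3 internal nodes.
5. **Blacklist and assembly.** Blacklisted guides are dropped; survivors are
   inserted into the precursor backbone with their star strand, flanked by
   class-specific adaptors (8 functional classes: CP, APC, MFS, DMT, MATE,
   ABC, PA, UF), and any oligo containing a BsaI site
   (`GGTCTC`/`GAGACC`, either strand) is removed so the library survives
   Golden Gate cloning.

QC from sequencing reports **coverage** (% of members detected ≥ once) and
**skew** (adjusted Fisher–Pearson skewness of per-member read fractions;
0 = perfectly even).

## Worked example

```python
from amiclade import design, simulate, thermo
from amiclade.seqio import DesignConfig

spec = simulate.FamilySimSpec(n_genes=8, cds_length=600,
                              per_branch_sub_prob=0.02, seed=42,
                              family_id="FAM1", class_label="ABC")
genes, tree = simulate.simulate_family(spec)
state, selected = design.design_family(genes, tree, DesignConfig(),
                                       model=thermo.load_model(),
                                       background={})
```

Running `python examples/01_design_family.py` (the same computation) prints:

```
selected 56 guides across 7 internal nodes
guides per node: {6: 8, 5: 8, 0: 8, 4: 8, 3: 8, 1: 8, 2: 8}
targets per guide: {2: 24, 4: 8, 5: 8, 7: 8, 8: 8}

example guide (node 6, rank 1): TGACACATGGGTCCCCGCTGA
  silences FAM1_G01: energy fraction 1.000 ...
  silences FAM1_G05: energy fraction 0.871 ...
```

Every internal node of the 8-gene family is filled to its budget of 8
guides; each guide silences between 2 and 8 genes, and every reported
energy fraction clears the 0.75 threshold (1.000 = a perfect-complement
site; 0.871 = a slightly mismatched but still admissible site). The other
example scripts assemble these guides into 133-nt oligos
(`02_assemble_oligos.py`), run sequencing QC (`03_library_qc.py`: 100 %
coverage and skew 0.000 on a uniform pool), and demonstrate the underlying
tree queries (`04_tree_queries.py`).

A thin CLI wraps the same functions:

```bash
amiclade simulate --mode families --n-families 2 --n-genes 6 --cds-length 300 --seed 5 --out fam
amiclade design --fasta fam.fasta --annotation fam.annotation.tsv --trees fam_trees --out lib
amiclade simulate --mode reads --library-tsv lib.tsv --depth 4 --seed 2 --out reads
amiclade qc --library-tsv lib.tsv --reads reads.fastq --out qcres
```

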