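"""Turn selected guides into orderable synthesis oligos.

Runs the full per-family pipeline (design -> backbone insertion -> class
adaptors -> BsaI screen) and dissects one finished oligo into its parts.
"""

from amiclade import pipeline, simulate, thermo
from amiclade.assembly import export_network
from amiclade.seqio import DesignConfig, write_library

spec = simulate.FamilySimSpec(
    n_genes=8, cds_length=600, per_branch_sub_prob=0.02,
    seed=42, family_id="FAM1", class_label="ABC",
)
genes, tree = simulate.simulate_family(spec)
config = DesignConfig()
entries = pipeline.design_and_assemble_family(
    genes, tree, config, model=thermo.load_model(), background={}
)
print(f"{len(entries)} library entries (each a unique guide in the backbone,"
      " flanked by ABC-class adaptors)")

e = entries[0]
print(f"\n{e.amirna_id}")
print("  mature (antisense arm):", e.candidate.mature)
print("  star (sense arm):      ", e.star)
print("  fwd/rev adaptors:      ", e.fwd_adaptor, "/", e.rev_adaptor)
print("  full oligo:", e.oligo)
print("  oligo length:", len(e.oligo), "nt; contains no",
      "/".join(config.forbidden_sites), "(Golden Gate safe)")

tsv, fasta = write_library(entries, "scratch_example_library")
net = export_network(entries, "scratch_example_network.tsv")
print(f"\nwrote {tsv}, {fasta} and the guide->gene edge list {net}")
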