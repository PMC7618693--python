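"""Check pooled-library representation from amplicon reads.

Builds a small library, simulates a uniform read pool (5 reads per member)
and a skewed lognormal pool, and reports coverage and skew for both.
"""

from amiclade import pipeline, qc, simulate, thermo
from amiclade.seqio import DesignConfig

panel = simulate.simulate_panel(seed=42, n_families=2, family_sizes=(8, 10))
library = pipeline.build_library(panel, DesignConfig(),
                                 model=thermo.load_model(), background={})
print(f"library of {len(library)} members")

for name, depth_spec in [("uniform x5", ("uniform", 5)),
                         ("lognormal(1.5, 0.7)", ("lognormal", 1.5, 0.7))]:
    reads = simulate.simulate_reads(library, depth_spec, seed=3)
    table = qc.count_reads(reads, library)
    cov = qc.coverage(table, library)
    sk = qc.skew(table)
    print(f"\n{name}: {table.total_reads} reads, "
          f"{table.unassigned} unassigned")
    print(f"  coverage {cov:.1f}%  (percent of members seen >= once; "
          "100% means nothing dropped out of the pool)")
    print(f"  skew {sk:.3f}  (0 = perfectly even representation; "
          "positive = a right tail of over-amplified members)")
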