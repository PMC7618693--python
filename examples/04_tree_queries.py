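"""The tree queries behind the selection algorithm, on a toy family.

Shows subfamily induction, MRCA, internal-node distances, and the
monophyletic clustering used to reject rescue-phase guides whose targets
are too scattered.
"""

from amiclade import phylo
from amiclade.phylo import FamilyTree

tree = FamilyTree.from_newick("((A,B),(C,(D,E)));")
print("tree: ((A,B),(C,(D,E)));")

for node in tree.internal_nodes:
    print(f"node {node.node_id}: subfamily {sorted(phylo.subfamily(tree, node))}")

print("\nd(A,B) =", phylo.leaf_distance(tree, "A", "B"),
      " (siblings: just their MRCA between them)")
print("d(A,E) =", phylo.leaf_distance(tree, "A", "E"),
      " (every internal node on the path, MRCA included)")

targets = {"A", "B", "D"}
blocks = phylo.monophyletic_partition(tree, targets)
print(f"\ntargets {sorted(targets)} split into monophyletic blocks {blocks}")
dist = phylo.cluster_distance(tree, blocks[0], blocks[1])
print(f"cluster distance {dist}: a rescue-phase guide with these targets is"
      f" {'accepted' if dist <= 3 else 'rejected'} under the <= 3 rule")
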