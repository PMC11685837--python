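"""Compute clustering feature vectors for validated stabilizing mutations.

Given a wild-type structure and mutations with measured melting-temperature
improvements, prints the nine-column feature table used for clustering:
mutation, position, ΔTm (°C), hydrogen-bond change, hydrophobic-contact
change, entropy flag, and the wild-type Cα coordinates.
"""

from grape import Mutation, feature_table, make_toy_pdb

structure, _ = make_toy_pdb(16, "helix", "ASDLKGHWYPVESTNQ", seed=0)
validated = [
    (Mutation.parse("S2E"), 2.5),
    (Mutation.parse("L4F"), 3.1),
    (Mutation.parse("G6A"), 1.8),
    (Mutation.parse("P10V"), 2.2),
]
table = feature_table(validated, structure)
print(table.to_string(index=False))
# hbond/hydrophobic are mutant-minus-wild-type interaction counts within
# 8 Å of the mutated residue; entropy is 1 when glycine or proline is
# involved; the coordinates locate the mutation on the structure.
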