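"""Cluster validated mutations and plan the first wet-lab combination round.

Clusters a feature table by silhouette-selected k-means, then shows the
round-by-round proposals the greedy strategy would request from the lab.
"""

import pandas as pd

from grape import cluster_mutations, cluster_report, feature_table, make_toy_pdb
from grape.greedy import plan_experiment
from grape.structure_io import Mutation

structure, _ = make_toy_pdb(20, "helix", "ASDLKGHWYPVESTNQARFE", seed=0)
validated = [
    ("S2E", 2.5), ("L4F", 3.1), ("K5R", 1.9), ("G6A", 1.8),
    ("W8F", 2.8), ("P10V", 2.2), ("S13T", 4.0), ("N15D", 1.7),
]
table = feature_table([(Mutation.parse(n), d) for n, d in validated], structure)

assignment = cluster_mutations(table, k="auto", seed=0)
print(f"auto-k chose k={assignment.k}, silhouette={assignment.silhouette:.3f}")
print(cluster_report(assignment, table).to_string(index=False))

# round 1: measure every single (already done above), so plan round 2 from
# the single-mutant measurements
results = pd.DataFrame({"variant": [n for n, _ in validated],
                        "delta_tm": [d for _, d in validated]})
proposal = plan_experiment(assignment.members, results)
for cluster, plan in proposal.items():
    print(f"cluster {cluster}: best {plan['current_best']!r} "
          f"({plan['current_delta_tm']:.1f} °C), "
          f"next round {plan['next_round']}")
# Each next-round entry is a combination variant to construct and measure;
# a cluster is converged when no remaining addition can clear the 1.5 °C
# acceptance bar.
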