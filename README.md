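# grape

Greedy-accumulation protein thermostabilization: design a library of
stabilizing single-point mutations by thresholded multi-predictor
consensus, extract structure-based feature vectors for experimentally
validated mutations, cluster them into mechanistically coherent groups,
and plan the greedy accumulation of mutations into combination variants
over (optionally epistatic) landscapes — together with the
classification-metric machinery used to benchmark stability predictors.

## Who this is for

Protein engineers who want to raise an enzyme's melting temperature (Tm)
with as few wet-lab rounds as possible, and methods developers who want a
desk-scale, fully offline implementation of the accumulate-within-clusters
strategy to experiment against.

## The method

**Library design.** Several ΔΔG-style predictors score a saturation scan of
single-point mutations (convention: more negative = more stabilizing). A
mutation enters the candidate library when its score passes at least one
algorithm's threshold — defaults −1.5 kcal/mol (FoldX-style), −1.0 REU
(Rosetta-style), −2.5 AEU (ABACUS-style) — so complementary predictors
enlarge the library rather than intersect it. An MSA consensus designer
adds back-to-consensus substitutions. External predictors plug in through a
registered-scorer interface; two built-ins (a fixture-driven scorer and a
heavy-atom contact scorer) let the whole pipeline run with no external
software.

**Features and clustering.** Each validated stabilizing mutation
(ΔTm ≥ 1.5 °C) gets a nine-column feature vector: mutation, position, ΔTm,
Δ(hydrogen bonds), Δ(hydrophobic contacts), a Gly/Pro backbone-entropy
flag, and the wild-type Cα coordinates. K-means on standardized features,
with silhouette-selected k, groups the mutations.

**Greedy accumulation.** Within each cluster, each experimental round
measures the current best variant extended by every remaining candidate
and accepts the best extension if it improves ΔTm by ≥ 1.5 °C. A cluster of
k mutations costs at most k(k+1)/2 measurements instead of 2^k. A synthetic
epistatic landscape, ΔTm(S) = Σ a_m + Σ e_mn + ε, with an exhaustive
brute-force oracle quantifies what greedy concedes under epistasis.

**Benchmarking.** Sensitivity, specificity, precision, accuracy and
F1 = 2·P·R/(P+R) from confusion counts, per algorithm plus the
any-algorithm ensemble row.

## Worked example

```sh
$ grape demo --seed 0 --out grape_demo
82 selected, 18 stabilizing singles, k=7, final A13E+A19K+D20F+F16Q+I1K+K9S+M22F+M7K+N12K+P14M+P17V+Q2D+S24Y+T8F+V15C+W10F+W18T+Y11T (ΔTm 72.84 °C) -> grape_demo
```

The demo builds a 24-residue toy helix, plants correlated scores for the
456-substitution saturation scan, selects 82 candidates past the
thresholds, "measures" singles on a noise-free synthetic landscape, keeps
the 18 that clear 1.5 °C (best single ΔTm 5.44 °C), clusters them into 7
groups, and greedily accumulates within and then across clusters; the
final combination variant reaches a simulated ΔTm of 72.84 °C. All
intermediate tables land in `grape_demo/` with a checksum manifest;
rerunning with the same seed reproduces every file byte for byte.

From Python, the same stages are plain function calls:

```python
from grape import make_toy_pdb, Mutation, feature_table, cluster_mutations

structure, _ = make_toy_pdb(16, "helix", "ASDLKGHWYPVESTNQ", seed=0)
table = feature_table([(Mutation.parse("S2E"), 2.5),
                       (Mutation.parse("L4F"), 3.1)], structure)
```

The `examples/` directory has one short narrative script per capability:
library design, feature tables, clustering + round planning, greedy vs the
exhaustive oracle, and predictor benchmarking.

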