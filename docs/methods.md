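# Methods

This note documents the models, parameter choices and numerical decisions
behind the package, and what the synthetic test conditions do and do not
establish about real proteins.

## Structures and mutant models

Structures are parsed from PDB with biotite and reduced to heavy atoms of
the 20 standard amino acids: hydrogens, waters, HETATM records,
non-standard residues and secondary altloc copies are dropped, and only
the first MODEL of a multi-model file is kept. The rationale is that every
downstream feature is defined on heavy atoms, so protonation and ligands
would only add unused state. Residue identity is (chain, author index,
insertion code); author numbering is preserved end to end so mutation
names match the numbering users see in their files. Validation requires
exactly one Cα per residue and strictly increasing residue indices per
chain; coordinates are promoted to float64 internally so geometric
features are reproducible to ~1e-9 under rigid transforms (PDB output
still rounds to the format's 3 decimals).

Mutant models are deliberately naive: the mutated residue's side chain is
replaced by the idealized heavy-atom template from the chemical component
dictionary, rigid-aligned on the residue's N–CA–C frame; backbone atoms and
all other residues are untouched, and no repacking or minimization is
performed. Production-quality mutant modelling belongs to external
force-field programs; a deterministic template keeps interaction-change
features exactly testable. The features computed from such models are
therefore coarse indicators for triage, not energy estimates.

The toy-structure generator places per-residue ideal templates on an ideal
backbone curve — helix: 1.5 Å rise and 100° turn per residue at 2.3 Å
radius; strand: 3.3 Å rise, 180° alternation; coil: a persistent random
walk with 3.8 Å virtual bonds. Internal residue geometry is ideal; peptide
connectivity between residues is only approximate, which is irrelevant to
the heavy-atom distance features the toys exercise. Cα–Cα spacing comes out
at 3.80–3.84 Å for all geometries.

## Library design

Scores follow the convention "more negative = more stabilizing" in each
algorithm's native unit. Selection is `score ≤ threshold` (inclusive
boundary — thresholds are phrased as cutoff levels and inclusivity is the
conservative, library-enriching reading), with defaults −1.5 kcal/mol,
−1.0 REU and −2.5 AEU for the three canonical predictor families. The
merged library is the union over algorithms ("pass any one"), which is
what makes complementary predictors enlarge the candidate pool; the
exclusivity report quantifies that complementarity. Selection is provably
monotone: tightening any threshold can only shrink the library.

External predictors integrate by registering a `(structure, mutation) →
score` callable; the package ships no subprocess adapters because no
external binaries are assumed. The built-in contact scorer
(−Δ heavy-atom contacts within 4.5 Å of the mutated side chain) exists to
run the pipeline end to end, not as a calibrated energy function.

Consensus design anchors the target sequence to an MSA row by exact match
after gap removal and proposes the modal non-gap residue of a column when
its frequency is ≥ 0.6 over ≥ 10 non-gap symbols (both configurable, both
conventional consensus-design practice; no published parameterization
exists to copy). Columns where the anchor has a gap are never proposed (no
insertion design), and output is invariant to MSA row order.

## Interaction features

The feature schema (ΔTm; Δhbond; Δhydrophobic; entropy flag; Cα x, y, z)
is fixed; the geometric criteria behind the two interaction counts are
this package's documented choices, configurable via `FeatureConfig`:

- Hydrogen bond: donor and acceptor are N/O heavy atoms from a per-residue
  chemistry table; distance ≤ 3.5 Å and antecedent–donor–acceptor angle
  ≥ 90°, where the antecedent is the heavy atom covalently bonded to the
  donor. This is a standard hydrogen-placement-free criterion;
  intra-residue pairs are excluded and each unordered atom pair counts
  once.
- Hydrophobic contact: side-chain carbon pairs at ≤ 5.0 Å between residues
  from {A,V,L,I,M,F,W,P,Y} with sequence separation ≥ 2.
- Entropy flag: 1 iff glycine or proline appears on either side of the
  substitution — backbone conformational entropy being the canonical
  "entropy" effect in stabilization engineering — giving a deterministic
  0/1.
- Δ-counts are mutant minus wild type restricted to residues with any atom
  within 8.0 Å of the mutated residue, so distant structural noise cannot
  contaminate a local feature. Antisymmetry (swapping wild type and mutant
  negates the deltas) holds by construction and is tested.

Both detectors use a k-d tree but are required by test to agree exactly
with an O(n²) all-pairs scan; both are isometry-invariant to ~1e-12.

## Clustering

Features mix °C, counts, a flag and Å, so all numeric columns are z-scored
(zero-spread columns map to 0); the three coordinate columns are further
multiplied by a joint `coordinate_weight` (default 1.0), and the binary
entropy flag passes through unscaled. Clustering is k-means with 20
restarts; `k="auto"` maximizes the silhouette over k = 2..min(8, n−1) with
ties broken toward smaller k (fewer clusters mean fewer parallel
experimental tracks). n = 2 degenerates to k = 2 with silhouette reported
as undefined. Tests compare partitions, never labels. The choice of
k-means over the nine described features is the minimal faithful reading
of "cluster the validated mutations"; no claim is made that any particular
published partition is reproduced, since the original algorithm and
distance were not specified.

## Greedy accumulation and the synthetic landscape

The greedy variant is steepest-ascent: every round evaluates all
one-mutation extensions of the current accepted set and accepts the single
best if it clears `min_improvement` (default 1.5 °C — the same bar that
defines a stabilizing single mutant) over the current measured value.
There is no backtracking: a candidate that measures worse in combination
is simply never accepted. Guarantees tested: the accepted ΔTm trace rises
by ≥ the tolerance per step; total evaluations for k candidates never
exceed k(k+1)/2; on additive noise-free landscapes with a vanishing
tolerance, greedy returns exactly the positive-effect set and matches the
exhaustive optimum.

The synthetic landscape is ΔTm(S) = Σ_{m∈S} a_m + Σ_{{m,n}⊆S} e_mn + ε with
additive effects a_m ~ N(1.0, 2.0²) °C, pairwise couplings e_mn ~
N(0, epistasis_sd²) on a random fraction of pairs, and i.i.d. Gaussian
measurement noise per evaluation (each requested subset is measured once;
replicate averaging is the caller's choice). Defaults for the benchmark
scenario are n = 8, epistasis fraction 0.3, coupling sd 1.0 °C, noise 0 —
a mid-size cluster with appreciable but not dominant pairwise epistasis.
The landscape has no higher-than-pairwise terms, no position constraints
and Gaussian effects only, so greedy regret measured here quantifies the
algorithm under those assumptions, not wet-lab reality. Under the default
scenario mean regret is ≈ 2 °C with ≈ 26 of the 255 possible subset
measurements used — the 1.5 °C acceptance bar trades some attainable ΔTm
for robustness and cost, which is the strategy's point.

`plan_experiment` replays the same acceptance rule against measured
results only, emitting the next round per cluster without calling any
evaluator — the interface for driving a real wet-lab campaign. Measured
variants mixing clusters are ignored for within-cluster planning, with a
warning. Cross-cluster combination first proposes the union of cluster
winners; if the measured union fails the acceptance bar against the best
cluster endpoint, it falls back to greedy re-checks of individual
cross-cluster additions. Clusters proposing different substitutions at one
position are a hard conflict.

## Benchmark metrics

Sensitivity tp/(tp+fn), specificity tn/(tn+fp), precision tp/(tp+fp),
accuracy (tp+tn)/total, F1 = 2PR/(P+R). Zero-denominator metrics are
reported as NA, never 0, to avoid silently deflating averages.
Experimental binarization: ΔΔG ≤ −|threshold| (default 0) or ΔTm ≥
threshold (default 1.5 °C), both boundaries inclusive; prediction
thresholds are inclusive likewise. The ensemble row labels a mutation
predicted-stabilizing when any algorithm selects it, so ensemble
sensitivity dominates every member and ensemble specificity is dominated
by every member — both directions are tested. The F1 harmonic identity is
exact on computed counts and reproduces published per-predictor F1 values
at 3 decimals from their printed precision/sensitivity, except where the
printed inputs carry too much rounding (two of the six published rows
recompute to 0.181 vs 0.182 and 0.091 vs 0.090).

## Pipeline, demo and determinism

Every run writes a manifest (configuration, seeds, SHA-256 of each
artifact) sufficient to re-run bit-identically; no artifact embeds a
timestamp. The inspection report flags candidates (hydrogen-bond loss,
buried polar introduction — ≥ 28 heavy atoms within 8 Å of the Cα —
Gly/Pro entropy change) but never drops them: library triage is a human
judgement, so the pipeline surfaces evidence only.

The demo generates a 24-residue helix (456-substitution scan), plants
correlated per-algorithm scores (shared N(0,1) stability component plus
per-algorithm N(0,0.5) disagreement, scaled to each algorithm's native
range), selects past the default thresholds, measures singles on a
noise-free landscape, keeps ΔTm ≥ 1.5 °C with one substitution per
position (same-site variants cannot be combined), clusters, and
accumulates within and across clusters. Problem sizes throughout the tests
(structures ≤ ~50 residues, landscapes n ≤ 12 against the exhaustive
oracle, 100–1000 randomized repetitions) are chosen so every oracle
comparison is exact while the whole suite runs in minutes on one core.

## Known limitations

- Mutant models are template-placed, unrepacked side chains; interaction
  deltas are triage indicators, not physics.
- The built-in contact scorer is a pipeline stand-in; real campaigns
  should register force-field or statistical predictors.
- The landscape model is additive-plus-pairwise with Gaussian terms;
  higher-order epistasis is out of scope.
- Greedy has no backtracking; on strongly deceptive landscapes its regret
  is bounded only by the oracle comparison, not by design.
- mmCIF, protonation, cavity detection and solvent-accessibility features
  are not implemented.
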