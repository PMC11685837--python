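"""End-to-end pipeline stages with reproducible run manifests.

Ties the stages together: structure in → per-algorithm scoring → threshold
selection and merge → feature-annotated inspection report → (after
experimental validation) clustering and greedy combination planning. Every
run writes a manifest recording the configuration, seeds and SHA-256
checksums of all artifacts, sufficient to re-run bit-identically.

The inspection report replaces interactive structural triage: candidates
that lose hydrogen bonds or introduce a buried polar side chain are flagged
for human review but never auto-rejected — triage of a mutation library is
a judgement call, so the pipeline surfaces the evidence and keeps every
candidate.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster as cluster_mod
from . import design, features, greedy
from .structure_io import (
    Mutation,
    ProteinStructure,
    enumerate_candidate_mutations,
    make_toy_pdb,
    read_pdb,
    select_chain,
    write_pdb,
)

__all__ = ["RunConfig", "run_design_stage", "run_full_demo", "write_manifest"]

logger = logging.getLogger(__name__)

POLAR_AA1 = frozenset("DEKRNQHSTY")
BURIAL_NEIGHBOR_CUTOFF = 28  # heavy atoms within 8 Å of the CA ≈ buried


@dataclass
class RunConfig:
    """Serializable configuration of a design run."""

    pdb: str | None = None
    chain: str = "A"
    scorers: list[str] = field(default_factory=lambda: ["contact"])
    predictions: list[str] = field(default_factory=list)
    thresholds: dict = field(default_factory=lambda: dict(design.DEFAULT_THRESHOLDS))
    msa: str | None = None
    min_frequency: float = 0.6
    min_depth: int = 10
    coordinate_weight: float = 1.0
    k: int | str = "auto"
    min_improvement: float = greedy.DEFAULT_MIN_IMPROVEMENT
    seed: int = 0
    out_dir: str = "grape_out"

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(out_dir: Path, config: dict, artifacts: list[Path]) -> Path:
    manifest = {
        "config": config,
        "artifacts": {p.name: _sha256(p) for p in sorted(artifacts)},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def _is_buried(structure: ProteinStructure, mutation: Mutation) -> bool:
    """Crude burial call: many heavy atoms near the mutated residue's CA."""
    from scipy.spatial import cKDTree

    ca = structure.ca_coord(mutation.chain_id, mutation.position,
                            mutation.ins_code)
    own = structure.residue_atoms(mutation.chain_id, mutation.position,
                                  mutation.ins_code)
    tree = cKDTree(np.asarray(structure.atoms.coord, dtype=float))
    n_near = len(tree.query_ball_point(ca, 8.0)) - own.array_length()
    return n_near >= BURIAL_NEIGHBOR_CUTOFF


def inspection_report(
    structure: ProteinStructure,
    selected: list[design.ScoredMutation],
    config: features.FeatureConfig = features.DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Feature-annotated review table for a selected library.

    Each candidate gets its interaction-change features and a ``flags``
    column naming potential pitfalls (lost hydrogen bonds, buried polar
    introduction, entropy change). Nothing is removed — flags are for the
    human doing library triage.
    """
    rows = []
    for sm in selected:
        fv = features.compute_features(structure, sm.mutation, delta_tm=0.0,
                                       config=config)
        flags = []
        if fv.d_hbond < 0:
            flags.append("hbond_loss")
        if sm.mutation.mut_aa in POLAR_AA1 and _is_buried(structure, sm.mutation):
            flags.append("buried_polar")
        if fv.entropy_flag:
            flags.append("entropy_change")
        rows.append({
            "mutation": sm.mutation.name,
            "selected_by": "+".join(sorted(sm.selected_by)),
            "d_hbond": fv.d_hbond,
            "d_hydrophobic": fv.d_hydrophobic,
            "entropy": fv.entropy_flag,
            "flags": "+".join(flags),
        })
    return pd.DataFrame(rows, columns=[
        "mutation", "selected_by", "d_hbond", "d_hydrophobic",
        "entropy", "flags",
    ])


def run_design_stage(config: RunConfig,
                     structure: ProteinStructure | None = None) -> dict:
    """Run structure → scores → thresholds → merged library → inspection.

    Returns the artifact paths; writes ``library.csv``, ``inspection.csv``
    and ``manifest.json`` under ``config.out_dir``. Fails fast if a listed
    scorer has no configured threshold.
    """
    thresholds = design.ThresholdConfig(thresholds=dict(config.thresholds))
    for name in config.scorers:
        if name not in thresholds.thresholds:
            raise KeyError(
                f"scorer {name!r} has no configured threshold; "
                f"known: {sorted(thresholds.thresholds)}"
            )
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if structure is None:
        if config.pdb is None:
            raise ValueError("config.pdb required when no structure is given")
        logger.info("design stage: reading %s", config.pdb)
        structure = read_pdb(config.pdb)
    structure = select_chain(structure, config.chain)
    candidates = enumerate_candidate_mutations(structure, config.chain)

    all_predictions: list[design.ScorePrediction] = []
    for name in config.scorers:
        logger.info("design stage: scoring %d candidates with %s",
                    len(candidates), name)
        scorer = design.get_scorer(name)
        all_predictions.extend(design.score_library(structure, candidates, scorer))
    for path in config.predictions:
        all_predictions.extend(design.predictions_from_csv(path, config.chain))

    selected = design.apply_thresholds(all_predictions, thresholds)
    library = design.merge_libraries([selected])
    if config.msa is not None:
        consensus = design.consensus_design(
            config.msa, structure.sequence(config.chain),
            config.min_frequency, config.min_depth, config.chain,
        )
        consensus_selected = [
            design.ScoredMutation(m, scores={"consensus": 0.0},
                                  selected_by={"consensus"})
            for m in consensus
        ]
        library = design.merge_libraries([library, consensus_selected])

    lib_path = out_dir / "library.csv"
    design.library_to_frame(library).to_csv(lib_path, index=False)
    insp_path = out_dir / "inspection.csv"
    inspection_report(structure, library).to_csv(insp_path, index=False)
    manifest = write_manifest(out_dir, asdict(config), [lib_path, insp_path])
    logger.info("design stage: %d candidates selected", len(library))
    return {"library": lib_path, "inspection": insp_path, "manifest": manifest,
            "selected": library}


def run_full_demo(seed: int = 0, out_dir: str | Path = "grape_demo",
                  n_residues: int = 24) -> dict:
    """Offline end-to-end demonstration on generated inputs.

    Generates a toy helix, plants per-algorithm scores for a saturation
    scan, selects and merges the candidate library, "measures" each
    selected single on a synthetic noise-free epistatic landscape, keeps
    singles with ΔTm >= 1.5 °C, computes their features, clusters them,
    runs greedy accumulation to convergence in every cluster, and combines
    the cluster winners. All intermediate tables, a summary and a checksum
    manifest are written to ``out_dir``; two runs with the same seed
    produce byte-identical artifacts.
    """
    rng = np.random.default_rng(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []

    structure, pdb_text = make_toy_pdb(n_residues, "helix", "random",
                                       seed=int(rng.integers(2**31 - 1)))
    pdb_path = out / "structure.pdb"
    pdb_path.write_text(pdb_text)
    artifacts.append(pdb_path)

    candidates = enumerate_candidate_mutations(structure, "A")
    # plant correlated per-algorithm scores: shared stability component plus
    # per-algorithm disagreement
    base = rng.normal(0.0, 1.0, size=len(candidates))
    predictions: list[design.ScorePrediction] = []
    scales = {"foldx": 1.0, "rosetta": 0.7, "abacus": 1.7}
    for algo, scale in scales.items():
        noise = rng.normal(0.0, 0.5, size=len(candidates))
        for m, b, e in zip(candidates, base, noise):
            predictions.append(design.ScorePrediction(
                mutation=m, algorithm=algo, score=float(scale * (b + e)),
                unit="arbitrary",
            ))
    pred_path = out / "predictions.csv"
    design.predictions_to_csv(predictions, pred_path)
    artifacts.append(pred_path)

    selected = design.apply_thresholds(predictions, design.ThresholdConfig())
    library = design.merge_libraries([selected])
    lib_path = out / "library.csv"
    design.library_to_frame(library).to_csv(lib_path, index=False)
    artifacts.append(lib_path)

    insp_path = out / "inspection.csv"
    inspection_report(structure, library).to_csv(insp_path, index=False)
    artifacts.append(insp_path)

    # synthetic "wet lab": noise-free epistatic landscape over the library
    names = [sm.mutation.name for sm in library]
    landscape = greedy.simulate_landscape(
        n=len(names), names=names,
        effect_distribution=(1.0, 2.0),
        epistasis_fraction=0.2, epistasis_sd=1.0, noise_sd=0.0,
        seed=int(rng.integers(2**31 - 1)),
    )
    singles = pd.DataFrame({
        "mutation": names,
        "delta_tm": [landscape.measure({m}) for m in names],
    })
    singles_path = out / "singles.csv"
    singles.to_csv(singles_path, index=False)
    artifacts.append(singles_path)

    stabilizing = singles[
        singles["delta_tm"] >= greedy.DEFAULT_MIN_IMPROVEMENT
    ].reset_index(drop=True)
    # one substitution per site can be combined: keep the best per position
    stabilizing = stabilizing.assign(
        _pos=[Mutation.parse(m).position for m in stabilizing["mutation"]]
    ).sort_values(
        ["_pos", "delta_tm"], ascending=[True, False]
    ).drop_duplicates("_pos").drop(columns="_pos").reset_index(drop=True)
    entries = [
        (Mutation.parse(row["mutation"]), float(row["delta_tm"]))
        for _, row in stabilizing.iterrows()
    ]
    table = features.feature_table(entries, structure)
    feat_path = out / "features.csv"
    table.to_csv(feat_path, index=False)
    artifacts.append(feat_path)

    assignment = cluster_mod.cluster_mutations(table, k="auto", seed=seed)
    clusters_path = out / "clusters.csv"
    pd.DataFrame(
        sorted(assignment.labels.items()), columns=["mutation", "cluster"]
    ).to_csv(clusters_path, index=False)
    artifacts.append(clusters_path)
    summary_path = out / "cluster_summary.csv"
    cluster_mod.cluster_report(assignment, table).to_csv(summary_path, index=False)
    artifacts.append(summary_path)

    # greedy accumulation within each cluster, ΔTm-descending candidate order
    dtm = dict(zip(table["mutation"], table["delta_tm"]))
    paths: dict[int, greedy.AccumulationPath] = {}
    for c, members in assignment.members.items():
        ordered = sorted(members, key=lambda m: -dtm[m])
        paths[c] = greedy.greedy_accumulate(ordered, landscape.measure)
    final = greedy.combine_cluster_winners(paths, landscape.measure)

    best_single = float(singles["delta_tm"].max())
    summary = {
        "seed": seed,
        "n_residues": n_residues,
        "n_candidates": len(candidates),
        "n_selected": len(library),
        "n_stabilizing_singles": int(len(stabilizing)),
        "best_single_delta_tm": best_single,
        "k_clusters": assignment.k,
        "silhouette": assignment.silhouette,
        "per_cluster": {
            str(c): {
                "accepted": p.accepted,
                "final_delta_tm": p.final_delta_tm,
                "evaluations": p.evaluations_used,
                "stop_reason": p.stop_reason,
            } for c, p in paths.items()
        },
        "final_variant": "+".join(final.accepted),
        "final_delta_tm": final.final_delta_tm,
    }
    summary_path_json = out / "summary.json"
    summary_path_json.write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n")
    artifacts.append(summary_path_json)

    write_manifest(out, {"seed": seed, "n_residues": n_residues}, artifacts)
    logger.info(
        "demo: %d selected, %d stabilizing singles, k=%d, final ΔTm %.2f °C",
        len(library), len(stabilizing), assignment.k, final.final_delta_tm,
    )
    return {"out_dir": out, "summary": summary, "paths": paths,
            "landscape": landscape, "assignment": assignment}
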