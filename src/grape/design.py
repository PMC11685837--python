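"""Stabilizing single-point mutation library design.

Per-algorithm ΔΔG-style scores are produced through a pluggable scorer
registry (more negative = more stabilizing, whatever the native unit), then
filtered against per-algorithm thresholds and merged into one candidate
library. The default thresholds follow established practice for the three
canonical predictors: FoldX at −1.5 kcal/mol, Rosetta at −1.0 REU and
ABACUS at −2.5 AEU. A mutation enters the library when it passes at least
one algorithm's threshold (boundary inclusive), so the merged library is
the union of the per-algorithm selections — complementary predictors
enlarge rather than intersect the candidate pool.

External predictors plug in by registering a callable with signature
``(structure, mutation) -> float``; the two built-ins are a fixture-driven
"planted" scorer and a heavy-atom contact-count scorer that lets the whole
pipeline run offline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from Bio import AlignIO

from .structure_io import Mutation, ProteinStructure, StructureError, build_mutant

__all__ = [
    "ScorePrediction",
    "ThresholdConfig",
    "ScoredMutation",
    "StabilityScorer",
    "PlantedScorer",
    "ContactScorer",
    "get_scorer",
    "register_scorer",
    "score_library",
    "apply_thresholds",
    "merge_libraries",
    "exclusivity_report",
    "consensus_design",
    "predictions_to_csv",
    "predictions_from_csv",
    "library_to_frame",
    "DEFAULT_THRESHOLDS",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScorePrediction:
    """One algorithm's score for one mutation (more negative = more stabilizing)."""

    mutation: Mutation
    algorithm: str
    score: float
    unit: str = "arbitrary"

    def __post_init__(self):
        if not np.isfinite(self.score):
            raise ValueError(
                f"non-finite score for {self.mutation.name} ({self.algorithm})"
            )


DEFAULT_THRESHOLDS = {"foldx": -1.5, "rosetta": -1.0, "abacus": -2.5}


@dataclass(frozen=True)
class ThresholdConfig:
    """Per-algorithm selection cutoffs; a score <= threshold selects (the
    boundary is inclusive by default)."""

    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    boundary_inclusive: bool = True

    @classmethod
    def parse(cls, text: str) -> "ThresholdConfig":
        """Parse ``"foldx=-1.5,rosetta=-1.0"`` style strings."""
        pairs = {}
        for item in text.split(","):
            name, value = item.split("=")
            pairs[name.strip()] = float(value)
        return cls(thresholds=pairs)

    def passes(self, algorithm: str, score: float) -> bool:
        if algorithm not in self.thresholds:
            raise KeyError(
                f"no threshold configured for algorithm {algorithm!r}; "
                f"known: {sorted(self.thresholds)}"
            )
        cutoff = self.thresholds[algorithm]
        return score <= cutoff if self.boundary_inclusive else score < cutoff


@dataclass
class ScoredMutation:
    """A mutation with its per-algorithm scores and the algorithms that
    selected it."""

    mutation: Mutation
    scores: dict[str, float] = field(default_factory=dict)
    selected_by: set[str] = field(default_factory=set)

    def __post_init__(self):
        if not self.selected_by <= set(self.scores):
            raise ValueError("selected_by must be a subset of scored algorithms")


# -- scorer registry ---------------------------------------------------------


class StabilityScorer:
    """Scorer contract: a registered name plus ``score(structure, mutation)``.

    Subprocess adapters for external force-field or statistical-energy
    predictors implement this same contract and register under their name.
    """

    name: str = "abstract"
    unit: str = "arbitrary"

    def score(self, structure: ProteinStructure, mutation: Mutation) -> float:
        raise NotImplementedError


class PlantedScorer(StabilityScorer):
    """Fixture-driven scorer: returns planted effects by mutation name."""

    name = "planted"

    def __init__(self, effects: dict[str, float], default: float = 1.0,
                 name: str | None = None, unit: str = "arbitrary"):
        self.effects = dict(effects)
        self.default = default
        if name is not None:
            self.name = name
        self.unit = unit

    def score(self, structure: ProteinStructure, mutation: Mutation) -> float:
        return float(self.effects.get(mutation.name, self.default))


class ContactScorer(StabilityScorer):
    """Heavy-atom packing scorer: score = −(Δ contacts) around the mutated
    side chain, in arbitrary units.

    Contacts are heavy-atom pairs between the mutated residue's side chain
    and other residues within the cutoff; a mutant that gains packing
    contacts over the wild type scores negative (stabilizing). Deliberately
    simple — it exists so the full pipeline runs end-to-end offline, not as
    a calibrated energy function.
    """

    name = "contact"

    def __init__(self, cutoff: float = 4.5):
        self.cutoff = cutoff

    def _side_chain_contacts(self, structure: ProteinStructure,
                             mutation: Mutation) -> int:
        res = structure.residue_atoms(mutation.chain_id, mutation.position,
                                      mutation.ins_code)
        side_mask = ~np.isin(res.atom_name, ("N", "CA", "C", "O"))
        if not side_mask.any():
            return 0
        side = np.asarray(res.coord[side_mask], dtype=float)
        others = []
        for key in structure.residue_keys():
            if key == (mutation.chain_id, mutation.position, mutation.ins_code):
                continue
            others.append(np.asarray(
                structure.residue_atoms(*key).coord, dtype=float))
        if not others:
            return 0
        other_coords = np.vstack(others)
        tree = cKDTree(other_coords)
        return int(sum(len(tree.query_ball_point(c, self.cutoff)) for c in side))

    def score(self, structure: ProteinStructure, mutation: Mutation) -> float:
        wt_contacts = self._side_chain_contacts(structure, mutation)
        mutant = build_mutant(structure, mutation)
        mut_contacts = self._side_chain_contacts(mutant, mutation)
        return float(-(mut_contacts - wt_contacts))


_SCORERS: dict[str, type[StabilityScorer]] = {}


def register_scorer(cls: type[StabilityScorer]) -> type[StabilityScorer]:
    _SCORERS[cls.name] = cls
    return cls


register_scorer(ContactScorer)


def get_scorer(name: str, **kwargs) -> StabilityScorer:
    if name not in _SCORERS:
        raise KeyError(f"unknown scorer {name!r}; registered: {sorted(_SCORERS)}")
    return _SCORERS[name](**kwargs)


# -- scoring and selection ---------------------------------------------------


def score_library(
    structure: ProteinStructure,
    mutations: list[Mutation],
    scorer: StabilityScorer,
) -> list[ScorePrediction]:
    """Score every mutation with one scorer; individual scorer failures are
    recorded and skipped rather than aborting the scan."""
    predictions: list[ScorePrediction] = []
    failures: list[str] = []
    for mutation in mutations:
        try:
            value = scorer.score(structure, mutation)
            predictions.append(ScorePrediction(
                mutation=mutation, algorithm=scorer.name,
                score=float(value), unit=scorer.unit,
            ))
        except Exception as exc:  # noqa: BLE001 - scorer adapters may raise anything
            failures.append(f"{mutation.name}: {exc}")
    if failures:
        logger.warning(
            "%s scorer failed on %d/%d mutations: %s",
            scorer.name, len(failures), len(mutations), "; ".join(failures[:5]),
        )
    return predictions


def apply_thresholds(
    predictions: list[ScorePrediction],
    config: ThresholdConfig | None = None,
) -> list[ScoredMutation]:
    """Select mutations passing at least one algorithm's threshold.

    Every prediction's algorithm must have a configured threshold;
    ``selected_by`` records exactly the algorithms whose cutoff the
    mutation met.
    """
    config = config or ThresholdConfig()
    by_mutation: dict[str, ScoredMutation] = {}
    order: list[str] = []
    for pred in predictions:
        if pred.algorithm not in config.thresholds:
            raise KeyError(
                f"no threshold configured for algorithm {pred.algorithm!r}; "
                f"known: {sorted(config.thresholds)}"
            )
        key = (pred.mutation.chain_id, pred.mutation.name)
        if key not in by_mutation:
            by_mutation[key] = ScoredMutation(mutation=pred.mutation)
            order.append(key)
        entry = by_mutation[key]
        entry.scores[pred.algorithm] = pred.score
        if config.passes(pred.algorithm, pred.score):
            entry.selected_by.add(pred.algorithm)
    return [by_mutation[k] for k in order if by_mutation[k].selected_by]


def merge_libraries(selected: list[list[ScoredMutation]]) -> list[ScoredMutation]:
    """Union of per-algorithm libraries keyed by mutation identity; score
    maps and selected_by sets are merged, output sorted by position then
    mutant residue."""
    merged: dict[tuple, ScoredMutation] = {}
    wt_at_position: dict[tuple, str] = {}
    for library in selected:
        for sm in library:
            m = sm.mutation
            pos_key = (m.chain_id, m.position, m.ins_code)
            if pos_key in wt_at_position and wt_at_position[pos_key] != m.wt_aa:
                raise StructureError(
                    f"conflicting wild-type residue at {m.chain_id}{m.position}: "
                    f"{wt_at_position[pos_key]} vs {m.wt_aa}"
                )
            wt_at_position[pos_key] = m.wt_aa
            key = (m.chain_id, m.position, m.ins_code, m.mut_aa)
            if key not in merged:
                merged[key] = ScoredMutation(mutation=m)
            merged[key].scores.update(sm.scores)
            merged[key].selected_by |= sm.selected_by
    return sorted(
        merged.values(),
        key=lambda sm: (sm.mutation.chain_id, sm.mutation.position,
                        sm.mutation.ins_code, sm.mutation.mut_aa),
    )


def exclusivity_report(selected: list[ScoredMutation]) -> dict[str, dict[str, int]]:
    """Per-algorithm complementarity counts: mutations selected only by that
    algorithm (exclusive), selected by it and at least one other (shared),
    and their sum (total)."""
    algorithms = sorted({a for sm in selected for a in sm.selected_by})
    report = {a: {"exclusive": 0, "shared": 0, "total": 0} for a in algorithms}
    for sm in selected:
        for a in sm.selected_by:
            report[a]["total"] += 1
            if len(sm.selected_by) == 1:
                report[a]["exclusive"] += 1
            else:
                report[a]["shared"] += 1
    return report


# -- consensus design --------------------------------------------------------


def consensus_design(
    msa_path,
    target_sequence: str,
    min_frequency: float = 0.6,
    min_depth: int = 10,
    chain_id: str = "A",
    position_offset: int = 0,
) -> list[Mutation]:
    """Propose back-to-consensus mutations from an aligned FASTA.

    The target sequence must match one MSA row exactly (after removing that
    row's gaps) — the anchor row. For each target position whose aligned
    column has a modal non-gap residue, at frequency >= ``min_frequency``
    over >= ``min_depth`` non-gap symbols, differing from the target
    residue, a mutation to the modal residue is proposed. Columns where the
    anchor row has a gap are never considered (no insertion design).
    Positions are 1-based plus ``position_offset``.
    """
    alignment = AlignIO.read(msa_path, "fasta")
    rows = [str(rec.seq).upper() for rec in alignment]
    anchor = None
    for row in rows:
        if row.replace("-", "").replace(".", "") == target_sequence.upper():
            anchor = row
            break
    if anchor is None:
        raise StructureError(
            "target sequence does not match any MSA row (gaps removed)"
        )
    proposals: list[Mutation] = []
    target_pos = 0
    for col in range(len(anchor)):
        aa_anchor = anchor[col]
        if aa_anchor in "-.":
            continue
        target_pos += 1
        column = [row[col] for row in rows if col < len(row)]
        residues = [c for c in column if c not in "-." and c != "X"]
        if len(residues) < min_depth:
            continue
        values, counts = np.unique(residues, return_counts=True)
        best = int(np.argmax(counts))
        modal, freq = str(values[best]), counts[best] / len(residues)
        if modal == aa_anchor or freq < min_frequency:
            continue
        proposals.append(Mutation(
            chain_id=chain_id, wt_aa=aa_anchor,
            position=target_pos + position_offset, mut_aa=modal,
        ))
    return proposals


# -- tabular I/O -------------------------------------------------------------


def predictions_to_csv(predictions: list[ScorePrediction], path=None) -> pd.DataFrame:
    """Write the interchange CSV ``mutation,algorithm,score,unit``."""
    df = pd.DataFrame([
        {"mutation": p.mutation.name, "algorithm": p.algorithm,
         "score": p.score, "unit": p.unit}
        for p in predictions
    ], columns=["mutation", "algorithm", "score", "unit"])
    if path is not None:
        df.to_csv(path, index=False)
    return df


def predictions_from_csv(path, chain_id: str = "A") -> list[ScorePrediction]:
    df = pd.read_csv(path)
    return [
        ScorePrediction(
            mutation=Mutation.parse(str(row["mutation"]), chain_id),
            algorithm=str(row["algorithm"]),
            score=float(row["score"]),
            unit=str(row.get("unit", "arbitrary")),
        )
        for _, row in df.iterrows()
    ]


def library_to_frame(selected: list[ScoredMutation]) -> pd.DataFrame:
    """Selected-library table: mutation identity, one score column per
    algorithm, and the selecting algorithms."""
    algorithms = sorted({a for sm in selected for a in sm.scores})
    rows = []
    for sm in selected:
        row = {
            "mutation": sm.mutation.name,
            "wt": sm.mutation.wt_aa,
            "position": sm.mutation.position,
            "mut": sm.mutation.mut_aa,
        }
        for a in algorithms:
            row[f"score_{a}"] = sm.scores.get(a, np.nan)
        row["selected_by"] = "+".join(sorted(sm.selected_by))
        rows.append(row)
    columns = ["mutation", "wt", "position", "mut"] + \
        [f"score_{a}" for a in algorithms] + ["selected_by"]
    return pd.DataFrame(rows, columns=columns)
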