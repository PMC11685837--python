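"""Structure-based mutation features for clustering stabilizing variants.

For each validated stabilizing mutation the feature vector combines the
measured melting-temperature improvement (ΔTm, °C), the change in
hydrogen-bond count and in hydrophobic-contact count between a naive mutant
model and the wild type (restricted to the local environment of the mutated
residue), a binary backbone-entropy flag, and the wild-type Cα coordinates
of the mutated position.

Hydrogen bonds use a hydrogen-free heavy-atom criterion: donor-acceptor
distance at most ``hbond_distance_cutoff`` and antecedent-donor-acceptor
angle at least ``hbond_angle_min`` (the antecedent is the heavy atom bonded
to the donor, standing in for the absent hydrogen). Hydrophobic contacts
count side-chain carbon pairs of apolar residues within
``hydrophobic_cutoff``, at sequence separation >= 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .chemistry import (
    BACKBONE_ATOMS,
    ENTROPY_AA1,
    HYDROPHOBIC_AA1,
    THREE_TO_ONE,
    acceptor_atoms,
    donor_atoms,
)
from .structure_io import Mutation, ProteinStructure, StructureError, build_mutant

__all__ = [
    "FeatureConfig",
    "HBond",
    "MutationFeatureVector",
    "detect_hbonds",
    "count_hydrophobic_contacts",
    "entropy_flag",
    "compute_features",
    "feature_table",
    "read_mutation_table",
    "FEATURE_COLUMNS",
]


@dataclass(frozen=True)
class FeatureConfig:
    """Geometric cutoffs for the interaction features.

    hbond_distance_cutoff : Å, donor-acceptor heavy-atom distance.
    hbond_angle_min : degrees, antecedent-donor-acceptor angle.
    hydrophobic_cutoff : Å, side-chain carbon-carbon distance.
    environment_radius : Å, radius around the mutated residue within which
        interaction changes are counted, so distant structural noise cannot
        contaminate a local feature.
    """

    hbond_distance_cutoff: float = 3.5
    hbond_angle_min: float = 90.0
    hydrophobic_cutoff: float = 5.0
    environment_radius: float = 8.0


DEFAULT_CONFIG = FeatureConfig()


@dataclass(frozen=True)
class HBond:
    """One detected hydrogen bond between heavy atoms."""

    donor_residue: tuple[str, int, str]
    donor_atom: str
    acceptor_residue: tuple[str, int, str]
    acceptor_atom: str
    distance: float
    angle: float

    @property
    def atom_pair(self) -> frozenset:
        return frozenset([
            (self.donor_residue, self.donor_atom),
            (self.acceptor_residue, self.acceptor_atom),
        ])


def _polar_sites(structure: ProteinStructure):
    """Collect donor sites (with antecedent coordinates) and acceptor sites."""
    donors = []    # (res_key, atom_name, coord, antecedent_coord)
    acceptors = []  # (res_key, atom_name, coord)
    for key in structure.residue_keys():
        res = structure.residue_atoms(*key)
        res_name = str(res.res_name[0])
        names = list(res.atom_name)
        for donor, antecedent in donor_atoms(res_name).items():
            if donor in names and antecedent in names:
                donors.append((
                    key, donor,
                    np.asarray(res.coord[names.index(donor)], dtype=float),
                    np.asarray(res.coord[names.index(antecedent)], dtype=float),
                ))
        for acc in acceptor_atoms(res_name):
            if acc in names:
                acceptors.append((
                    key, acc,
                    np.asarray(res.coord[names.index(acc)], dtype=float),
                ))
    return donors, acceptors


def detect_hbonds(
    structure: ProteinStructure,
    residue_scope: set | None = None,
    config: FeatureConfig = DEFAULT_CONFIG,
) -> list[HBond]:
    """Detect hydrogen bonds between heavy N/O donor and acceptor atoms.

    Intra-residue pairs are excluded and each unordered atom pair is
    reported once (when both directions qualify, the shorter-listed donor
    direction is kept). ``residue_scope``, when given, restricts output to
    bonds touching at least one residue key in the scope.
    """
    donors, acceptors = _polar_sites(structure)
    if not donors or not acceptors:
        return []
    acc_coords = np.array([a[2] for a in acceptors])
    tree = cKDTree(acc_coords)
    seen: set[frozenset] = set()
    bonds: list[HBond] = []
    for d_key, d_name, d_coord, ant_coord in donors:
        for j in tree.query_ball_point(d_coord, config.hbond_distance_cutoff):
            a_key, a_name, a_coord = acceptors[j]
            if a_key == d_key:
                continue
            if residue_scope is not None and \
                    d_key not in residue_scope and a_key not in residue_scope:
                continue
            dist = float(np.linalg.norm(a_coord - d_coord))
            if dist < 1e-6:
                continue
            v1 = ant_coord - d_coord
            v2 = a_coord - d_coord
            cosang = (v1 @ v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
            if angle < config.hbond_angle_min:
                continue
            pair = frozenset([(d_key, d_name), (a_key, a_name)])
            if pair in seen:
                continue
            seen.add(pair)
            bonds.append(HBond(d_key, d_name, a_key, a_name, dist, angle))
    return bonds


def count_hydrophobic_contacts(
    structure: ProteinStructure,
    residue_scope: set | None = None,
    config: FeatureConfig = DEFAULT_CONFIG,
) -> int:
    """Count side-chain carbon-carbon contacts between apolar residues.

    A contact is a pair of side-chain carbon atoms, one from each of two
    residues in the hydrophobic set separated by at least 2 in sequence,
    at distance <= the cutoff. Each atom pair counts once.
    """
    sites = []  # (res_key, seq_pos, coord)
    seq_pos = {key: i for i, key in enumerate(structure.residue_keys())}
    for key in structure.residue_keys():
        res = structure.residue_atoms(*key)
        if THREE_TO_ONE[str(res.res_name[0])] not in HYDROPHOBIC_AA1:
            continue
        mask = (res.element == "C") & ~np.isin(res.atom_name, sorted(BACKBONE_ATOMS))
        for coord in res.coord[mask]:
            sites.append((key, seq_pos[key], np.asarray(coord, dtype=float)))
    if len(sites) < 2:
        return 0
    coords = np.array([s[2] for s in sites])
    tree = cKDTree(coords)
    count = 0
    for i, j in tree.query_pairs(config.hydrophobic_cutoff):
        ki, pi = sites[i][0], sites[i][1]
        kj, pj = sites[j][0], sites[j][1]
        if abs(pi - pj) < 2:
            continue
        if residue_scope is not None and \
                ki not in residue_scope and kj not in residue_scope:
            continue
        count += 1
    return count


def entropy_flag(mutation: Mutation) -> int:
    """1 if the substitution involves glycine or proline on either side
    (potential backbone conformational-entropy change), else 0."""
    involved = {mutation.wt_aa, mutation.mut_aa}
    return int(bool(involved & ENTROPY_AA1))


@dataclass(frozen=True)
class MutationFeatureVector:
    """The clustering feature vector of one validated stabilizing mutation."""

    mutation: Mutation
    delta_tm: float
    d_hbond: int
    d_hydrophobic: int
    entropy_flag: int
    ca_x: float
    ca_y: float
    ca_z: float


def _environment_scope(structure: ProteinStructure, mutation: Mutation,
                       radius: float) -> set:
    """Residue keys with any atom within *radius* of the mutated residue."""
    res = structure.residue_atoms(mutation.chain_id, mutation.position,
                                  mutation.ins_code)
    tree = cKDTree(np.asarray(res.coord, dtype=float))
    scope = set()
    for key in structure.residue_keys():
        other = structure.residue_atoms(*key)
        d, _ = tree.query(np.asarray(other.coord, dtype=float), k=1)
        if np.min(d) <= radius:
            scope.add(key)
    return scope


def compute_features(
    wt: ProteinStructure,
    mutation: Mutation,
    delta_tm: float,
    mutant: ProteinStructure | None = None,
    config: FeatureConfig = DEFAULT_CONFIG,
) -> MutationFeatureVector:
    """Compute one mutation's feature vector against the wild-type structure.

    Interaction changes are mutant count minus wild-type count, restricted
    to residues with any atom within ``config.environment_radius`` of the
    mutated residue; the Cα coordinate is taken from the wild type.
    """
    if mutant is None:
        mutant = build_mutant(wt, mutation)
    scope_wt = _environment_scope(wt, mutation, config.environment_radius)
    scope_mut = _environment_scope(mutant, mutation, config.environment_radius)
    d_hbond = (
        len(detect_hbonds(mutant, scope_mut, config))
        - len(detect_hbonds(wt, scope_wt, config))
    )
    d_hydro = (
        count_hydrophobic_contacts(mutant, scope_mut, config)
        - count_hydrophobic_contacts(wt, scope_wt, config)
    )
    ca = wt.ca_coord(mutation.chain_id, mutation.position, mutation.ins_code)
    return MutationFeatureVector(
        mutation=mutation,
        delta_tm=float(delta_tm),
        d_hbond=int(d_hbond),
        d_hydrophobic=int(d_hydro),
        entropy_flag=entropy_flag(mutation),
        ca_x=float(ca[0]), ca_y=float(ca[1]), ca_z=float(ca[2]),
    )


FEATURE_COLUMNS = [
    "mutation", "position", "delta_tm",
    "hbond", "hydrophobic", "entropy",
    "ca_x", "ca_y", "ca_z",
]


def feature_table(
    entries: list[tuple[Mutation, float]],
    wt: ProteinStructure,
    config: FeatureConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Feature vectors for a list of (mutation, ΔTm) pairs as a DataFrame
    in the canonical column order; serializable to CSV."""
    names = [m.name for m, _ in entries]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise StructureError(f"duplicate mutation names: {sorted(dupes)}")
    rows = []
    for mutation, delta_tm in entries:
        fv = compute_features(wt, mutation, delta_tm, config=config)
        rows.append({
            "mutation": mutation.name,
            "position": mutation.position,
            "delta_tm": fv.delta_tm,
            "hbond": fv.d_hbond,
            "hydrophobic": fv.d_hydrophobic,
            "entropy": fv.entropy_flag,
            "ca_x": fv.ca_x, "ca_y": fv.ca_y, "ca_z": fv.ca_z,
        })
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def read_mutation_table(path, chain_id: str = "A") -> list[tuple[Mutation, float]]:
    """Read validated mutations with ΔTm values from .csv (columns
    ``mutation,delta_tm``) or whitespace-separated .txt (two columns)."""
    text = open(path).read()
    entries: list[tuple[Mutation, float]] = []
    if "," in text.splitlines()[0]:
        df = pd.read_csv(path)
        if not {"mutation", "delta_tm"} <= set(df.columns):
            raise StructureError(
                "mutation CSV needs columns 'mutation' and 'delta_tm'"
            )
        for _, row in df.iterrows():
            entries.append((Mutation.parse(str(row["mutation"]), chain_id),
                            float(row["delta_tm"])))
    else:
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, value = line.split()
            entries.append((Mutation.parse(name, chain_id), float(value)))
    return entries
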