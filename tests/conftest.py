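"""Shared fixtures and independent brute-force oracles.

The geometric oracles here deliberately re-derive hydrogen bonds and
hydrophobic contacts by full O(n²) pair enumeration with numpy distance
matrices, independent of the neighbor-tree implementation they check.
"""

import numpy as np
import pytest
import biotite.structure as struc
from scipy.spatial.distance import cdist

from grape.chemistry import (
    BACKBONE_ATOMS,
    HYDROPHOBIC_AA1,
    THREE_TO_ONE,
    acceptor_atoms,
    donor_atoms,
)
from grape.structure_io import ProteinStructure, make_toy_pdb


def _element_of(atom_name: str) -> str:
    return atom_name[0]


def make_custom_structure(residues, chain_id="A"):
    """Build a ProteinStructure from hand-placed atoms.

    ``residues``: list of (res_name3, res_id, [(atom_name, (x, y, z)), ...]).
    """
    n = sum(len(atoms) for _, _, atoms in residues)
    arr = struc.AtomArray(n)
    i = 0
    for res_name, res_id, atoms in residues:
        for name, coord in atoms:
            arr.atom_name[i] = name
            arr.element[i] = _element_of(name)
            arr.res_name[i] = res_name
            arr.res_id[i] = res_id
            arr.chain_id[i] = chain_id
            arr.coord[i] = coord
            i += 1
    arr.hetero = np.zeros(n, dtype=bool)
    return ProteinStructure(arr)


# -- brute-force geometric oracles -------------------------------------------


def brute_force_hbonds(structure, config=None):
    """All-pairs hydrogen-bond scan; returns the set of unordered atom pairs."""
    from grape.features import DEFAULT_CONFIG

    config = config or DEFAULT_CONFIG
    donors, acceptors = [], []
    for key in structure.residue_keys():
        res = structure.residue_atoms(*key)
        res_name = str(res.res_name[0])
        names = list(res.atom_name)
        for donor, antecedent in donor_atoms(res_name).items():
            if donor in names and antecedent in names:
                donors.append((key, donor, res.coord[names.index(donor)],
                               res.coord[names.index(antecedent)]))
        for acc in acceptor_atoms(res_name):
            if acc in names:
                acceptors.append((key, acc, res.coord[names.index(acc)]))
    pairs = set()
    for d_key, d_name, d_xyz, ant_xyz in donors:
        for a_key, a_name, a_xyz in acceptors:
            if a_key == d_key:
                continue
            dist = float(np.linalg.norm(np.asarray(a_xyz) - np.asarray(d_xyz)))
            if dist > config.hbond_distance_cutoff or dist < 1e-6:
                continue
            v1 = np.asarray(ant_xyz, float) - np.asarray(d_xyz, float)
            v2 = np.asarray(a_xyz, float) - np.asarray(d_xyz, float)
            cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
            if np.degrees(np.arccos(np.clip(cosang, -1, 1))) < config.hbond_angle_min:
                continue
            pairs.add(frozenset([(d_key, d_name), (a_key, a_name)]))
    return pairs


def brute_force_hydrophobic(structure, config=None):
    """All-pairs hydrophobic side-chain carbon contact count."""
    from grape.features import DEFAULT_CONFIG

    config = config or DEFAULT_CONFIG
    seq_pos = {key: i for i, key in enumerate(structure.residue_keys())}
    sites = []
    for key in structure.residue_keys():
        res = structure.residue_atoms(*key)
        if THREE_TO_ONE[str(res.res_name[0])] not in HYDROPHOBIC_AA1:
            continue
        for j in range(res.array_length()):
            if str(res.element[j]) == "C" and \
                    str(res.atom_name[j]) not in BACKBONE_ATOMS:
                sites.append((seq_pos[key], res.coord[j]))
    count = 0
    if len(sites) >= 2:
        coords = np.array([s[1] for s in sites], dtype=float)
        dist = cdist(coords, coords)
        for i in range(len(sites)):
            for j in range(i + 1, len(sites)):
                if abs(sites[i][0] - sites[j][0]) >= 2 and \
                        dist[i, j] <= config.hydrophobic_cutoff:
                    count += 1
    return count


def random_rotation(rng):
    """Uniform random rotation matrix via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def blob_table(n_per_blob=5, separation=8.0, seed=0):
    """Planted two-blob mutation feature table.

    The blobs emulate two mechanistically coherent groups of stabilizing
    mutations: each blob has its own ΔTm level, interaction signature and
    spatial patch, with unit within-blob spread, separated by ``separation``
    spreads along ΔTm and the Cα coordinates.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    signatures = [
        {"hbond": 1, "hydrophobic": 0, "entropy": 0},
        {"hbond": 0, "hydrophobic": 2, "entropy": 1},
    ]
    rows = []
    for blob in range(2):
        for i in range(n_per_blob):
            center = blob * separation
            rows.append({
                "mutation": f"A{blob * n_per_blob + i + 1}V",
                "position": blob * n_per_blob + i + 1,
                "delta_tm": 2.0 + center + rng.normal(scale=1.0),
                **signatures[blob],
                "ca_x": center + rng.normal(scale=1.0),
                "ca_y": center + rng.normal(scale=1.0),
                "ca_z": center + rng.normal(scale=1.0),
            })
    return pd.DataFrame(rows)


# -- fixtures ----------------------------------------------------------------


@pytest.fixture(scope="session")
def helix12():
    structure, text = make_toy_pdb(12, "helix", "ASDLKGHWYPVE", seed=1)
    return structure, text


@pytest.fixture(scope="session")
def two_chain():
    a, _ = make_toy_pdb(5, "helix", "AAAAA", seed=0)
    b, _ = make_toy_pdb(4, "strand", "GGGG", seed=0)
    atoms_b = b.atoms.copy()
    atoms_b.chain_id = np.full(atoms_b.array_length(), "B")
    atoms_b.coord = atoms_b.coord + np.array([30.0, 0.0, 0.0])
    return ProteinStructure(a.atoms + atoms_b)
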