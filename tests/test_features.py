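"""Geometric interaction features: hydrogen bonds, hydrophobic contacts,
entropy flag, feature vectors and tables."""

import numpy as np
import pytest

from conftest import (
    brute_force_hbonds,
    brute_force_hydrophobic,
    make_custom_structure,
    random_rotation,
)
from grape.features import (
    compute_features,
    count_hydrophobic_contacts,
    detect_hbonds,
    entropy_flag,
    feature_table,
    read_mutation_table,
    FEATURE_COLUMNS,
)
from grape.structure_io import Mutation, StructureError, make_toy_pdb


def constructed_nh_o_pair():
    """Two glycines whose backbone N...O pair sits at 2.9 Å with a 150°
    antecedent-donor-acceptor angle — exactly one hydrogen bond."""
    res1 = [
        ("N", (-1.4, 0.0, 0.0)), ("CA", (0.0, 0.0, 0.0)),
        ("C", (1.5, 0.0, 0.0)), ("O", (2.1, 1.0, 0.0)),
    ]
    o1 = np.array([2.1, 1.0, 0.0])
    n2 = o1 + np.array([2.9, 0.0, 0.0])
    v = np.array([np.cos(np.deg2rad(30.0)), np.sin(np.deg2rad(30.0)), 0.0])
    ca2 = n2 + 1.46 * v
    res2 = [
        ("N", tuple(n2)), ("CA", tuple(ca2)),
        ("C", tuple(ca2 + np.array([1.5, 0.0, 0.0]))),
        ("O", tuple(ca2 + np.array([2.1, 1.0, 0.0]))),
    ]
    return make_custom_structure([("GLY", 1, res1), ("GLY", 2, res2)])


class TestDetectHbonds:
    def test_distant_polar_atoms_no_bond(self):
        structure, _ = make_toy_pdb(2, "strand", "SS", seed=0)
        far = structure.transformed(np.eye(3), np.zeros(3))
        far.atoms.coord[far.atoms.res_id == 2] += np.array([10.0, 0.0, 0.0])
        assert detect_hbonds(far) == []

    def test_constructed_pair_exactly_one_bond(self):
        structure = constructed_nh_o_pair()
        bonds = detect_hbonds(structure)
        assert len(bonds) == 1
        bond = bonds[0]
        assert bond.donor_atom == "N" and bond.acceptor_atom == "O"
        assert bond.distance == pytest.approx(2.9, abs=1e-6)
        assert bond.angle == pytest.approx(150.0, abs=1e-6)
        # independent all-pairs oracle agrees
        assert len(brute_force_hbonds(structure)) == 1

    def test_angle_gate(self):
        structure = constructed_nh_o_pair()
        # tightening the angle cutoff beyond 150° removes the bond
        from grape.features import FeatureConfig

        strict = FeatureConfig(hbond_angle_min=160.0)
        assert detect_hbonds(structure, config=strict) == []

    def test_isometry_invariance(self, helix12):
        structure, _ = helix12
        baseline = {b.atom_pair for b in detect_hbonds(structure)}
        rng = np.random.default_rng(7)
        for _ in range(5):
            moved = structure.transformed(random_rotation(rng),
                                          rng.normal(scale=20.0, size=3))
            assert {b.atom_pair for b in detect_hbonds(moved)} == baseline

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_random_structures(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 25))
        geometry = ["helix", "strand", "coil"][seed % 3]
        structure, _ = make_toy_pdb(n, geometry, "random", seed=seed)
        found = {frozenset([(b.donor_residue, b.donor_atom),
                            (b.acceptor_residue, b.acceptor_atom)])
                 for b in detect_hbonds(structure)}
        assert found == brute_force_hbonds(structure)


class TestHydrophobicContacts:
    def test_all_glycine_zero(self):
        structure, _ = make_toy_pdb(6, "helix", "GGGGGG", seed=0)
        assert count_hydrophobic_contacts(structure) == 0

    def test_distant_leucines_zero(self):
        structure, _ = make_toy_pdb(3, "strand", "LGL", seed=0)
        moved = structure.transformed(np.eye(3), np.zeros(3))
        moved.atoms.coord[moved.atoms.res_id == 3] += np.array([20.0, 0.0, 0.0])
        assert count_hydrophobic_contacts(moved) == 0

    def test_constructed_val_leu_three_contacts(self):
        backbone = lambda z: [("N", (-10.0, -1.0, z)), ("CA", (-10.0, 0.0, z)),
                              ("C", (-10.0, 1.0, z)), ("O", (-10.0, 2.0, z))]
        val = [("CB", (0.0, 0.0, 0.0)), ("CG1", (1.5, 0.0, 0.0)),
               ("CG2", (-1.5, 0.0, 0.0))]
        leu = [("CB", (0.0, 4.0, 0.0)), ("CG", (0.0, 5.5, 0.0)),
               ("CD1", (1.5, 6.3, 0.0)), ("CD2", (-1.5, 6.3, 0.0))]
        structure = make_custom_structure([
            ("VAL", 1, backbone(0.0) + val),
            ("GLY", 2, backbone(8.0)),
            ("LEU", 3, backbone(16.0) + leu),
        ])
        # CB-CB 4.0, CG1-CB 4.27, CG2-CB 4.27; everything else > 5.0
        assert count_hydrophobic_contacts(structure) == 3
        assert brute_force_hydrophobic(structure) == 3

    def test_adjacent_residues_excluded(self):
        structure, _ = make_toy_pdb(2, "helix", "LL", seed=0)
        assert count_hydrophobic_contacts(structure) == 0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_random_structures(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(6, 25))
        structure, _ = make_toy_pdb(n, ["helix", "strand", "coil"][seed % 3],
                                    "random", seed=200 + seed)
        assert count_hydrophobic_contacts(structure) == \
            brute_force_hydrophobic(structure)


class TestEntropyFlag:
    @pytest.mark.parametrize("name,expected", [
        ("A5P", 1), ("G5A", 1), ("P5G", 1), ("S5E", 0), ("L5F", 0),
    ])
    def test_glycine_proline_rule(self, name, expected):
        assert entropy_flag(Mutation.parse(name)) == expected


class TestComputeFeatures:
    def test_ca_from_wild_type(self, helix12):
        structure, _ = helix12
        fv = compute_features(structure, Mutation.parse("L4G"), delta_tm=2.0)
        assert np.allclose([fv.ca_x, fv.ca_y, fv.ca_z],
                           structure.ca_coord("A", 4))

    def test_to_glycine_never_gains_hydrophobic(self, helix12):
        structure, _ = helix12
        for name in ("L4G", "W8G", "V11G"):
            fv = compute_features(structure, Mutation.parse(name), delta_tm=2.0)
            assert fv.d_hydrophobic <= 0

    def test_planted_new_bond_counts_plus_one(self):
        wt = constructed_nh_o_pair()
        # mutant: GLY2 -> SER2 whose OG forms a second bond to O1
        o1 = np.array([2.1, 1.0, 0.0])
        res2 = [(n, tuple(np.asarray(c))) for n, c in
                zip(wt.residue_atoms("A", 2).atom_name,
                    wt.residue_atoms("A", 2).coord)]
        cb = np.array(res2[1][1]) + np.array([0.0, 1.5, 0.0])
        og_dir = (o1 - cb) / np.linalg.norm(o1 - cb)
        og = o1 - 2.9 * og_dir  # 2.9 Å from O1, antecedent CB behind it (180°)
        mut_res2 = res2 + [("CB", tuple(cb)), ("OG", tuple(og))]
        res1 = [(n, tuple(np.asarray(c))) for n, c in
                zip(wt.residue_atoms("A", 1).atom_name,
                    wt.residue_atoms("A", 1).coord)]
        mutant = make_custom_structure([("GLY", 1, res1), ("SER", 2, mut_res2)])
        delta_oracle = len(brute_force_hbonds(mutant)) - len(brute_force_hbonds(wt))
        assert delta_oracle == 1
        fv = compute_features(wt, Mutation.parse("G2S"), delta_tm=2.0,
                              mutant=mutant)
        assert fv.d_hbond == 1

    def test_antisymmetry_of_deltas(self, helix12):
        structure, _ = helix12
        from grape.structure_io import build_mutant

        mutation = Mutation.parse("K5F")
        mutant = build_mutant(structure, mutation)
        forward = compute_features(structure, mutation, 0.0, mutant=mutant)
        back = compute_features(mutant, Mutation.parse("F5K"), 0.0,
                                mutant=structure)
        assert forward.d_hbond == -back.d_hbond
        assert forward.d_hydrophobic == -back.d_hydrophobic


class TestFeatureTable:
    def entries(self):
        return [(Mutation.parse("L4G"), 2.0), (Mutation.parse("K5F"), 3.5),
                (Mutation.parse("S2P"), 1.6)]

    def test_columns_and_rows(self, helix12):
        structure, _ = helix12
        table = feature_table(self.entries(), structure)
        assert list(table.columns) == FEATURE_COLUMNS
        assert len(table) == 3
        row = table.set_index("mutation").loc["K5F"]
        assert np.allclose([row["ca_x"], row["ca_y"], row["ca_z"]],
                           structure.ca_coord("A", 5))

    def test_empty_input_gives_header_only(self, helix12):
        structure, _ = helix12
        table = feature_table([], structure)
        assert list(table.columns) == FEATURE_COLUMNS and len(table) == 0

    def test_duplicate_mutations_rejected(self, helix12):
        structure, _ = helix12
        with pytest.raises(StructureError, match="duplicate"):
            feature_table([(Mutation.parse("L4G"), 2.0),
                           (Mutation.parse("L4G"), 2.5)], structure)


class TestMutationTableIO:
    def test_csv_and_txt_variants(self, tmp_path):
        csv = tmp_path / "hits.csv"
        csv.write_text("mutation,delta_tm\nS121E,2.5\nD186H,1.6\n")
        txt = tmp_path / "hits.txt"
        txt.write_text("S121E 2.5\nD186H 1.6\n")
        for path in (csv, txt):
            entries = read_mutation_table(path)
            assert [(m.name, v) for m, v in entries] == \
                [("S121E", 2.5), ("D186H", 1.6)]
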