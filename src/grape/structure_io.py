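"""Protein structure I/O, validation, mutant building and toy-structure generation.

Structures are held as biotite ``AtomArray`` objects wrapped in
:class:`ProteinStructure`, which adds residue-level bookkeeping (author
numbering with insertion codes, per-chain sequences, Cα lookup). Parsing
keeps heavy protein atoms only: hydrogens, waters, other HETATM records and
secondary altloc copies are dropped, because every downstream feature
(hydrogen bonds by heavy-atom geometry, hydrophobic carbon contacts) is
defined on heavy atoms.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass

import numpy as np
import biotite.structure as struc
import biotite.structure.info as struc_info
from biotite.structure.io.pdb import PDBFile

from .chemistry import (
    BACKBONE_ATOMS,
    ONE_TO_THREE,
    STANDARD_AA3,
    THREE_TO_ONE,
)

__all__ = [
    "Atom",
    "Mutation",
    "ProteinStructure",
    "StructureError",
    "read_pdb",
    "read_pdb_text",
    "write_pdb",
    "select_chain",
    "enumerate_candidate_mutations",
    "build_mutant",
    "make_toy_pdb",
]


class StructureError(ValueError):
    """Raised for unparsable or chemically invalid structures and mutations."""


@dataclass(frozen=True)
class Atom:
    """One heavy atom with PDB naming and author residue identity."""

    name: str
    element: str
    coord: tuple[float, float, float]
    residue_index: int
    residue_name: str
    chain_id: str
    ins_code: str = ""

    @property
    def is_backbone(self) -> bool:
        return self.name in BACKBONE_ATOMS


_MUTATION_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


@dataclass(frozen=True)
class Mutation:
    """A single-point substitution, e.g. S121E on chain A."""

    chain_id: str
    wt_aa: str
    position: int
    mut_aa: str
    ins_code: str = ""

    def __post_init__(self):
        if self.wt_aa == self.mut_aa:
            raise StructureError(
                f"mutation at position {self.position}: wild-type and mutant "
                f"residue are both {self.wt_aa}"
            )
        for aa in (self.wt_aa, self.mut_aa):
            if aa not in ONE_TO_THREE:
                raise StructureError(f"unknown amino acid code {aa!r}")

    @property
    def name(self) -> str:
        """Canonical one-letter rendering, e.g. ``S121E``."""
        return f"{self.wt_aa}{self.position}{self.ins_code}{self.mut_aa}"

    def __str__(self) -> str:
        return self.name

    @classmethod
    def parse(cls, text: str, chain_id: str = "A") -> "Mutation":
        """Parse a canonical mutation name like ``S121E``."""
        m = _MUTATION_RE.match(text.strip())
        if m is None:
            raise StructureError(f"cannot parse mutation name {text!r}")
        return cls(chain_id=chain_id, wt_aa=m.group(1),
                   position=int(m.group(2)), mut_aa=m.group(3))


class ProteinStructure:
    """Heavy-atom protein structure backed by a biotite ``AtomArray``.

    Residue identity is (chain_id, author residue index, insertion code);
    author numbering is preserved end-to-end so mutation names match the
    numbering users see in their PDB files.
    """

    def __init__(self, atoms: struc.AtomArray, validate: bool = True):
        # keep coordinates in double precision so geometric features are
        # stable to ~1e-9 under rigid transforms (PDB I/O still rounds to
        # the format's 3 decimals)
        atoms._coord = np.asarray(atoms.coord, dtype=np.float64)
        self.atoms = atoms
        if validate:
            self._validate()
        self._index_residues()

    # -- construction helpers ------------------------------------------------

    def _validate(self) -> None:
        if self.atoms.array_length() == 0:
            raise StructureError("structure contains no parsable protein atoms")
        starts = struc.get_residue_starts(self.atoms)
        bounds = np.append(starts, self.atoms.array_length())
        prev_chain = None
        prev_key = None
        for s, e in zip(bounds[:-1], bounds[1:]):
            names = self.atoms.atom_name[s:e]
            res_id = int(self.atoms.res_id[s])
            ins = str(self.atoms.ins_code[s]) if "ins_code" in self.atoms.get_annotation_categories() else ""
            chain = str(self.atoms.chain_id[s])
            res_name = str(self.atoms.res_name[s])
            if np.count_nonzero(names == "CA") != 1:
                raise StructureError(
                    f"residue {res_name} {chain}{res_id}{ins} does not have "
                    "exactly one CA atom"
                )
            key = (res_id, ins)
            if chain == prev_chain and prev_key is not None and key <= prev_key:
                raise StructureError(
                    f"residue indices not strictly increasing in chain {chain} "
                    f"at {res_id}{ins}"
                )
            prev_chain, prev_key = chain, key

    def _index_residues(self) -> None:
        atoms = self.atoms
        if "ins_code" not in atoms.get_annotation_categories():
            atoms.set_annotation(
                "ins_code", np.full(atoms.array_length(), "", dtype="U1")
            )
        starts = struc.get_residue_starts(atoms)
        bounds = np.append(starts, atoms.array_length())
        self._res_slices: dict[tuple[str, int, str], slice] = {}
        self._res_order: list[tuple[str, int, str]] = []
        for s, e in zip(bounds[:-1], bounds[1:]):
            key = (str(atoms.chain_id[s]), int(atoms.res_id[s]),
                   str(atoms.ins_code[s]))
            self._res_slices[key] = slice(int(s), int(e))
            self._res_order.append(key)

    # -- basic queries -------------------------------------------------------

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for chain, _, _ in self._res_order:
            seen.setdefault(chain, None)
        return list(seen)

    def residue_keys(self, chain_id: str | None = None) -> list[tuple[str, int, str]]:
        if chain_id is None:
            return list(self._res_order)
        return [k for k in self._res_order if k[0] == chain_id]

    @property
    def n_residues(self) -> int:
        return len(self._res_order)

    def residue_atoms(self, chain_id: str, position: int,
                      ins_code: str = "") -> struc.AtomArray:
        key = (chain_id, position, ins_code)
        if key not in self._res_slices:
            raise StructureError(
                f"no residue {position}{ins_code} in chain {chain_id}"
            )
        return self.atoms[self._res_slices[key]]

    def residue_name1(self, chain_id: str, position: int,
                      ins_code: str = "") -> str:
        res = self.residue_atoms(chain_id, position, ins_code)
        return THREE_TO_ONE[str(res.res_name[0])]

    def sequence(self, chain_id: str | None = None) -> str:
        """One-letter sequence of a chain (or of the only chain)."""
        if chain_id is None:
            chains = self.chains
            if len(chains) != 1:
                raise StructureError(
                    f"chain_id required for multi-chain structure {chains}"
                )
            chain_id = chains[0]
        return "".join(
            THREE_TO_ONE[str(self.atoms.res_name[self._res_slices[k].start])]
            for k in self.residue_keys(chain_id)
        )

    def ca_coord(self, chain_id: str, position: int,
                 ins_code: str = "") -> np.ndarray:
        res = self.residue_atoms(chain_id, position, ins_code)
        return np.asarray(res.coord[res.atom_name == "CA"][0], dtype=float)

    def iter_atoms(self) -> list[Atom]:
        """Materialize the structure as a list of :class:`Atom` records."""
        a = self.atoms
        return [
            Atom(
                name=str(a.atom_name[i]),
                element=str(a.element[i]),
                coord=tuple(float(x) for x in a.coord[i]),
                residue_index=int(a.res_id[i]),
                residue_name=str(a.res_name[i]),
                chain_id=str(a.chain_id[i]),
                ins_code=str(a.ins_code[i]),
            )
            for i in range(a.array_length())
        ]

    def transformed(self, rotation: np.ndarray,
                    translation: np.ndarray) -> "ProteinStructure":
        """Return a rigidly transformed copy (x -> R x + t)."""
        atoms = self.atoms.copy()
        atoms._coord = np.asarray(atoms.coord, dtype=np.float64) \
            @ np.asarray(rotation, dtype=float).T \
            + np.asarray(translation, dtype=float)
        return ProteinStructure(atoms, validate=False)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ProteinStructure):
            return NotImplemented
        a, b = self.atoms, other.atoms
        return (
            a.array_length() == b.array_length()
            and np.array_equal(a.atom_name, b.atom_name)
            and np.array_equal(a.res_id, b.res_id)
            and np.array_equal(a.res_name, b.res_name)
            and np.array_equal(a.chain_id, b.chain_id)
            and np.allclose(a.coord, b.coord)
        )


# -- PDB I/O -----------------------------------------------------------------


def _clean_atom_array(atoms: struc.AtomArray) -> struc.AtomArray:
    """Keep heavy atoms of standard amino acids; drop waters/HETATM/H."""
    mask = (
        ~atoms.hetero
        & ~np.isin(atoms.element, ("H", "D"))
        & np.isin(atoms.res_name, sorted(STANDARD_AA3))
    )
    return atoms[mask]


def read_pdb(path, model_policy: str = "first") -> ProteinStructure:
    """Read a PDB file into a validated heavy-atom :class:`ProteinStructure`.

    Parameters
    ----------
    path
        PDB file path or file-like object.
    model_policy
        ``"first"`` keeps the first MODEL of a multi-model (e.g. NMR) file;
        ``"error"`` rejects multi-model files.
    """
    pdb = PDBFile.read(path)
    n_models = pdb.get_model_count()
    if n_models == 0:
        raise StructureError("no ATOM records found")
    if n_models > 1 and model_policy == "error":
        raise StructureError(f"file contains {n_models} models")
    atoms = pdb.get_structure(model=1, altloc="first",
                              extra_fields=["b_factor", "occupancy"])
    atoms = _clean_atom_array(atoms)
    if atoms.array_length() == 0:
        raise StructureError("no standard protein ATOM records found")
    return ProteinStructure(atoms)


def read_pdb_text(text: str, model_policy: str = "first") -> ProteinStructure:
    """Read a structure from PDB-format text."""
    return read_pdb(io.StringIO(text), model_policy=model_policy)


def write_pdb(structure: ProteinStructure, path=None) -> str:
    """Write ATOM records; returns the PDB text (and writes to *path* if given)."""
    pdb = PDBFile()
    pdb.set_structure(structure.atoms)
    text = "\n".join(pdb.lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


# -- chain selection and candidate enumeration -------------------------------


def select_chain(structure: ProteinStructure, chain_id: str) -> ProteinStructure:
    """Restrict a structure to one chain, preserving residue numbering."""
    if chain_id not in structure.chains:
        raise StructureError(
            f"chain {chain_id!r} not present; available chains: "
            f"{structure.chains}"
        )
    atoms = structure.atoms[structure.atoms.chain_id == chain_id]
    return ProteinStructure(atoms.copy(), validate=False)


def enumerate_candidate_mutations(
    structure: ProteinStructure,
    chain_id: str,
    exclude_positions: set[int] | None = None,
) -> list[Mutation]:
    """Saturation scan: all 19 substitutions at every non-excluded residue,
    ordered by position then mutant residue alphabetically."""
    if chain_id not in structure.chains:
        raise StructureError(
            f"chain {chain_id!r} not present; available chains: "
            f"{structure.chains}"
        )
    exclude = exclude_positions or set()
    out: list[Mutation] = []
    for chain, pos, ins in structure.residue_keys(chain_id):
        if pos in exclude:
            continue
        wt = structure.residue_name1(chain, pos, ins)
        for mut in sorted(ONE_TO_THREE):
            if mut != wt:
                out.append(Mutation(chain, wt, pos, mut, ins))
    return out


# -- mutant building ---------------------------------------------------------


def _template_heavy(res_name3: str) -> struc.AtomArray:
    """Idealized heavy-atom residue template (no OXT) from the chemical
    component dictionary bundled with biotite."""
    tmpl = struc_info.residue(res_name3)
    mask = ~np.isin(tmpl.element, ("H", "D")) & (tmpl.atom_name != "OXT")
    return tmpl[mask]


def build_mutant(structure: ProteinStructure, mutation: Mutation) -> ProteinStructure:
    """Build a naive mutant model: the side chain of the mutated residue is
    replaced by an idealized template rigid-aligned on the N-CA-C frame.

    Backbone atoms of the mutated residue, and every other residue, are left
    untouched; no repacking or minimization is performed. The resulting model
    is deterministic, which keeps the interaction-change features testable.
    """
    res = structure.residue_atoms(mutation.chain_id, mutation.position,
                                  mutation.ins_code)
    found = THREE_TO_ONE[str(res.res_name[0])]
    if found != mutation.wt_aa:
        raise StructureError(
            f"expected {mutation.wt_aa} at {mutation.position}, found {found}"
        )
    tmpl = _template_heavy(ONE_TO_THREE[mutation.mut_aa])

    def backbone_subset(arr: struc.AtomArray) -> struc.AtomArray:
        idx = [int(np.flatnonzero(arr.atom_name == n)[0]) for n in ("N", "CA", "C")]
        return arr[idx]

    _, transform = struc.superimpose(backbone_subset(res), backbone_subset(tmpl))
    placed = transform.apply(tmpl)

    new_res = res[np.isin(res.atom_name, ("N", "CA", "C", "O"))].copy()
    new_res.res_name = np.full(new_res.array_length(),
                               ONE_TO_THREE[mutation.mut_aa])
    side = placed[~np.isin(placed.atom_name, ("N", "CA", "C", "O"))].copy()
    for cat in ("chain_id", "res_id", "res_name", "ins_code", "hetero"):
        if cat in new_res.get_annotation_categories():
            side.set_annotation(
                cat, np.full(side.array_length(), new_res.get_annotation(cat)[0])
            )
    for cat in new_res.get_annotation_categories():
        if cat not in side.get_annotation_categories():
            fill = np.zeros if new_res.get_annotation(cat).dtype.kind == "f" \
                else (lambda n: np.full(n, "", dtype="U1"))
            side.set_annotation(cat, fill(side.array_length()))

    sl = structure._res_slices[
        (mutation.chain_id, mutation.position, mutation.ins_code)
    ]
    before = structure.atoms[: sl.start]
    after = structure.atoms[sl.stop:]
    atoms = before + new_res + side + after
    return ProteinStructure(atoms, validate=False)


# -- toy-structure generation ------------------------------------------------

_GEOMETRIES = {
    # rise per residue (Å), turn per residue (deg), helix radius (Å)
    "helix": (1.5, 100.0, 2.3),
    "strand": (3.3, 180.0, 0.94),
}


def _ca_trace(n: int, geometry: str, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Return (ca_positions, outward_normals) for an ideal backbone curve."""
    if geometry in _GEOMETRIES:
        rise, turn_deg, radius = _GEOMETRIES[geometry]
        phi = np.deg2rad(turn_deg) * np.arange(n)
        ca = np.column_stack(
            [radius * np.cos(phi), radius * np.sin(phi), rise * np.arange(n)]
        )
        normals = np.column_stack([np.cos(phi), np.sin(phi), np.zeros(n)])
        return ca, normals
    if geometry == "coil":
        # persistent random walk with fixed 3.8 Å virtual bonds
        ca = np.zeros((n, 3))
        direction = np.array([1.0, 0.0, 0.0])
        for i in range(1, n):
            step = 0.75 * direction + 0.65 * rng.normal(size=3)
            direction = step / np.linalg.norm(step)
            ca[i] = ca[i - 1] + 3.8 * direction
        normals = np.zeros((n, 3))
        for i in range(n):
            t = ca[min(i + 1, n - 1)] - ca[max(i - 1, 0)]
            t /= np.linalg.norm(t)
            ref = np.array([0.0, 0.0, 1.0])
            if abs(t @ ref) > 0.9:
                ref = np.array([0.0, 1.0, 0.0])
            nrm = np.cross(t, ref)
            normals[i] = nrm / np.linalg.norm(nrm)
        return ca, normals
    raise StructureError(f"unknown geometry {geometry!r}")


def make_toy_pdb(
    n_residues: int,
    geometry: str = "helix",
    sequence: str = "random",
    seed: int = 0,
) -> tuple[ProteinStructure, str]:
    """Generate a deterministic toy structure with ideal-template residues.

    Each residue's idealized heavy-atom template is rigid-placed so that its
    N-CA-C frame sits on an ideal backbone curve (helix: 1.5 Å rise and 100°
    turn per residue about the axis). Returns the structure and its PDB text;
    ``read_pdb`` round-trips the text.
    """
    if n_residues < 2:
        raise StructureError("need at least 2 residues")
    rng = np.random.default_rng(seed)
    if sequence == "random":
        sequence = "".join(rng.choice(sorted(ONE_TO_THREE), size=n_residues))
    if len(sequence) != n_residues:
        raise StructureError(
            f"sequence length {len(sequence)} != n_residues {n_residues}"
        )
    ca, normals = _ca_trace(n_residues, geometry, rng)

    # local N/C targets: CA->N and CA->C in the tangent/inward plane, 111° apart
    alpha = np.deg2rad(34.5)
    pieces = []
    for i, aa in enumerate(sequence):
        t = ca[min(i + 1, n_residues - 1)] - ca[max(i - 1, 0)]
        t /= np.linalg.norm(t)
        inward = -normals[i] + (normals[i] @ t) * t
        inward /= np.linalg.norm(inward)
        n_pos = ca[i] + 1.46 * (-np.cos(alpha) * t + np.sin(alpha) * inward)
        c_pos = ca[i] + 1.52 * (np.cos(alpha) * t + np.sin(alpha) * inward)

        tmpl = _template_heavy(ONE_TO_THREE[aa])
        target = tmpl[[int(np.flatnonzero(tmpl.atom_name == n)[0])
                       for n in ("N", "CA", "C")]].copy()
        target.coord = np.array([n_pos, ca[i], c_pos])
        _, transform = struc.superimpose(target, tmpl[
            [int(np.flatnonzero(tmpl.atom_name == n)[0]) for n in ("N", "CA", "C")]
        ])
        placed = transform.apply(tmpl)
        placed.chain_id = np.full(placed.array_length(), "A")
        placed.res_id = np.full(placed.array_length(), i + 1)
        placed.hetero = np.zeros(placed.array_length(), dtype=bool)
        pieces.append(placed)

    atoms = pieces[0]
    for p in pieces[1:]:
        atoms = atoms + p
    structure = ProteinStructure(atoms)
    return structure, write_pdb(structure)
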