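"""Molecular data model and chemical file I/O.

The central container is :class:`MolecularStructure`, a light-weight
atom/bond record used for both carriers (graphene / graphene-oxide sheets)
and ligands.  Structures are read and written in the Tripos Mol2 dialect
(SYBYL atom types, charge column always present); binding energies are
carried in ``#``-comment lines so annotated files stay readable by any
standard Mol2 viewer.  Ligands may additionally be read from SDF or SMILES
via RDKit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "Atom",
    "Bond",
    "MolecularStructure",
    "ComplexPose",
    "Mol2ParseError",
    "read_mol2",
    "write_mol2",
    "read_sdf",
    "read_smiles",
    "write_xyz",
    "total_formal_charge",
    "longest_intramolecular_distance",
    "to_rdkit",
    "from_rdkit",
]

AROMATIC = "ar"  # bond-order token for aromatic bonds


@dataclass
class Atom:
    element: str
    atom_type: str  # SYBYL label, e.g. C.ar, C.3, O.3, H
    position: np.ndarray  # (3,) in Å
    partial_charge: float = 0.0
    formal_charge: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("atom position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("atom position must be finite")


@dataclass(frozen=True)
class Bond:
    i: int
    j: int
    order: object = 1  # 1, 2, 3 or "ar"

    def key(self) -> tuple[int, int]:
        return (self.i, self.j) if self.i < self.j else (self.j, self.i)


class MolecularStructure:
    """Atoms, bonds and annotations for one molecule.

    Invariants (checked by :meth:`validate`): bond indices reference
    existing atoms, no self-bonds, no duplicate bonds, finite coordinates.
    """

    def __init__(
        self,
        atoms: Iterable[Atom] = (),
        bonds: Iterable[Bond] = (),
        name: str = "MOL",
        annotations: Mapping[str, object] | None = None,
    ) -> None:
        self.atoms: list[Atom] = list(atoms)
        self.bonds: list[Bond] = list(bonds)
        self.name = name
        self.annotations: dict[str, object] = dict(annotations or {})
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        n = len(self.atoms)
        seen: set[tuple[int, int]] = set()
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n):
                raise ValueError(f"bond ({b.i},{b.j}) references missing atom")
            if b.i == b.j:
                raise ValueError(f"self-bond on atom {b.i}")
            if b.key() in seen:
                raise ValueError(f"duplicate bond {b.key()}")
            seen.add(b.key())
        for idx, a in enumerate(self.atoms):
            if not np.all(np.isfinite(a.position)):
                raise ValueError(f"non-finite coordinates on atom {idx}")

    # -- convenience ------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.position for a in self.atoms])

    def set_coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (self.n_atoms, 3):
            raise ValueError("coordinate array shape mismatch")
        for a, p in zip(self.atoms, xyz):
            a.position = p.copy()

    def neighbours(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in self.atoms]
        for b in self.bonds:
            adj[b.i].append(b.j)
            adj[b.j].append(b.i)
        return adj

    def copy(self) -> "MolecularStructure":
        return MolecularStructure(
            atoms=[
                Atom(a.element, a.atom_type, a.position.copy(), a.partial_charge, a.formal_charge, a.name)
                for a in self.atoms
            ],
            bonds=list(self.bonds),
            name=self.name,
            annotations=dict(self.annotations),
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<MolecularStructure {self.name!r}: {self.n_atoms} atoms, {len(self.bonds)} bonds>"


@dataclass
class ComplexPose:
    """A carrier held rigid plus a ligand in one posed conformation."""

    carrier: MolecularStructure
    ligand: MolecularStructure
    genome: object | None = None  # PoseGenome that produced the ligand pose


# ---------------------------------------------------------------------------
# simple queries


def total_formal_charge(structure: MolecularStructure) -> int:
    """Sum of per-atom formal charges (e).  Spin multiplicity is reported
    as 1 throughout the package (ground-state models)."""
    return int(sum(a.formal_charge for a in structure.atoms))


def longest_intramolecular_distance(structure: MolecularStructure) -> float:
    """Maximum pairwise Euclidean distance (Å); 0 for a single atom."""
    if structure.n_atoms == 0:
        raise ValueError("empty structure has no intramolecular distance")
    if structure.n_atoms == 1:
        return 0.0
    xyz = structure.coords
    # pairwise max via broadcasting; fine at ligand/carrier sizes
    d2 = np.sum((xyz[:, None, :] - xyz[None, :, :]) ** 2, axis=-1)
    return float(math.sqrt(d2.max()))


# ---------------------------------------------------------------------------
# Tripos Mol2 I/O


class Mol2ParseError(ValueError):
    pass


_ORDER_TO_MOL2 = {1: "1", 2: "2", 3: "3", AROMATIC: "ar"}
_MOL2_TO_ORDER = {"1": 1, "2": 2, "3": 3, "ar": AROMATIC, "am": 1, "du": 1, "un": 1}


def read_mol2(path: str | Path) -> MolecularStructure:
    """Parse a Tripos Mol2 file (MOLECULE/ATOM/BOND records).

    Energy comment lines of the form ``# KEY=value`` are collected into
    ``annotations``; unknown record blocks are preserved verbatim under
    ``annotations['mol2:<BLOCK>']``.
    """
    path = Path(path)
    text = path.read_text()
    lines = text.splitlines()

    annotations: dict[str, object] = {}
    blocks: dict[str, list[tuple[int, str]]] = {}
    current: str | None = None
    for lineno, raw in enumerate(lines, start=1):
        stripped = raw.strip()
        if stripped.startswith("#"):
            body = stripped.lstrip("#").strip()
            if "=" in body:
                key, _, val = body.partition("=")
                try:
                    annotations[key.strip()] = float(val.strip())
                except ValueError:
                    annotations[key.strip()] = val.strip()
            continue
        if stripped.startswith("@<TRIPOS>"):
            current = stripped[len("@<TRIPOS>"):].upper()
            blocks.setdefault(current, [])
            continue
        if current is not None:
            blocks[current].append((lineno, raw))

    if "MOLECULE" not in blocks or "ATOM" not in blocks:
        raise Mol2ParseError(f"{path}: missing @<TRIPOS>MOLECULE or ATOM block")
    if "BOND" not in blocks:
        raise Mol2ParseError(f"{path}: missing @<TRIPOS>BOND block")

    mol_lines = [l for _, l in blocks["MOLECULE"] if l.strip()]
    name = mol_lines[0].strip() if mol_lines else "MOL"

    atoms: list[Atom] = []
    id_map: dict[int, int] = {}
    for lineno, raw in blocks["ATOM"]:
        if not raw.strip():
            continue
        parts = raw.split()
        if len(parts) < 6:
            raise Mol2ParseError(f"{path}:{lineno}: malformed ATOM record: {raw.strip()!r}")
        try:
            atom_id = int(parts[0])
            x, y, z = (float(v) for v in parts[2:5])
        except ValueError as exc:
            raise Mol2ParseError(f"{path}:{lineno}: malformed ATOM record: {raw.strip()!r}") from exc
        atom_type = parts[5]
        charge = float(parts[8]) if len(parts) > 8 else 0.0
        element = atom_type.split(".")[0].capitalize()
        id_map[atom_id] = len(atoms)
        atoms.append(Atom(element, atom_type, np.array([x, y, z]), charge, 0, name=parts[1]))

    bonds: list[Bond] = []
    for lineno, raw in blocks["BOND"]:
        if not raw.strip():
            continue
        parts = raw.split()
        if len(parts) < 4:
            raise Mol2ParseError(f"{path}:{lineno}: malformed BOND record: {raw.strip()!r}")
        try:
            i, j = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise Mol2ParseError(f"{path}:{lineno}: malformed BOND record: {raw.strip()!r}") from exc
        order = _MOL2_TO_ORDER.get(parts[3].lower())
        if order is None:
            raise Mol2ParseError(f"{path}:{lineno}: unknown bond type {parts[3]!r}")
        if i not in id_map or j not in id_map:
            raise Mol2ParseError(f"{path}:{lineno}: bond references unknown atom id")
        bonds.append(Bond(id_map[i], id_map[j], order))

    # formal charges: recover integer charges from a UNITY_ATOM_ATTR block if
    # present (written by write_mol2); otherwise left at 0
    for lineno, raw in blocks.get("UNITY_ATOM_ATTR", []):
        parts = raw.split()
        if len(parts) == 3 and parts[1] == "charge":
            try:
                atoms[id_map[int(parts[0])]].formal_charge = int(parts[2])
            except (ValueError, KeyError):
                pass

    for blk, blines in blocks.items():
        if blk not in ("MOLECULE", "ATOM", "BOND", "UNITY_ATOM_ATTR"):
            annotations[f"mol2:{blk}"] = "\n".join(l for _, l in blines)

    return MolecularStructure(atoms, bonds, name=name, annotations=annotations)


def write_mol2(
    structure: MolecularStructure,
    path: str | Path,
    energies: Mapping[str, float] | None = None,
) -> None:
    """Write Tripos Mol2.  ``energies`` (e.g. an ``EnergyReport.as_dict()``)
    are emitted as ``# KEY=value`` comment lines before the MOLECULE block."""
    path = Path(path)
    out: list[str] = []
    for key, val in (energies or {}).items():
        out.append(f"# {key}={val:.6f}" if isinstance(val, float) else f"# {key}={val}")
    out.append("@<TRIPOS>MOLECULE")
    out.append(structure.name)
    out.append(f"{structure.n_atoms:d} {len(structure.bonds):d} 0 0 0")
    out.append("SMALL")
    out.append("USER_CHARGES")
    out.append("@<TRIPOS>ATOM")
    for idx, a in enumerate(structure.atoms, start=1):
        name = a.name or f"{a.element}{idx}"
        x, y, z = a.position
        out.append(
            f"{idx:>7d} {name:<8s} {x:>12.4f} {y:>12.4f} {z:>12.4f} "
            f"{a.atom_type:<8s} 1 MOL {a.partial_charge:>10.6f}"
        )
    out.append("@<TRIPOS>BOND")
    for idx, b in enumerate(structure.bonds, start=1):
        out.append(f"{idx:>6d} {b.i + 1:>6d} {b.j + 1:>6d} {_ORDER_TO_MOL2[b.order]:>4s}")
    attrs = [(i + 1, a.formal_charge) for i, a in enumerate(structure.atoms) if a.formal_charge]
    if attrs:
        out.append("@<TRIPOS>UNITY_ATOM_ATTR")
        for atom_id, q in attrs:
            out.append(f"{atom_id} charge {q}")
    path.write_text("\n".join(out) + "\n")


def write_xyz(structure: MolecularStructure, path: str | Path, comment: str = "") -> None:
    """Plain XYZ (Å), used when handing geometries to external engines."""
    path = Path(path)
    lines = [str(structure.n_atoms), comment]
    for a in structure.atoms:
        x, y, z = a.position
        lines.append(f"{a.element:<2s} {x:>14.8f} {y:>14.8f} {z:>14.8f}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# RDKit bridges (SDF / SMILES input, fingerprints, charges, logP)

_BOND_TO_RDKIT = None


def _rdkit_bond_types():
    global _BOND_TO_RDKIT
    if _BOND_TO_RDKIT is None:
        from rdkit import Chem

        _BOND_TO_RDKIT = {
            1: Chem.BondType.SINGLE,
            2: Chem.BondType.DOUBLE,
            3: Chem.BondType.TRIPLE,
            AROMATIC: Chem.BondType.AROMATIC,
        }
    return _BOND_TO_RDKIT


def to_rdkit(structure: MolecularStructure, sanitize: str = "partial"):
    """Convert to an RDKit mol.

    ``sanitize='partial'`` skips kekulization and aromaticity re-perception,
    which large sheet fragments (and GO models with sp3 islands in the ring
    network) may not survive; ring info is still computed so Morgan
    fingerprints and Gasteiger charges work.
    """
    from rdkit import Chem

    em = Chem.RWMol()
    for a in structure.atoms:
        ra = Chem.Atom(a.element)
        ra.SetFormalCharge(int(a.formal_charge))
        ra.SetNoImplicit(True)
        em.AddAtom(ra)
    bt = _rdkit_bond_types()
    for b in structure.bonds:
        em.AddBond(b.i, b.j, bt[b.order])
        if b.order == AROMATIC:
            em.GetAtomWithIdx(b.i).SetIsAromatic(True)
            em.GetAtomWithIdx(b.j).SetIsAromatic(True)
            em.GetBondBetweenAtoms(b.i, b.j).SetIsAromatic(True)
    mol = em.GetMol()
    if sanitize == "full":
        Chem.SanitizeMol(mol)
    else:
        mol.UpdatePropertyCache(strict=False)
        Chem.SanitizeMol(
            mol,
            Chem.SanitizeFlags.SANITIZE_SYMMRINGS
            | Chem.SanitizeFlags.SANITIZE_SETHYBRIDIZATION
            | Chem.SanitizeFlags.SANITIZE_SETCONJUGATION,
        )
    conf = Chem.Conformer(structure.n_atoms)
    for i, a in enumerate(structure.atoms):
        conf.SetAtomPosition(i, tuple(float(v) for v in a.position))
    mol.AddConformer(conf)
    return mol


def from_rdkit(mol, name: str = "MOL") -> MolecularStructure:
    """Convert an RDKit mol (with a 3D conformer) to a MolecularStructure."""
    from rdkit import Chem

    if mol.GetNumConformers() == 0:
        raise ValueError("RDKit mol has no 3D conformer")
    conf = mol.GetConformer()
    atoms: list[Atom] = []
    for at in mol.GetAtoms():
        p = conf.GetAtomPosition(at.GetIdx())
        atoms.append(
            Atom(
                at.GetSymbol(),
                at.GetSymbol(),  # typed later by the force field
                np.array([p.x, p.y, p.z]),
                0.0,
                at.GetFormalCharge(),
            )
        )
    bonds: list[Bond] = []
    for b in mol.GetBonds():
        if b.GetBondType() == Chem.BondType.AROMATIC or b.GetIsAromatic():
            order: object = AROMATIC
        elif b.GetBondType() == Chem.BondType.DOUBLE:
            order = 2
        elif b.GetBondType() == Chem.BondType.TRIPLE:
            order = 3
        else:
            order = 1
        bonds.append(Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
    return MolecularStructure(atoms, bonds, name=name)


def read_sdf(path: str | Path) -> list[MolecularStructure]:
    from rdkit import Chem

    supplier = Chem.SDMolSupplier(str(path), removeHs=False)
    out = []
    for idx, mol in enumerate(supplier):
        if mol is None:
            continue
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol{idx}"
        out.append(from_rdkit(mol, name=name or f"mol{idx}"))
    return out


def read_smiles(smiles: str, name: str = "MOL", seed: int = 7) -> MolecularStructure:
    """Build a 3D structure from SMILES (hydrogens added, ETKDG embedding)."""
    from rdkit import Chem
    from rdkit.Chem import AllChem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    if AllChem.EmbedMolecule(mol, params) != 0:
        raise ValueError(f"3D embedding failed for SMILES {smiles!r}")
    AllChem.MMFFOptimizeMolecule(mol, maxIters=200)
    return from_rdkit(mol, name=name)
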