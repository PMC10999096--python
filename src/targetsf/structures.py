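"""Molecular structures, pose/receptor file IO, and pocket clipping.

Containers are deliberately toolkit-neutral: a :class:`MolecularStructure`
is a flat table of atoms (element, coordinates in Å, formal charge,
aromaticity, attached-hydrogen count) plus a bond list, with optional
per-atom residue annotations for receptors. Converters to and from RDKit
molecules are provided for ligands; receptors are parsed directly from
PDB text so that residue bookkeeping survives regardless of chemistry
perception.

Docking itself is out of scope: poses are read from SDF/MOL2 files that
an external engine produced, and the best-pose docking score travels
along as an opaque number.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger("targetsf.structures")

__all__ = [
    "MolecularStructure",
    "ProteinLigandComplex",
    "structure_from_rdkit",
    "structure_to_rdkit",
    "read_ligand_poses",
    "read_receptor",
    "clip_pocket",
    "write_sdf",
    "write_pdb",
]

# Covalent radii (Å) for proximity bonding of receptor atoms.
_COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05,
    "P": 1.07, "F": 0.57, "CL": 1.02, "BR": 1.20, "I": 1.39,
    "NA": 1.66, "MG": 1.41, "ZN": 1.22, "FE": 1.32, "K": 2.03, "CA": 1.76,
}

_WATER_RESNAMES = {"HOH", "WAT", "H2O", "DOD"}


@dataclass
class MolecularStructure:
    """Atoms, bonds and (for receptors) residue annotations.

    Coordinates are in Å. Atom indices are 0-based internally; file
    serializations use each format's 1-based convention.
    """

    elements: list[str]
    coords: np.ndarray  # (n_atoms, 3) float
    bonds: list[tuple[int, int, int]] = field(default_factory=list)
    formal_charges: list[int] | None = None
    aromatic: list[bool] | None = None
    n_hydrogens: list[int] | None = None
    res_names: list[str] | None = None
    res_numbers: list[int] | None = None
    chains: list[str] | None = None
    atom_names: list[str] | None = None
    name: str = ""
    properties: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n = len(self.elements)
        if self.coords.shape[0] != n:
            raise ValueError("coords/elements length mismatch")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if self.formal_charges is None:
            self.formal_charges = [0] * n
        if self.aromatic is None:
            self.aromatic = [False] * n
        if self.n_hydrogens is None:
            self.n_hydrogens = [0] * n
        seen = set()
        for i, j, _order in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ValueError(f"invalid bond ({i}, {j}) for {n} atoms")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicated bond {key}")
            seen.add(key)

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def heavy_indices(self) -> np.ndarray:
        return np.array(
            [i for i, el in enumerate(self.elements) if el.upper() != "H"],
            dtype=int,
        )

    def neighbors(self) -> list[list[tuple[int, int]]]:
        """Adjacency list of (neighbor index, bond order) pairs."""
        adj: list[list[tuple[int, int]]] = [[] for _ in range(self.n_atoms)]
        for i, j, order in self.bonds:
            adj[i].append((j, order))
            adj[j].append((i, order))
        return adj

    def ring_membership(self) -> list[bool]:
        """Per-atom flag: atom lies on at least one cycle."""
        # iterative leaf pruning: acyclic atoms are peeled off until only
        # cycle atoms (degree >= 2 in the residual graph) remain
        deg = [0] * self.n_atoms
        adj = [set() for _ in range(self.n_atoms)]
        for i, j, _ in self.bonds:
            adj[i].add(j)
            adj[j].add(i)
            deg[i] += 1
            deg[j] += 1
        stack = [i for i in range(self.n_atoms) if deg[i] <= 1]
        alive = [True] * self.n_atoms
        while stack:
            i = stack.pop()
            if not alive[i] or deg[i] > 1:
                continue
            alive[i] = False
            for j in adj[i]:
                if alive[j]:
                    deg[j] -= 1
                    if deg[j] <= 1:
                        stack.append(j)
        return [alive[i] and deg[i] >= 2 for i in range(self.n_atoms)]

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "MolecularStructure":
        """Copy with coordinates rigidly rotated then translated."""
        xyz = self.coords
        if rotation is not None:
            xyz = xyz @ np.asarray(rotation, float).T
        if translation is not None:
            xyz = xyz + np.asarray(translation, float)
        out = MolecularStructure(
            elements=list(self.elements),
            coords=xyz,
            bonds=list(self.bonds),
            formal_charges=list(self.formal_charges),
            aromatic=list(self.aromatic),
            n_hydrogens=list(self.n_hydrogens),
            res_names=None if self.res_names is None else list(self.res_names),
            res_numbers=None if self.res_numbers is None else list(self.res_numbers),
            chains=None if self.chains is None else list(self.chains),
            atom_names=None if self.atom_names is None else list(self.atom_names),
            name=self.name,
            properties=dict(self.properties),
        )
        return out


@dataclass
class ProteinLigandComplex:
    """One receptor plus one docked ligand pose."""

    receptor: MolecularStructure
    ligand: MolecularStructure
    pose_score: float | None = None

    def __post_init__(self):
        if self.receptor.n_atoms == 0:
            raise ValueError("empty receptor")
        if self.ligand.n_atoms == 0:
            raise ValueError("empty ligand")

    def transformed(self, rotation=None, translation=None) -> "ProteinLigandComplex":
        """Rigidly move the whole complex (receptor and ligand together)."""
        return ProteinLigandComplex(
            receptor=self.receptor.transformed(rotation, translation),
            ligand=self.ligand.transformed(rotation, translation),
            pose_score=self.pose_score,
        )


# ---------------------------------------------------------------------------
# RDKit conversion


def structure_from_rdkit(mol, name: str = "") -> MolecularStructure:
    """Convert an RDKit Mol (with a conformer if 3D use is intended)."""
    from rdkit import Chem

    mol = Chem.Mol(mol)
    try:
        Chem.Kekulize(mol, clearAromaticFlags=False)
    except Exception:  # pragma: no cover - unkekulizable input kept as-is
        pass
    n = mol.GetNumAtoms()
    if mol.GetNumConformers():
        conf = mol.GetConformer()
        coords = np.array([list(conf.GetAtomPosition(i)) for i in range(n)])
    else:
        coords = np.zeros((n, 3))
    elements, charges, aromatic, nhs = [], [], [], []
    for atom in mol.GetAtoms():
        elements.append(atom.GetSymbol())
        charges.append(atom.GetFormalCharge())
        aromatic.append(atom.GetIsAromatic())
        nhs.append(atom.GetTotalNumHs(includeNeighbors=True))
    bonds = []
    for b in mol.GetBonds():
        order = int(round(b.GetBondTypeAsDouble())) or 1
        bonds.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
    props = {k: mol.GetProp(k) for k in mol.GetPropNames()}
    return MolecularStructure(
        elements=elements, coords=coords, bonds=bonds,
        formal_charges=charges, aromatic=aromatic, n_hydrogens=nhs,
        name=name or (mol.GetProp("_Name") if mol.HasProp("_Name") else ""),
        properties=props,
    )


def structure_to_rdkit(structure: MolecularStructure, sanitize: bool = True):
    """Build an RDKit Mol (with one conformer) from a structure."""
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    rw = Chem.RWMol()
    for el, q in zip(structure.elements, structure.formal_charges):
        atom = Chem.Atom(el)
        atom.SetFormalCharge(q)
        rw.AddAtom(atom)
    order_map = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE,
                 3: Chem.BondType.TRIPLE}
    for i, j, order in structure.bonds:
        rw.AddBond(i, j, order_map.get(order, Chem.BondType.SINGLE))
    mol = rw.GetMol()
    conf = Chem.Conformer(mol.GetNumAtoms())
    for i, xyz in enumerate(structure.coords):
        conf.SetAtomPosition(i, Point3D(*map(float, xyz)))
    mol.AddConformer(conf)
    if sanitize:
        Chem.SanitizeMol(mol)
    return mol


# ---------------------------------------------------------------------------
# Pose reading

_SCORE_TAGS = ("pose_score", "minimizedAffinity", "docking_score", "score",
               "SCORE", "Smina score")


def _pose_score_from_props(props: dict) -> float | None:
    for tag in _SCORE_TAGS:
        if tag in props:
            try:
                return float(str(props[tag]).split()[0])
            except (ValueError, IndexError):
                continue
    return None


def read_ligand_poses(path: str | Path) -> list[MolecularStructure]:
    """Read docked ligand poses from an SDF (V2000) or MOL2 file.

    One structure per record; 3D coordinates and record-level property
    tags (including any docking-score tag) are preserved. Malformed
    records are skipped with a log entry; a file yielding zero valid
    records is an error.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".mol2" or "@<TRIPOS>MOLECULE" in text:
        structures = _read_mol2(text)
    else:
        structures = _read_sdf(text)
    if not structures:
        raise ValueError(f"no valid ligand records in {path}")
    for s in structures:
        score = _pose_score_from_props(s.properties)
        if score is not None:
            s.properties["pose_score"] = score
    return structures


def _read_sdf(text: str) -> list[MolecularStructure]:
    from rdkit import Chem

    supplier = Chem.SDMolSupplier()
    supplier.SetData(text, sanitize=True, removeHs=False)
    out = []
    for idx, mol in enumerate(supplier):
        if mol is None:
            logger.warning("skipping malformed SDF record %d", idx)
            continue
        out.append(structure_from_rdkit(mol))
    return out


def _mol2_element(atom_type: str) -> str:
    """Map a Tripos atom type (e.g. 'C.ar', 'N.4', 'Du') to an element."""
    head = atom_type.split(".")[0]
    alpha = "".join(c for c in head if c.isalpha())
    if not alpha:
        return "C"
    if alpha.capitalize() in ("Cl", "Br", "Na", "Mg", "Zn", "Fe", "Ca", "Du"):
        return alpha.capitalize()
    return alpha[0].upper()


def _read_mol2(text: str) -> list[MolecularStructure]:
    structures = []
    blocks = text.split("@<TRIPOS>MOLECULE")[1:]
    for bi, block in enumerate(blocks):
        try:
            lines = block.splitlines()
            name = lines[1].strip() if len(lines) > 1 else ""
            atom_sec = _mol2_section(block, "ATOM")
            bond_sec = _mol2_section(block, "BOND")
            elements, coords, charges = [], [], []
            id_map: dict[int, int] = {}
            for row in atom_sec:
                parts = row.split()
                id_map[int(parts[0])] = len(elements)
                elements.append(_mol2_element(parts[5]))
                coords.append([float(parts[2]), float(parts[3]), float(parts[4])])
                q = float(parts[8]) if len(parts) > 8 else 0.0
                charges.append(int(round(q)) if abs(q - round(q)) < 0.25 else 0)
            bonds = []
            order_map = {"1": 1, "2": 2, "3": 3, "am": 1, "ar": 1, "du": 1,
                         "un": 1, "nc": 1}
            for row in bond_sec:
                parts = row.split()
                bonds.append((id_map[int(parts[1])], id_map[int(parts[2])],
                              order_map.get(parts[3].lower(), 1)))
            aromatic = [False] * len(elements)
            for row in bond_sec:
                parts = row.split()
                if parts[3].lower() == "ar":
                    aromatic[id_map[int(parts[1])]] = True
                    aromatic[id_map[int(parts[2])]] = True
            structures.append(MolecularStructure(
                elements=elements, coords=np.array(coords), bonds=bonds,
                aromatic=aromatic, name=name))
        except Exception as exc:
            logger.warning("skipping malformed MOL2 record %d: %s", bi, exc)
    return structures


def _mol2_section(block: str, section: str) -> list[str]:
    marker = f"@<TRIPOS>{section}"
    if marker not in block:
        return []
    body = block.split(marker, 1)[1]
    rows = []
    for line in body.splitlines()[1:] if body.startswith("\n") is False else body.splitlines():
        if line.startswith("@<TRIPOS>"):
            break
        if line.strip():
            rows.append(line)
    return rows


# ---------------------------------------------------------------------------
# Receptor reading (PDB)


def read_receptor(path_or_text: str | Path, chain: str = "A",
                  keep_waters: bool = False) -> MolecularStructure:
    """Parse ATOM/HETATM records of one chain from PDB-format text.

    Residue annotations (name, number, chain) are kept per atom; waters
    (HOH/WAT) are dropped unless ``keep_waters``. Bonds are assigned by
    covalent-radius proximity (the format carries no connectivity for
    standard residues).
    """
    p = Path(path_or_text) if isinstance(path_or_text, (str, Path)) else None
    if p is not None and p.exists():
        text = p.read_text()
    else:
        text = str(path_or_text)
    available = set()
    elements, coords, names = [], [], []
    res_names, res_numbers, chains = [], [], []
    for line in text.splitlines():
        if not (line.startswith("ATOM") or line.startswith("HETATM")):
            continue
        ch = line[21].strip() or " "
        available.add(ch)
        if ch != chain:
            continue
        resname = line[17:20].strip()
        if not keep_waters and resname in _WATER_RESNAMES:
            continue
        el = line[76:78].strip() if len(line) >= 78 else ""
        if not el:
            atom_name = line[12:16].strip()
            el = "".join(c for c in atom_name if c.isalpha())[:1]
        elements.append(el.capitalize())
        names.append(line[12:16].strip())
        coords.append([float(line[30:38]), float(line[38:46]), float(line[46:54])])
        res_names.append(resname)
        res_numbers.append(int(line[22:26]))
        chains.append(ch)
    if not elements:
        raise ValueError(
            f"chain {chain!r} not found; available chains: {sorted(available)}")
    coords = np.array(coords)
    bonds = _proximity_bonds(elements, coords)
    return MolecularStructure(
        elements=elements, coords=coords, bonds=bonds,
        res_names=res_names, res_numbers=res_numbers, chains=chains,
        atom_names=names)


def _proximity_bonds(elements: Sequence[str], coords: np.ndarray,
                     tolerance: float = 0.45) -> list[tuple[int, int, int]]:
    """Single bonds between atoms closer than the covalent-radius sum + tol."""
    n = len(elements)
    bonds = []
    if n < 2:
        return bonds
    from scipy.spatial.distance import pdist, squareform

    dmat = squareform(pdist(coords))
    radii = [_COVALENT_RADII.get(el.upper(), 0.77) for el in elements]
    for i in range(n):
        for j in range(i + 1, n):
            if dmat[i, j] <= radii[i] + radii[j] + tolerance:
                bonds.append((i, j, 1))
    return bonds


# ---------------------------------------------------------------------------
# Pocket clipping


def clip_pocket(receptor: MolecularStructure,
                reference_ligand: MolecularStructure,
                radius: float) -> MolecularStructure:
    """Keep whole residues with any atom within ``radius`` Å of the ligand.

    Emulates a binding-site definition centered on a co-crystallized
    reference ligand. Raises if no residue survives.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if receptor.res_numbers is None:
        raise ValueError("receptor lacks residue annotations")
    from scipy.spatial.distance import cdist

    dmat = cdist(receptor.coords, reference_ligand.coords)
    near = dmat.min(axis=1) <= radius
    keep_res = {
        (receptor.chains[i] if receptor.chains else "A",
         receptor.res_numbers[i])
        for i in range(receptor.n_atoms) if near[i]
    }
    keep_atoms = [
        i for i in range(receptor.n_atoms)
        if ((receptor.chains[i] if receptor.chains else "A",
             receptor.res_numbers[i]) in keep_res)
    ]
    if not keep_atoms:
        raise ValueError("no residues within radius; pocket would be empty")
    index_map = {old: new for new, old in enumerate(keep_atoms)}
    bonds = [(index_map[i], index_map[j], o) for i, j, o in receptor.bonds
             if i in index_map and j in index_map]
    return MolecularStructure(
        elements=[receptor.elements[i] for i in keep_atoms],
        coords=receptor.coords[keep_atoms],
        bonds=bonds,
        formal_charges=[receptor.formal_charges[i] for i in keep_atoms],
        aromatic=[receptor.aromatic[i] for i in keep_atoms],
        n_hydrogens=[receptor.n_hydrogens[i] for i in keep_atoms],
        res_names=[receptor.res_names[i] for i in keep_atoms],
        res_numbers=[receptor.res_numbers[i] for i in keep_atoms],
        chains=[receptor.chains[i] for i in keep_atoms] if receptor.chains else None,
        atom_names=[receptor.atom_names[i] for i in keep_atoms]
        if receptor.atom_names else None,
        name=receptor.name)


# ---------------------------------------------------------------------------
# Writers (plain-text fixture formats)


def write_sdf(structures: Iterable[MolecularStructure], path: str | Path) -> None:
    """Write structures as an SDF (V2000) file, property tags included."""
    lines: list[str] = []
    for s in structures:
        lines.append(s.name or "mol")
        lines.append("  targetsf")
        lines.append("")
        lines.append(f"{s.n_atoms:3d}{len(s.bonds):3d}  0  0  0  0  0  0  0  0999 V2000")
        for i in range(s.n_atoms):
            x, y, z = s.coords[i]
            lines.append(f"{x:10.4f}{y:10.4f}{z:10.4f} {s.elements[i]:<3s}"
                         f" 0  0  0  0  0  0  0  0  0  0  0  0")
        for i, j, order in s.bonds:
            lines.append(f"{i + 1:3d}{j + 1:3d}{order:3d}  0")
        charged = [(i, q) for i, q in enumerate(s.formal_charges) if q]
        if charged:
            entries = "".join(f" {i + 1:3d} {q:3d}" for i, q in charged)
            lines.append(f"M  CHG{len(charged):3d}{entries}")
        lines.append("M  END")
        for key, value in s.properties.items():
            lines.append(f"> <{key}>")
            lines.append(str(value))
            lines.append("")
        lines.append("$$$$")
    Path(path).write_text("\n".join(lines) + "\n")


def write_pdb(structure: MolecularStructure, path: str | Path) -> None:
    """Write a receptor-style structure as PDB ATOM records."""
    lines = []
    for i in range(structure.n_atoms):
        el = structure.elements[i]
        name = (structure.atom_names[i] if structure.atom_names
                else f"{el}{i + 1}")[:4]
        resname = structure.res_names[i] if structure.res_names else "LIG"
        resnum = structure.res_numbers[i] if structure.res_numbers else 1
        ch = structure.chains[i] if structure.chains else "A"
        x, y, z = structure.coords[i]
        lines.append(
            f"ATOM  {i + 1:5d} {name:<4s}{resname:>4s} {ch}{resnum:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {el.upper():>2s}")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
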