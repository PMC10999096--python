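"""Feature schemes for ligands and docked protein-ligand complexes.

Three encodings are provided, mirroring the common practice for training
target-specific scoring functions:

* ``morgan_fp`` — a ligand-only circular (Morgan/ECFP-style) binary
  fingerprint, default 512 bits at radius 2;
* ``plec_fp`` — protein-ligand extended connectivity fingerprint: for
  every heavy-atom contact across the interface, circular environments
  of the ligand atom (depths 0..1) are paired with environments of the
  protein atom (depths 0..5), hashed and folded into a 4092-bit binary
  vector;
* ``grid_features`` — a count-based interaction vector of length
  2^ecfp_power + 3·2^splif_power + 4 (2052 at the default powers):
  folded circular-environment counts within the bounding box, three
  distance-binned SPLIF contact-pair blocks, three distance-binned
  hydrogen-bond counts and one salt-bridge count.

All identifiers come from a stable 32-bit FNV-1a hash of canonical byte
tuples, never from a process-seeded hash, so vectors are reproducible
across runs and platforms. Every scheme is invariant to atom reordering;
PLEC and GRID are additionally invariant to rigid rototranslation of the
complex because they only consume interatomic distances and graph
topology.

The 2048-bit radius-2 RDKit Morgan fingerprint used for compound
similarity (dissimilar splits, hit clustering) lives here as well, as
``similarity_fingerprint``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._hashing import hash_tuple
from .structures import MolecularStructure, ProteinLigandComplex

logger = logging.getLogger("targetsf.features")

__all__ = [
    "FingerprintConfig",
    "FeatureVector",
    "atom_environment_id",
    "environment_ids",
    "morgan_fp",
    "tanimoto",
    "similarity_fingerprint",
    "detect_contacts",
    "plec_fp",
    "grid_features",
    "concat_features",
    "save_features",
    "load_features",
]

#: canonical order of schemes inside a COMBINED vector
_SCHEME_ORDER = {"MORGAN": 0, "PLEC": 1, "GRID": 2}

DEFAULT_PLEC_CUTOFF = 4.5  # Å, heavy-atom contact cutoff
SPLIF_BINS = ((0.0, 2.0), (2.0, 3.0), (3.0, 4.5))  # Å
SALT_BRIDGE_CUTOFF = 4.0  # Å


@dataclass(frozen=True)
class FingerprintConfig:
    """Named featurization scheme with its size/depth parameters."""

    scheme: str = "MORGAN"
    n_bits: int = 512
    radius: int = 2
    depth_ligand: int = 1
    depth_protein: int = 5
    contact_cutoff: float = DEFAULT_PLEC_CUTOFF
    ecfp_power: int = 9
    splif_power: int = 9
    voxel_width: float = 16.0

    @staticmethod
    def morgan(n_bits: int = 512, radius: int = 2) -> "FingerprintConfig":
        return FingerprintConfig(scheme="MORGAN", n_bits=n_bits, radius=radius)

    @staticmethod
    def plec(size: int = 4092, depth_ligand: int = 1, depth_protein: int = 5,
             cutoff: float = DEFAULT_PLEC_CUTOFF) -> "FingerprintConfig":
        return FingerprintConfig(scheme="PLEC", n_bits=size,
                                 depth_ligand=depth_ligand,
                                 depth_protein=depth_protein,
                                 contact_cutoff=cutoff)

    @staticmethod
    def grid(ecfp_power: int = 9, splif_power: int = 9,
             voxel_width: float = 16.0) -> "FingerprintConfig":
        return FingerprintConfig(scheme="GRID", ecfp_power=ecfp_power,
                                 splif_power=splif_power,
                                 voxel_width=voxel_width)

    @property
    def length(self) -> int:
        if self.scheme == "GRID":
            return 2 ** self.ecfp_power + 3 * 2 ** self.splif_power + 4
        return self.n_bits


@dataclass
class FeatureVector:
    """Fixed-length numeric encoding under a named scheme."""

    scheme: str
    values: np.ndarray
    config: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values)

    def __len__(self) -> int:
        return int(self.values.shape[0])


# ---------------------------------------------------------------------------
# Circular atom environments


def _heavy_graph(structure: MolecularStructure):
    """Heavy-atom adjacency with effective attached-H counts."""
    heavy = [i for i, el in enumerate(structure.elements) if el.upper() != "H"]
    pos = {a: k for k, a in enumerate(heavy)}
    adj: list[list[tuple[int, int]]] = [[] for _ in heavy]
    explicit_h = [0] * structure.n_atoms
    for i, j, order in structure.bonds:
        hi = structure.elements[i].upper() == "H"
        hj = structure.elements[j].upper() == "H"
        if hi and not hj:
            explicit_h[j] += 1
        elif hj and not hi:
            explicit_h[i] += 1
        elif not hi and not hj:
            adj[pos[i]].append((pos[j], order))
            adj[pos[j]].append((pos[i], order))
    n_h = [max(structure.n_hydrogens[a], explicit_h[a]) for a in heavy]
    return heavy, pos, adj, n_h


def environment_ids(structure: MolecularStructure, max_depth: int
                    ) -> list[list[int]]:
    """Identifiers of the circular environment of every heavy atom.

    Returns ``ids[k][d]`` — the depth-``d`` identifier of the ``k``-th
    heavy atom (heavy atoms in structure order). Depth-0 identifiers
    hash the atom-invariant tuple (element, heavy degree, attached-H
    count, formal charge, aromaticity, ring membership); the depth-``d``
    identifier hashes ``(d, own depth-(d-1) id, sorted (bond order,
    neighbor depth-(d-1) id) pairs)``, which makes the whole scheme
    independent of input atom ordering.
    """
    heavy, _pos, adj, n_h = _heavy_graph(structure)
    in_ring = structure.ring_membership()
    layer = [
        hash_tuple((
            "atom",
            structure.elements[a].capitalize(),
            len(adj[k]),
            n_h[k],
            structure.formal_charges[a],
            bool(structure.aromatic[a]),
            bool(in_ring[a]),
        ))
        for k, a in enumerate(heavy)
    ]
    ids = [[v] for v in layer]
    for d in range(1, max_depth + 1):
        nxt = []
        for k in range(len(heavy)):
            pairs = sorted((order, layer[nb]) for nb, order in adj[k])
            nxt.append(hash_tuple((d, layer[k], tuple(pairs))))
        for k, v in enumerate(nxt):
            ids[k].append(v)
        layer = nxt
    return ids


def atom_environment_id(structure: MolecularStructure, atom_index: int,
                        depth: int) -> int:
    """Identifier of one atom's circular environment at ``depth``."""
    if depth < 0:
        raise ValueError("depth must be non-negative")
    heavy = [i for i, el in enumerate(structure.elements)
             if el.upper() != "H"]
    if atom_index not in heavy:
        raise ValueError(f"atom {atom_index} is not a heavy atom")
    ids = environment_ids(structure, depth)
    return ids[heavy.index(atom_index)][depth]


def _deduped_environments(structure: MolecularStructure, radius: int
                          ) -> list[int]:
    """Environment identifiers after duplicate-atom-set removal.

    Two environments covering the same set of atoms describe the same
    substructure; only one identifier is kept per atom set — the one of
    lowest depth, ties broken by the smaller identifier, which keeps the
    result invariant to input atom ordering.
    """
    heavy, _pos, adj, _n_h = _heavy_graph(structure)
    ids = environment_ids(structure, radius)
    # BFS balls give the atom set covered at each depth
    best: dict[frozenset, tuple[int, int]] = {}
    for k in range(len(heavy)):
        ball = {k}
        frontier = {k}
        for d in range(radius + 1):
            key = frozenset(ball)
            cand = (d, ids[k][d])
            if key not in best or cand < best[key]:
                best[key] = cand
            frontier = {nb for a in frontier for nb, _ in adj[a]} - ball
            ball |= frontier
    return [identifier for _d, identifier in best.values()]


def morgan_fp(structure: MolecularStructure, n_bits: int = 512,
              radius: int = 2) -> FeatureVector:
    """Ligand-only circular fingerprint folded into ``n_bits`` bits."""
    if structure.n_atoms == 0 or len(structure.heavy_indices()) == 0:
        raise ValueError("cannot fingerprint an empty molecule")
    values = np.zeros(n_bits, dtype=np.uint8)
    for identifier in _deduped_environments(structure, radius):
        values[identifier % n_bits] = 1
    return FeatureVector("MORGAN", values,
                         {"n_bits": n_bits, "radius": radius})


# ---------------------------------------------------------------------------
# Similarity


def tanimoto(fp_a, fp_b) -> float:
    """Tanimoto coefficient |a∧b| / |a∨b| of two binary vectors."""
    a = np.asarray(fp_a.values if isinstance(fp_a, FeatureVector) else fp_a)
    b = np.asarray(fp_b.values if isinstance(fp_b, FeatureVector) else fp_b)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    a = a.astype(bool)
    b = b.astype(bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def similarity_fingerprint(smiles: str, n_bits: int = 2048, radius: int = 2):
    """RDKit Morgan bit vector used for compound-similarity analyses.

    This is the field-standard 2048-bit radius-2 fingerprint behind
    dissimilar train/test splitting, hit clustering and nearest-training-
    molecule lookups. Returns an RDKit ExplicitBitVect (so bulk Tanimoto
    routines can be used); ``None`` for unparsable SMILES.
    """
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius,
                                                    fpSize=n_bits)
    return gen.GetFingerprint(mol)


# ---------------------------------------------------------------------------
# Interface contacts and PLEC


def detect_contacts(complex_: ProteinLigandComplex,
                    cutoff: float = DEFAULT_PLEC_CUTOFF
                    ) -> list[tuple[int, int, float]]:
    """Heavy-atom cross pairs within ``cutoff`` Å (closed boundary).

    Returns (ligand atom index, protein atom index, distance) triples;
    hydrogens are excluded on both sides.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    from scipy.spatial.distance import cdist

    lig_idx = complex_.ligand.heavy_indices()
    prot_idx = complex_.receptor.heavy_indices()
    if len(lig_idx) == 0 or len(prot_idx) == 0:
        return []
    dmat = cdist(complex_.ligand.coords[lig_idx],
                 complex_.receptor.coords[prot_idx])
    out = []
    for a, b in zip(*np.nonzero(dmat <= cutoff)):
        out.append((int(lig_idx[a]), int(prot_idx[b]), float(dmat[a, b])))
    return out


def plec_fp(complex_: ProteinLigandComplex, depth_ligand: int = 1,
            depth_protein: int = 5, size: int = 4092,
            cutoff: float = DEFAULT_PLEC_CUTOFF,
            pairing: str = "cross") -> FeatureVector:
    """Protein-ligand extended connectivity fingerprint.

    For every interface contact, the ligand atom's environments at
    depths 0..``depth_ligand`` are paired with the protein atom's
    environments at depths 0..``depth_protein``; each pair is hashed and
    folded modulo ``size``. ``pairing='cross'`` takes the full depth
    cross-product; ``'diagonal'`` pairs depth k with depth k (clipped to
    each side's maximum), the leaner convention some implementations use.

    A contact-free complex yields a valid all-zero vector (logged).
    """
    if depth_ligand < 0 or depth_protein < 0:
        raise ValueError("depths must be non-negative")
    values = np.zeros(size, dtype=np.uint8)
    contacts = detect_contacts(complex_, cutoff)
    if not contacts:
        logger.info("no interface contacts within %.2f Å; zero PLEC vector",
                    cutoff)
        return FeatureVector("PLEC", values, _plec_config(
            size, depth_ligand, depth_protein, cutoff, pairing))
    lig_ids = environment_ids(complex_.ligand, depth_ligand)
    prot_ids = environment_ids(complex_.receptor, depth_protein)
    lig_heavy = list(complex_.ligand.heavy_indices())
    prot_heavy = list(complex_.receptor.heavy_indices())
    lig_pos = {a: k for k, a in enumerate(lig_heavy)}
    prot_pos = {a: k for k, a in enumerate(prot_heavy)}
    if pairing == "cross":
        depth_pairs = [(i, j) for i in range(depth_ligand + 1)
                       for j in range(depth_protein + 1)]
    elif pairing == "diagonal":
        depth_pairs = [(min(k, depth_ligand), min(k, depth_protein))
                       for k in range(max(depth_ligand, depth_protein) + 1)]
        depth_pairs = sorted(set(depth_pairs))
    else:
        raise ValueError(f"unknown pairing {pairing!r}")
    for la, pa, _dist in contacts:
        lk, pk = lig_pos[la], prot_pos[pa]
        for i, j in depth_pairs:
            raw = hash_tuple(("plec", lig_ids[lk][i], prot_ids[pk][j]))
            values[raw % size] = 1
    return FeatureVector("PLEC", values, _plec_config(
        size, depth_ligand, depth_protein, cutoff, pairing))


def _plec_config(size, dl, dp, cutoff, pairing):
    return {"size": size, "depth_ligand": dl, "depth_protein": dp,
            "cutoff": cutoff, "pairing": pairing}


# ---------------------------------------------------------------------------
# Hydrogen-bond / salt-bridge typing (rule-based; no partial charges)


def donor_mask(structure: MolecularStructure) -> np.ndarray:
    """Heavy atoms that can donate a hydrogen bond: N or O carrying H."""
    heavy, _pos, _adj, n_h = _heavy_graph(structure)
    mask = np.zeros(structure.n_atoms, dtype=bool)
    for k, a in enumerate(heavy):
        if structure.elements[a].upper() in ("N", "O") and n_h[k] > 0:
            mask[a] = True
    return mask


def acceptor_mask(structure: MolecularStructure) -> np.ndarray:
    """Heavy atoms that can accept a hydrogen bond: any N or O."""
    return np.array([el.upper() in ("N", "O") for el in structure.elements])


# ---------------------------------------------------------------------------
# GRID features


def grid_features(complex_: ProteinLigandComplex, ecfp_power: int = 9,
                  splif_power: int = 9, voxel_width: float = 16.0
                  ) -> FeatureVector:
    """Count-based grid interaction features of a docked complex.

    Layout (2052 values at the default powers of 9):

    * block 0 — ``2^ecfp_power`` folded counts of deduplicated circular
      environments (radius 2) of ligand and pocket heavy atoms lying
      inside the bounding sphere of diameter ``voxel_width`` Å centered
      on the ligand centroid (a sphere, not a box, so the whole vector
      is invariant to rigid rototranslation);
    * blocks 1-3 — for each contact distance bin (0, 2], (2, 3],
      (3, 4.5] Å, ``2^splif_power`` folded counts of SPLIF pairs (the
      depth-1 environments of the two contacting atoms, hashed jointly);
    * 3 hydrogen-bond counts, one per distance bin (rule-based donor and
      acceptor typing, either direction across the interface);
    * 1 salt-bridge count: formally charged N⁺/O⁻ cross pairs within
      4.0 Å.
    """
    from scipy.spatial.distance import cdist

    n_ecfp = 2 ** ecfp_power
    n_splif = 2 ** splif_power
    values = np.zeros(n_ecfp + 3 * n_splif + 4, dtype=float)

    center = complex_.ligand.coords.mean(axis=0)
    half = voxel_width / 2.0

    # block 0: circular-environment counts inside the box
    offset = 0
    for structure in (complex_.ligand, complex_.receptor):
        heavy = structure.heavy_indices()
        if len(heavy) == 0:
            continue
        inside = np.linalg.norm(structure.coords[heavy] - center,
                                axis=1) <= half
        if not inside.any():
            continue
        boxed = _deduped_environments_subset(structure,
                                             set(heavy[inside].tolist()))
        for identifier in boxed:
            values[identifier % n_ecfp] += 1

    # SPLIF blocks + hydrogen bonds per distance bin
    contacts = detect_contacts(complex_, SPLIF_BINS[-1][1])
    lig_ids = environment_ids(complex_.ligand, 1)
    prot_ids = environment_ids(complex_.receptor, 1)
    lig_heavy = list(complex_.ligand.heavy_indices())
    prot_heavy = list(complex_.receptor.heavy_indices())
    lig_pos = {a: k for k, a in enumerate(lig_heavy)}
    prot_pos = {a: k for k, a in enumerate(prot_heavy)}
    don_l, acc_l = donor_mask(complex_.ligand), acceptor_mask(complex_.ligand)
    don_p, acc_p = donor_mask(complex_.receptor), acceptor_mask(complex_.receptor)
    for la, pa, dist in contacts:
        for b, (lo, hi) in enumerate(SPLIF_BINS):
            if lo < dist <= hi:
                raw = hash_tuple(("splif",
                                  lig_ids[lig_pos[la]][1],
                                  prot_ids[prot_pos[pa]][1]))
                values[n_ecfp + b * n_splif + raw % n_splif] += 1
                if (don_l[la] and acc_p[pa]) or (acc_l[la] and don_p[pa]):
                    values[n_ecfp + 3 * n_splif + b] += 1
                break

    # salt bridges: charged N+/O- cross pairs within 4.0 Å
    def _charged(structure, element, sign):
        return [i for i in range(structure.n_atoms)
                if structure.elements[i].upper() == element
                and sign * structure.formal_charges[i] > 0]

    n_salt = 0
    for lig_sel, prot_sel in (
            (_charged(complex_.ligand, "N", +1), _charged(complex_.receptor, "O", -1)),
            (_charged(complex_.ligand, "O", -1), _charged(complex_.receptor, "N", +1))):
        if lig_sel and prot_sel:
            dmat = cdist(complex_.ligand.coords[lig_sel],
                         complex_.receptor.coords[prot_sel])
            n_salt += int((dmat <= SALT_BRIDGE_CUTOFF).sum())
    values[-1] = n_salt

    return FeatureVector("GRID", values, {
        "ecfp_power": ecfp_power, "splif_power": splif_power,
        "voxel_width": voxel_width})


def _deduped_environments_subset(structure: MolecularStructure,
                                 allowed_atoms: set[int],
                                 radius: int = 2) -> list[int]:
    """Deduplicated environments centered on a subset of heavy atoms."""
    heavy, _pos, adj, _n_h = _heavy_graph(structure)
    ids = environment_ids(structure, radius)
    best: dict[frozenset, tuple[int, int]] = {}
    for k, a in enumerate(heavy):
        if a not in allowed_atoms:
            continue
        ball = {k}
        frontier = {k}
        for d in range(radius + 1):
            key = frozenset(ball)
            cand = (d, ids[k][d])
            if key not in best or cand < best[key]:
                best[key] = cand
            frontier = {nb for x in frontier for nb, _ in adj[x]} - ball
            ball |= frontier
    return [identifier for _d, identifier in best.values()]


# ---------------------------------------------------------------------------
# Combination and persistence


def concat_features(fv_a: FeatureVector, fv_b: FeatureVector) -> FeatureVector:
    """Concatenate two feature vectors of distinct schemes.

    The result is always laid out in canonical scheme order (MORGAN,
    PLEC, GRID) regardless of argument order, so combined matrices line
    up column-wise no matter how callers assembled them.
    """
    if fv_a.scheme == fv_b.scheme:
        raise ValueError(f"cannot combine two {fv_a.scheme} vectors")
    parts = sorted([fv_a, fv_b],
                   key=lambda fv: _SCHEME_ORDER.get(fv.scheme, 99))
    values = np.concatenate([np.asarray(p.values, dtype=float)
                             for p in parts])
    return FeatureVector("COMBINED", values, {
        "parts": [{"scheme": p.scheme, "length": len(p), **p.config}
                  for p in parts]})


def save_features(path: str | Path, matrix: np.ndarray, scheme: str,
                  config: dict, compound_ids: list[str]) -> None:
    """Persist a feature matrix (.npz) with a JSON sidecar."""
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"), X=np.asarray(matrix))
    sidecar = {"scheme": scheme, "config": config,
               "compound_ids": list(compound_ids),
               "n_columns": int(np.asarray(matrix).shape[1])}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_features(path: str | Path):
    """Load a feature matrix and its sidecar; returns (X, metadata)."""
    path = Path(path)
    X = np.load(path.with_suffix(".npz"))["X"]
    meta = json.loads(path.with_suffix(".json").read_text())
    if X.shape[1] != meta["n_columns"]:
        raise ValueError("sidecar column count disagrees with matrix")
    return X, meta
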