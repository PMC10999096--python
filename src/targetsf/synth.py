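"""Seed-controlled synthetic fixtures for every pipeline stage.

The generator emulates the shape of the real inputs — a bioactivity
export with biochemical/cellular/binding annotations, docked
protein-ligand poses, property-matched decoys — at toy scale, with
known per-row ground truth, so curation, featurization, training and
evaluation are all testable without any download.

Toy molecules are valence-respecting acyclic C/N/O(/S) graphs with a
simple sequential 3D embedding (every bond placed at 1.5 Å); toy
"receptors" are shells of labeled pseudo-residues placed outside
contact range of the ligand. A learnable activity signal is planted by
moving a fixed anchor triad of receptor atoms (N, O, O) into contact
distance of the first three ligand atoms, so interface fingerprints of
signal-carrying complexes differ systematically from signal-free ones.

All randomness flows from a single spec seed through a counter-based
splitting scheme (:func:`child_rng`), so each sub-generator is
independently reproducible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._hashing import hash_tuple
from .curation import (CurationLog, DataSplit, curate, filter_certain,
                       load_activity_records, split_by_assay)
from .features import acceptor_mask, donor_mask, morgan_fp, tanimoto
from .structures import MolecularStructure, ProteinLigandComplex

logger = logging.getLogger("targetsf.synth")

__all__ = [
    "FixtureSpec",
    "child_rng",
    "gen_molecule",
    "gen_molecule_with_properties",
    "gen_pocket_complex",
    "gen_activity_table",
    "gen_property_matched_decoys",
    "gen_benchmark",
    "Benchmark",
    "count_donors",
    "count_acceptors",
]

_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2}
BOND_LENGTH = 1.5  # Å
DECOY_SIMILARITY_CEILING = 0.4
ANCHOR_DISTANCE = 3.2  # Å, anchor atoms to their ligand partner atoms
SHELL_CLEARANCE = 5.5  # Å beyond the ligand's outermost atom


def child_rng(seed: int, *keys) -> np.random.Generator:
    """Independent generator derived from a root seed and a key path."""
    return np.random.default_rng(hash_tuple((int(seed),) + tuple(keys)))


@dataclass
class FixtureSpec:
    """Study-composition knobs for the synthetic generators.

    Defaults mirror the composition of the emulated study: a
    biochemical-assay majority with ~60% actives, a smaller cell-assayed
    subset destined for testing, a sliver of binding-only records, a
    decoy-to-active ratio of 50, and planted curation hazards (missing
    SMILES, censored and uncertain relations, over-dispersed
    replicates) in known numbers.
    """

    seed: int = 0
    n_compounds: int = 200
    active_fraction: float = 0.6
    assay_mix: tuple[float, float, float] = (0.65, 0.25, 0.10)
    decoy_ratio: int = 50
    pocket_size: int = 8  # pseudo-residues in the receptor shell
    signal_strength: float = 0.9
    replicate_fraction: float = 0.25
    n_missing_smiles: int = 4
    n_uncertain: int = 3
    n_dispersion_rejects: int = 3
    gt_fraction: float = 0.3  # censored (">") share of inactives
    counts: dict | None = None  # explicit per-partition counts override
    heavy_atom_range: tuple[int, int] = (8, 16)

    def __post_init__(self):
        if abs(sum(self.assay_mix) - 1.0) > 1e-9:
            raise ValueError("assay_mix proportions must sum to 1")
        if self.decoy_ratio < 1:
            raise ValueError("decoy_ratio must be >= 1")
        if not 0.0 <= self.signal_strength <= 1.0:
            raise ValueError("signal_strength must lie in [0, 1]")

    def partition_counts(self) -> dict:
        if self.counts is not None:
            return dict(self.counts)
        n_train = round(self.n_compounds * self.assay_mix[0])
        n_test = round(self.n_compounds * self.assay_mix[1])
        n_bind = self.n_compounds - n_train - n_test
        return {
            "train_active": round(n_train * self.active_fraction),
            "train_inactive": n_train - round(n_train * self.active_fraction),
            "test_active": round(n_test * self.active_fraction),
            "test_inactive": n_test - round(n_test * self.active_fraction),
            "binding_only": n_bind,
        }


# ---------------------------------------------------------------------------
# Toy molecules


def _embed_tree(elements, bonds, parents, rng) -> np.ndarray:
    """Sequential 3D embedding: each atom 1.5 Å from its parent, placed
    in the direction (of several tried) that best avoids clashes.

    Atoms are visited in tree order from the root, so a parent is always
    placed before its children regardless of index order.
    """
    n = len(elements)
    children: list[list[int]] = [[] for _ in range(n)]
    for i, p in enumerate(parents):
        if p is not None:
            children[p].append(i)
    coords = np.zeros((n, 3))
    placed = [0]
    queue = list(children[0])
    while queue:
        i = queue.pop(0)
        p = parents[i]
        best, best_sep = None, -1.0
        for _ in range(24):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            cand = coords[p] + BOND_LENGTH * direction
            others = np.array([coords[k] for k in placed if k != p])
            sep = (np.linalg.norm(others - cand, axis=1).min()
                   if len(others) else np.inf)
            if sep > best_sep:
                best, best_sep = cand, sep
            if sep > 1.8:
                break
        coords[i] = best
        placed.append(i)
        queue.extend(children[i])
    return coords


def _build_structure(elements, bonds, parents, rng, name="") -> MolecularStructure:
    degree = [0] * len(elements)
    for i, j, _ in bonds:
        degree[i] += 1
        degree[j] += 1
    n_h = [max(0, _VALENCE[el] - d) for el, d in zip(elements, degree)]
    coords = _embed_tree(elements, bonds, parents, rng)
    return MolecularStructure(elements=list(elements), coords=coords,
                              bonds=list(bonds), n_hydrogens=n_h, name=name)


def gen_molecule(seed: int, n_heavy_atoms: int) -> MolecularStructure:
    """Random valence-respecting connected molecule with 3D coordinates."""
    if n_heavy_atoms < 1:
        raise ValueError("need at least one heavy atom")
    rng = child_rng(seed, "molecule")
    elements, bonds, parents = _random_tree(rng, n_heavy_atoms)
    return _build_structure(elements, bonds, parents, rng,
                            name=f"syn{seed}")


def _random_tree(rng, n_heavy):
    elements = [str(rng.choice(["C", "C", "C", "N", "O", "S"]))]
    bonds, parents = [], [None]
    free = [_VALENCE[elements[0]]]
    for i in range(1, n_heavy):
        candidates = [k for k in range(i) if free[k] > 0]
        if not candidates:  # pragma: no cover - valences never all exhaust
            candidates = [i - 1]
        p = int(rng.choice(candidates))
        el = str(rng.choice(["C", "C", "C", "N", "O", "S"]))
        elements.append(el)
        parents.append(p)
        bonds.append((p, i, 1))
        free[p] -= 1
        free.append(_VALENCE[el] - 1)
    return elements, bonds, parents


def gen_molecule_with_properties(rng: np.random.Generator, n_heavy: int,
                                 n_acceptors: int, n_donors: int,
                                 name: str = "") -> MolecularStructure:
    """Molecule with exact H-bond donor/acceptor counts.

    Acceptors are N/O atoms; donors are the subset carrying hydrogens.
    Donors are attached as leaves (O-H / N-H2); non-donor acceptors are
    ethers (O spliced into a C-C edge, degree 2, no H). Requires
    ``n_heavy >= n_acceptors + 2``.
    """
    if n_donors > n_acceptors:
        raise ValueError("donors are a subset of acceptors")
    n_carbons = n_heavy - n_acceptors
    if n_carbons < 2:
        raise ValueError("need at least two carbons for the scaffold")
    if n_acceptors - n_donors > n_carbons - 1:
        raise ValueError("not enough C-C edges for the requested ethers")
    # carbon scaffold
    elements = ["C"] * n_carbons
    bonds, parents = [], [None]
    free = [4]
    for i in range(1, n_carbons):
        candidates = [k for k in range(i) if free[k] > 1]
        p = int(rng.choice(candidates)) if candidates else i - 1
        parents.append(p)
        bonds.append((p, i, 1))
        free[p] -= 1
        free.append(3)
    # donor leaves
    for _ in range(n_donors):
        el = str(rng.choice(["O", "N"]))
        candidates = [k for k in range(len(elements))
                      if elements[k] == "C" and free[k] > 0]
        p = int(rng.choice(candidates))
        elements.append(el)
        parents.append(p)
        bonds.append((p, len(elements) - 1, 1))
        free[p] -= 1
        free.append(_VALENCE[el] - 1)
    # ether (non-donor acceptor) insertions: split a C-C edge with O
    for _ in range(n_acceptors - n_donors):
        cc = [bi for bi, (i, j, _) in enumerate(bonds)
              if elements[i] == "C" and elements[j] == "C"]
        bi = int(rng.choice(cc))
        i, j, _ = bonds[bi]
        o = len(elements)
        elements.append("O")
        parents.append(i)
        bonds[bi] = (i, o, 1)
        bonds.append((o, j, 1))
        free.append(0)  # O with two bonds: saturated
        if parents[j] == i:
            parents[j] = o
    return _build_structure(elements, bonds, parents, rng, name=name)


def count_donors(structure: MolecularStructure) -> int:
    return int(donor_mask(structure).sum())


def count_acceptors(structure: MolecularStructure) -> int:
    heavy = structure.heavy_indices()
    return int(acceptor_mask(structure)[heavy].sum())


# ---------------------------------------------------------------------------
# Toy complexes

_RES_NAMES = ("ALA", "SER", "VAL", "LEU", "THR", "GLY", "PHE", "ASP")


def gen_pocket_complex(seed: int, ligand: MolecularStructure,
                       plant_signal: bool,
                       pocket_size: int = 8) -> ProteinLigandComplex:
    """Pseudo-receptor shell around a ligand, optionally with a planted
    anchor triad in contact range.

    Every complex gets ligand-dependent background contacts: roughly a
    third of the shell residues (3 atoms each, annotated with residue
    names/numbers on chain A) sit ~4 Å outside randomly chosen ligand
    atoms, inside the default 4.5 Å contact cutoff, the way any docked
    pose touches its pocket; the remaining residues sit
    ``SHELL_CLEARANCE`` Å beyond the ligand's outermost atom, out of
    contact range. When ``plant_signal``, an additional anchor triad
    (N, O, O) is placed ``ANCHOR_DISTANCE`` Å from the first three
    ligand atoms, giving signal-carrying complexes a reproducible,
    ligand-dependent interface signature on top of the background.
    """
    rng = child_rng(seed, "pocket", plant_signal)
    center = ligand.coords.mean(axis=0)
    extent = float(np.linalg.norm(ligand.coords - center, axis=1).max())
    shell_r = extent + SHELL_CLEARANCE
    n_contact_res = max(2, pocket_size // 3)

    elements, coords = [], []
    res_names, res_numbers, chains, charges = [], [], [], []
    bonds = []
    for r in range(pocket_size):
        if r < n_contact_res:
            lig_atom = int(rng.integers(ligand.n_atoms))
            direction = ligand.coords[lig_atom] - center
            norm = np.linalg.norm(direction)
            if norm < 1e-9:
                direction = rng.normal(size=3)
                norm = np.linalg.norm(direction)
            direction = direction / norm
            base = ligand.coords[lig_atom] + \
                float(rng.uniform(3.6, 4.3)) * direction
        else:
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            base = center + shell_r * direction
        resname = _RES_NAMES[r % len(_RES_NAMES)]
        for a, el in enumerate(("C", "C", str(rng.choice(["N", "O", "C"])))):
            elements.append(el)
            coords.append(base + a * BOND_LENGTH * _perp(direction, rng, a))
            res_names.append(resname)
            res_numbers.append(r + 1)
            chains.append("A")
            charges.append(0)
        first = len(elements) - 3
        bonds.extend([(first, first + 1, 1), (first + 1, first + 2, 1)])

    if plant_signal:
        anchor_elements = ("N", "O", "O")
        n_anchor_atoms = min(3, ligand.n_atoms)
        first = len(elements)
        for a in range(n_anchor_atoms):
            lig_xyz = ligand.coords[a]
            direction = lig_xyz - center
            norm = np.linalg.norm(direction)
            direction = direction / norm if norm > 1e-9 else np.array([1.0, 0, 0])
            elements.append(anchor_elements[a])
            coords.append(lig_xyz + ANCHOR_DISTANCE * direction)
            res_names.append("ANC")
            res_numbers.append(pocket_size + 1)
            chains.append("A")
            charges.append(0)
        for a in range(first, len(elements) - 1):
            bonds.append((a, a + 1, 1))

    receptor = MolecularStructure(
        elements=elements, coords=np.array(coords), bonds=bonds,
        formal_charges=charges, res_names=res_names,
        res_numbers=res_numbers, chains=chains,
        name=f"pocket{seed}")
    return ProteinLigandComplex(receptor=receptor, ligand=ligand,
                                pose_score=float(rng.normal(-7.0, 1.0)))


def _perp(direction, rng, step):
    if step == 0:
        return np.zeros(3)
    v = np.cross(direction, [0.0, 0.0, 1.0])
    if np.linalg.norm(v) < 1e-6:
        v = np.cross(direction, [0.0, 1.0, 0.0])
    return v / np.linalg.norm(v)


# ---------------------------------------------------------------------------
# Activity tables


def _smiles_of(structure: MolecularStructure) -> str:
    from rdkit import Chem

    from .structures import structure_to_rdkit

    return Chem.MolToSmiles(structure_to_rdkit(structure))


def _pic50_to_nM(pic50: float) -> float:
    return 10.0 ** (9.0 - pic50)


def gen_activity_table(spec: FixtureSpec):
    """Reproducible activity table with known per-row ground truth.

    Returns ``(DataFrame, truth)``. ``truth`` carries the intended
    partition and label of every compound, the generated 3D structure
    of every assayed compound, and the planted counts of curation
    hazards (missing SMILES, uncertain relations, over-dispersed
    replicate sets) so tests can compare curation bookkeeping against
    the generator's own.
    """
    rng = child_rng(spec.seed, "table")
    counts = spec.partition_counts()
    rows: list[dict] = []
    truth = {
        "labels": {}, "partitions": {}, "structures": {},
        "n_missing_smiles": spec.n_missing_smiles,
        "n_uncertain": spec.n_uncertain,
        "n_dispersion_rejects": spec.n_dispersion_rejects,
        "counts": counts,
    }
    serial = 0

    def new_compound(partition, active):
        nonlocal serial
        serial += 1
        cid = f"SYN{serial:05d}"
        n_heavy = int(rng.integers(*spec.heavy_atom_range))
        n_acc = int(rng.integers(1, min(4, n_heavy - 2) + 1))
        don_min = max(0, n_acc - (n_heavy - n_acc - 1))
        n_don = int(rng.integers(don_min, n_acc + 1))
        structure = gen_molecule_with_properties(
            child_rng(spec.seed, "mol", cid), n_heavy, n_acc, n_don, name=cid)
        truth["labels"][cid] = "active" if active else "inactive"
        truth["partitions"][cid] = partition
        truth["structures"][cid] = structure
        return cid, _smiles_of(structure)

    def potency(active):
        return float(rng.uniform(6.2, 8.5) if active
                     else rng.uniform(3.5, 5.8))

    def emit(cid, smiles, assay, pic50=None, relation="eq", value=None):
        rows.append({
            "compound_id": cid, "smiles": smiles, "relation":
                {"eq": "=", "gt": ">", "lt": "<"}[relation],
            "value_nM": value if value is not None else _pic50_to_nM(pic50),
            "assay_kind": assay})

    def emit_replicated(cid, smiles, assay, pic50):
        n_rep = (int(rng.integers(2, 4))
                 if rng.random() < spec.replicate_fraction else 1)
        for _ in range(n_rep):
            emit(cid, smiles, assay, pic50 + float(rng.uniform(-0.1, 0.1)))

    for _ in range(counts["train_active"]):
        cid, smi = new_compound("train", True)
        emit_replicated(cid, smi, "biochemical", potency(True))
    for k in range(counts["train_inactive"]):
        cid, smi = new_compound("train", False)
        if rng.random() < spec.gt_fraction:
            emit(cid, smi, "biochemical", relation="gt", value=10000.0)
        else:
            emit_replicated(cid, smi, "biochemical", potency(False))
    for _ in range(counts["test_active"]):
        cid, smi = new_compound("test", True)
        emit_replicated(cid, smi, "cellular", potency(True))
        emit(cid, smi, "biochemical", potency(True))
    for _ in range(counts["test_inactive"]):
        cid, smi = new_compound("test", False)
        emit(cid, smi, "cellular", potency(False))
        # biochemical potency is typically better than cellular; sometimes
        # even in the active range — the cell readout still decides
        emit(cid, smi, "biochemical",
             potency(rng.random() < min(0.5, spec.active_fraction)))
    for _ in range(counts.get("binding_only", 0)):
        is_active = bool(rng.random() < spec.active_fraction)
        cid, smi = new_compound("binding", is_active)
        emit(cid, smi, "binding", potency(is_active))

    # planted hazards, all on extra compounds so the partition counts
    # above stay exact
    for k in range(spec.n_dispersion_rejects):
        serial += 1
        cid = f"SYNREJ{serial:05d}"
        smi = _smiles_of(gen_molecule(hash_tuple((spec.seed, "rej", k)) , 9))
        emit(cid, smi, "biochemical", 1.0)
        emit(cid, smi, "biochemical", 9.0)
        truth["partitions"][cid] = "rejected_dispersion"
    for k in range(spec.n_uncertain):
        serial += 1
        cid = f"SYNUNC{serial:05d}"
        smi = _smiles_of(gen_molecule(hash_tuple((spec.seed, "unc", k)), 9))
        emit(cid, smi, "biochemical", 5.0, relation="lt")
        truth["partitions"][cid] = "dropped_uncertain"
    for k in range(spec.n_missing_smiles):
        serial += 1
        rows.append({"compound_id": f"SYNMISS{serial:05d}", "smiles": "",
                     "relation": "=", "value_nM": 100.0,
                     "assay_kind": "biochemical"})

    order = rng.permutation(len(rows))
    df = pd.DataFrame([rows[i] for i in order]).reset_index(drop=True)
    return df, truth


# ---------------------------------------------------------------------------
# Property-matched decoys


def gen_property_matched_decoys(actives: list[MolecularStructure],
                                ratio: int = 50, seed: int = 0,
                                max_attempts: int = 60
                                ) -> list[MolecularStructure]:
    """Decoys matched to each active's simple properties.

    Each decoy matches its template's heavy-atom count (±1), H-bond
    donor count (±1) and acceptor count (±1) while staying below
    Tanimoto 0.4 to the template (this package's 2048-bit radius-2
    circular fingerprint) — chemically similar in bulk properties,
    structurally dissimilar, the contract a graph-generative decoy
    engine fulfils at scale. When a template's attempt budget runs out,
    fewer decoys are returned with a warning.
    """
    if not actives:
        raise ValueError("need at least one active template")
    decoys = []
    for t_index, template in enumerate(actives):
        rng = child_rng(seed, "decoys", t_index)
        t_heavy = len(template.heavy_indices())
        t_don = count_donors(template)
        t_acc = count_acceptors(template)
        t_fp = morgan_fp(template, n_bits=2048, radius=2)
        made = 0
        attempts = 0
        while made < ratio and attempts < max_attempts * ratio:
            attempts += 1
            n_heavy = int(np.clip(t_heavy + rng.integers(-1, 2), 4, None))
            n_acc = int(np.clip(t_acc + rng.integers(-1, 2), 0,
                                max(0, n_heavy - 2)))
            n_don = int(np.clip(t_don + rng.integers(-1, 2), 0, n_acc))
            if n_acc - n_don > n_heavy - n_acc - 2:
                continue  # infeasible combination; redraw
            cand = gen_molecule_with_properties(
                rng, n_heavy, n_acc, n_don,
                name=f"DECOY{t_index:04d}_{made:03d}")
            if tanimoto(t_fp, morgan_fp(cand, n_bits=2048, radius=2)) \
                    >= DECOY_SIMILARITY_CEILING:
                continue
            decoys.append(cand)
            made += 1
        if made < ratio:
            logger.warning("decoy budget exhausted for template %d: "
                           "%d/%d generated", t_index, made, ratio)
    return decoys


# ---------------------------------------------------------------------------
# End-to-end benchmark


@dataclass
class Benchmark:
    """Pipeline-ready bundle with ground truth for recovery tests."""

    spec: FixtureSpec
    split: DataSplit
    complexes: dict[str, ProteinLigandComplex]
    structures: dict[str, MolecularStructure]
    decoy_ids: list[str]
    binder: dict[str, bool]  # latent ground truth behind the planted signal
    log: CurationLog = field(default_factory=CurationLog)

    def test_ids_and_labels(self):
        """Full test set: true molecules plus decoys (decoys negative)."""
        ids = [c.compound_id for c in self.split.test_true] + self.decoy_ids
        labels = [c.is_active for c in self.split.test_true] + \
            [False] * len(self.decoy_ids)
        return ids, np.array(labels, dtype=bool)


def gen_benchmark(spec: FixtureSpec, standardize: bool = False) -> Benchmark:
    """Generate activity data, run curation and splitting, build complexes.

    The activity label of every assayed compound equals its latent
    binder flag with probability (1 + signal_strength)/2; the planted
    anchor signal in the docked complex follows the binder flag, never
    the label. Decoys are non-binders by construction. At
    signal_strength 1 the features separate actives perfectly; at 0 the
    labels are independent of the features. ``standardize=False`` skips
    re-standardizing the generator's already-canonical SMILES.
    """
    table, truth = gen_activity_table(spec)
    log = CurationLog()
    records = load_activity_records(table, log=log)
    compounds = curate(records, standardize=standardize, log=log)
    split = split_by_assay(compounds, log=log)

    flip_p = (1.0 - spec.signal_strength) / 2.0
    rng = child_rng(spec.seed, "binder")
    binder: dict[str, bool] = {}
    for group in (split.training, split.test_true):
        for c in group:
            flip = bool(rng.random() < flip_p)
            binder[c.compound_id] = c.is_active != flip

    active_templates = [truth["structures"][c.compound_id]
                        for c in split.test_true if c.is_active]
    decoys = gen_property_matched_decoys(active_templates,
                                         ratio=spec.decoy_ratio,
                                         seed=spec.seed)
    structures = dict(truth["structures"])
    for d in decoys:
        structures[d.name] = d
        binder[d.name] = False
    split.test_decoys = [d.name for d in decoys]

    complexes = {}
    for cid, flag in binder.items():
        complexes[cid] = gen_pocket_complex(
            hash_tuple((spec.seed, "cplx", cid)), structures[cid],
            plant_signal=flag, pocket_size=spec.pocket_size)
    return Benchmark(spec=spec, split=split, complexes=complexes,
                     structures=structures, decoy_ids=split.test_decoys,
                     binder=binder, log=log)
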