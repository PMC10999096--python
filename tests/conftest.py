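import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from targetsf.structures import MolecularStructure, ProteinLigandComplex

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def ethane():
    return MolecularStructure(
        elements=["C", "C"], coords=[[0, 0, 0], [1.5, 0, 0]],
        bonds=[(0, 1, 1)], n_hydrogens=[3, 3])


@pytest.fixture
def propane():
    return MolecularStructure(
        elements=["C", "C", "C"],
        coords=[[0, 0, 0], [1.5, 0, 0], [3.0, 0, 0]],
        bonds=[(0, 1, 1), (1, 2, 1)], n_hydrogens=[3, 2, 3])


@pytest.fixture
def single_carbon():
    return MolecularStructure(elements=["C"], coords=np.zeros((1, 3)),
                              n_hydrogens=[4])


@pytest.fixture
def toy_complex(single_carbon):
    receptor = MolecularStructure(
        elements=["N"], coords=[[3.0, 0.0, 0.0]],
        res_names=["ALA"], res_numbers=[1], chains=["A"])
    return ProteinLigandComplex(receptor=receptor, ligand=single_carbon)


def permuted_copy(structure: MolecularStructure, rng) -> MolecularStructure:
    """Same molecule with atoms listed in a different order."""
    perm = rng.permutation(structure.n_atoms)  # perm[k] = old index at slot k
    inverse = np.empty_like(perm)
    inverse[perm] = np.arange(structure.n_atoms)
    return MolecularStructure(
        elements=[structure.elements[i] for i in perm],
        coords=structure.coords[perm],
        bonds=[(int(inverse[i]), int(inverse[j]), o)
               for i, j, o in structure.bonds],
        formal_charges=[structure.formal_charges[i] for i in perm],
        aromatic=[structure.aromatic[i] for i in perm],
        n_hydrogens=[structure.n_hydrogens[i] for i in perm],
        res_names=None if structure.res_names is None
        else [structure.res_names[i] for i in perm],
        res_numbers=None if structure.res_numbers is None
        else [structure.res_numbers[i] for i in perm],
        chains=None if structure.chains is None
        else [structure.chains[i] for i in perm])


def random_rotation(rng) -> np.ndarray:
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
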