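import numpy as np
import pytest

from qsar3d.chem_prep import Atom, Bond, Molecule, assign_atom_parameters


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_molecule(coords, elements=None, charges=None, mol_id="m", role="unassigned"):
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    n = len(coords)
    elements = elements or ["C"] * n
    charges = charges if charges is not None else [0.0] * n
    atoms = [Atom(e, c, partial_charge=float(q))
             for e, c, q in zip(elements, coords, charges)]
    mol = Molecule(id=mol_id, atoms=atoms, role=role)
    assign_atom_parameters(mol)
    return mol


@pytest.fixture
def single_carbon():
    return make_molecule([[0.0, 0.0, 0.0]])


def ethanol_molecule():
    """Ethanol with explicit hydrogens, built from RDKit for connectivity."""
    from rdkit import Chem

    m = Chem.AddHs(Chem.MolFromSmiles("CCO"))
    atoms = [Atom(a.GetSymbol(), np.zeros(3)) for a in m.GetAtoms()]
    order = {Chem.BondType.SINGLE: 1.0, Chem.BondType.DOUBLE: 2.0,
             Chem.BondType.TRIPLE: 3.0, Chem.BondType.AROMATIC: 1.5}
    bonds = [Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order[b.GetBondType()])
             for b in m.GetBonds()]
    return Molecule(id="ethanol", atoms=atoms, bonds=bonds), m
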