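"""Core molecule containers.

A :class:`Molecule` is a light, array-friendly record: ordered atoms with 3D
coordinates, per-atom physical parameters, an optional activity and a
train/test role. Bond connectivity is kept as simple ``(i, j, order)``
triples so charge assignment and donor/acceptor typing do not depend on any
toolkit object staying alive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from qsar3d._params import params_for

ROLE_TRAIN = "train"
ROLE_TEST = "test"
ROLE_UNASSIGNED = "unassigned"
_ROLES = {ROLE_TRAIN, ROLE_TEST, ROLE_UNASSIGNED}


@dataclass
class Atom:
    element: str
    coords: np.ndarray                  # shape (3,), Angstrom
    partial_charge: float = 0.0         # e
    vdw_radius: float = 0.0             # Angstrom
    well_depth: float = 0.0             # kcal/mol
    hydrophobicity: float = 0.0
    is_donor: bool = False
    is_acceptor: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise ValueError("Atom.coords must be a 3-vector")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.element}")


@dataclass
class Bond:
    i: int
    j: int
    order: float = 1.0   # 1, 2, 3 or 1.5 (aromatic)


@dataclass
class Molecule:
    id: str
    atoms: list[Atom]
    bonds: list[Bond] = field(default_factory=list)
    pic50: float | None = None
    role: str = ROLE_UNASSIGNED

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"molecule {self.id!r} has no atoms")
        if self.pic50 is not None and not math.isfinite(self.pic50):
            raise ValueError(f"molecule {self.id!r} has non-finite pIC50")
        if self.role not in _ROLES:
            raise ValueError(f"molecule {self.id!r} has unknown role {self.role!r}")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """Atom coordinates as an (n_atoms, 3) array (copy)."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    def set_coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (self.n_atoms, 3):
            raise ValueError("coordinate array shape mismatch")
        for atom, row in zip(self.atoms, xyz):
            atom.coords = row.copy()

    def charges(self) -> np.ndarray:
        return np.array([a.partial_charge for a in self.atoms], dtype=float)

    def neighbors(self, idx: int) -> list[int]:
        out = []
        for b in self.bonds:
            if b.i == idx:
                out.append(b.j)
            elif b.j == idx:
                out.append(b.i)
        return out

    def copy(self) -> "Molecule":
        return Molecule(
            id=self.id,
            atoms=[replace(a, coords=a.coords.copy()) for a in self.atoms],
            bonds=[replace(b) for b in self.bonds],
            pic50=self.pic50,
            role=self.role,
        )


def assign_atom_parameters(mol: Molecule) -> Molecule:
    """Fill vdW radius, well depth, hydrophobicity and donor/acceptor flags.

    Donor: N or O carrying at least one bonded hydrogen. Acceptor: any N or O,
    except an N that is both aromatic-bonded and a donor (pyrrole-type NH,
    whose lone pair is part of the ring system).
    """
    aromatic = set()
    for b in mol.bonds:
        if b.order == 1.5:
            aromatic.add(b.i)
            aromatic.add(b.j)
    for idx, atom in enumerate(mol.atoms):
        p = params_for(atom.element)
        atom.vdw_radius = p.vdw_radius
        atom.well_depth = p.well_depth
        atom.hydrophobicity = p.hydrophobicity
        if atom.element in ("N", "O"):
            has_h = any(mol.atoms[n].element == "H" for n in mol.neighbors(idx))
            atom.is_donor = has_h
            atom.is_acceptor = not (atom.element == "N" and has_h and idx in aromatic)
        else:
            atom.is_donor = False
            atom.is_acceptor = False
    return mol


@dataclass
class Dataset:
    molecules: list[Molecule]

    def __post_init__(self) -> None:
        ids = [m.id for m in self.molecules]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate molecule ids: {dupes}")

    def __iter__(self):
        return iter(self.molecules)

    def __len__(self) -> int:
        return len(self.molecules)

    def get(self, mol_id: str) -> Molecule:
        for m in self.molecules:
            if m.id == mol_id:
                return m
        raise KeyError(mol_id)

    @property
    def train(self) -> list[Molecule]:
        return [m for m in self.molecules if m.role == ROLE_TRAIN]

    @property
    def test(self) -> list[Molecule]:
        return [m for m in self.molecules if m.role == ROLE_TEST]
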