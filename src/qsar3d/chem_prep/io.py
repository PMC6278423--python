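"""Structure and activity-table readers/writers.

SDF (V2000) and MOL2 parsing is delegated to RDKit; this layer converts
toolkit molecules into plain :class:`~qsar3d.chem_prep.types.Molecule`
records, preserving atom order and any MOL2 partial charges.
"""

from __future__ import annotations

import math
import os

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem

from .types import Atom, Bond, Dataset, Molecule, ROLE_UNASSIGNED, ROLE_TRAIN, ROLE_TEST

_BOND_ORDER = {
    Chem.BondType.SINGLE: 1.0,
    Chem.BondType.DOUBLE: 2.0,
    Chem.BondType.TRIPLE: 3.0,
    Chem.BondType.AROMATIC: 1.5,
}

_CHARGE_PROP = "PartialCharge"


def _from_rdkit(rdmol: Chem.Mol, mol_id: str, record_index: int) -> Molecule:
    if rdmol.GetNumConformers() == 0:
        raise ValueError(f"record {record_index}: no 3D coordinates")
    conf = rdmol.GetConformer()
    if not conf.Is3D() and rdmol.GetNumAtoms() > 1:
        # flat-but-tagged-2D files are still accepted if any z is nonzero
        zs = [conf.GetAtomPosition(i).z for i in range(rdmol.GetNumAtoms())]
        if all(z == 0.0 for z in zs) and rdmol.GetNumAtoms() > 3:
            raise ValueError(f"record {record_index}: coordinates are not 3D")
    atoms = []
    for at in rdmol.GetAtoms():
        pos = conf.GetAtomPosition(at.GetIdx())
        charge = 0.0
        if at.HasProp("_TriposPartialCharge"):          # set by the MOL2 parser
            charge = at.GetDoubleProp("_TriposPartialCharge")
        elif at.HasProp(_CHARGE_PROP):                   # SDF atom property list
            charge = at.GetDoubleProp(_CHARGE_PROP)
        atoms.append(Atom(element=at.GetSymbol(),
                          coords=np.array([pos.x, pos.y, pos.z]),
                          partial_charge=charge))
    bonds = [Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(),
                  _BOND_ORDER.get(b.GetBondType(), 1.0))
             for b in rdmol.GetBonds()]
    return Molecule(id=mol_id, atoms=atoms, bonds=bonds)


def read_structures(path: str, format: str | None = None) -> list[Molecule]:
    """Read molecules from an SDF or MOL2 file.

    Coordinates are taken as Angstrom; MOL2 partial charges (and SDF atom
    property lists named ``PartialCharge``) populate ``partial_charge``.
    Atom order follows the file.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format is None:
        format = "MOL2" if path.lower().endswith(".mol2") else "SDF"
    format = format.upper()
    if format not in ("SDF", "MOL2"):
        raise ValueError(f"unsupported format {format!r} (use SDF or MOL2)")

    molecules: list[Molecule] = []
    if format == "SDF":
        supplier = Chem.SDMolSupplier(path, removeHs=False, sanitize=False)
        for idx, rdmol in enumerate(supplier):
            if rdmol is None:
                raise ValueError(f"unparseable SDF record at index {idx} in {path}")
            Chem.CreateAtomDoublePropertyList(rdmol, _CHARGE_PROP)  # no-op if absent
            name = rdmol.GetProp("_Name") if rdmol.HasProp("_Name") else ""
            molecules.append(_from_rdkit(rdmol, name or f"mol{idx}", idx))
    else:
        # RDKit's MOL2 reader handles one record per file; split multi-record
        # files on the molecule header ourselves.
        with open(path) as fh:
            text = fh.read()
        chunks = [c for c in text.split("@<TRIPOS>MOLECULE") if c.strip()]
        for idx, chunk in enumerate(chunks):
            block = "@<TRIPOS>MOLECULE" + chunk
            rdmol = Chem.MolFromMol2Block(block, removeHs=False, sanitize=False)
            if rdmol is None:
                raise ValueError(f"unparseable MOL2 record at index {idx} in {path}")
            name = rdmol.GetProp("_Name") if rdmol.HasProp("_Name") else ""
            molecules.append(_from_rdkit(rdmol, name or f"mol{idx}", idx))
    return molecules


def to_rdkit(mol: Molecule) -> Chem.Mol:
    """Convert to an RDKit molecule with a 3D conformer and charge properties."""
    rw = Chem.RWMol()
    for atom in mol.atoms:
        rw.AddAtom(Chem.Atom(atom.element))
    for b in mol.bonds:
        bt = {1.0: Chem.BondType.SINGLE, 2.0: Chem.BondType.DOUBLE,
              3.0: Chem.BondType.TRIPLE, 1.5: Chem.BondType.AROMATIC}[b.order]
        rw.AddBond(b.i, b.j, bt)
    conf = Chem.Conformer(mol.n_atoms)
    for i, atom in enumerate(mol.atoms):
        conf.SetAtomPosition(i, atom.coords.tolist())
    conf.Set3D(True)
    out = rw.GetMol()
    out.AddConformer(conf)
    out.SetProp("_Name", mol.id)
    for rd_at, atom in zip(out.GetAtoms(), mol.atoms):
        rd_at.SetDoubleProp(_CHARGE_PROP, atom.partial_charge)
        rd_at.SetNoImplicit(True)
    Chem.SanitizeMol(out, Chem.SanitizeFlags.SANITIZE_FINDRADICALS)
    return out


def write_sdf(molecules: list[Molecule], path: str) -> None:
    """Write molecules as V2000 SDF; partial charges go into an atom
    property list so a round trip through :func:`read_structures` preserves
    them."""
    writer = Chem.SDWriter(path)
    try:
        for mol in molecules:
            rdmol = to_rdkit(mol)
            Chem.CreateAtomDoublePropertyList(rdmol, _CHARGE_PROP)
            writer.write(rdmol)
    finally:
        writer.close()


def read_activity_table(path: str) -> Dataset:
    """Read a delimited activity table into a Dataset skeleton.

    Columns: ``id`` plus either ``ic50_uM`` or ``pic50``; optional ``role``
    (train/test). IC50 values are micromolar and converted via
    pIC50 = -log10(IC50 * 1e-6); explicit pIC50 values are taken verbatim.
    The skeleton molecules carry a single placeholder atom; structures are
    attached separately.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    if "id" not in df.columns:
        raise ValueError("activity table needs an 'id' column")
    has_ic50 = "ic50_um" in df.columns
    has_pic50 = "pic50" in df.columns
    if not (has_ic50 or has_pic50):
        raise ValueError("activity table needs an 'ic50_uM' or 'pic50' column")
    ids = df["id"].astype(str).tolist()
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate ids in activity table: {dupes}")
    molecules = []
    for _, row in df.iterrows():
        if has_pic50 and not pd.isna(row.get("pic50")):
            pic50 = float(row["pic50"])
        else:
            ic50 = float(row["ic50_um"])
            if ic50 <= 0 or not math.isfinite(ic50):
                raise ValueError(f"nonpositive IC50 for id {row['id']}: {ic50}")
            pic50 = ic50_to_pic50(ic50)
        role = ROLE_UNASSIGNED
        if "role" in df.columns and not pd.isna(row.get("role")):
            role = str(row["role"]).strip().lower()
            if role not in (ROLE_TRAIN, ROLE_TEST, ROLE_UNASSIGNED):
                raise ValueError(f"unknown role {role!r} for id {row['id']}")
        molecules.append(Molecule(id=str(row["id"]),
                                  atoms=[Atom("C", np.zeros(3))],
                                  pic50=pic50, role=role))
    return Dataset(molecules)


def ic50_to_pic50(ic50_uM: float) -> float:
    """-log10 of a micromolar IC50 expressed in mol/L."""
    if ic50_uM <= 0:
        raise ValueError(f"IC50 must be positive, got {ic50_uM}")
    return -math.log10(ic50_uM * 1e-6)


def read_core_mappings(path: str) -> dict[str, list[tuple[int, int]]]:
    """Read a core-mapping file: ``mol_id<TAB>mol_atom_index<TAB>template_atom_index``
    per line (0-based). Lines starting with '#' are ignored."""
    mappings: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{ln}: expected 3 tab-separated fields")
            mol_id, mi, ti = parts[0], int(parts[1]), int(parts[2])
            mappings.setdefault(mol_id, []).append((mi, ti))
    return mappings
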