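"""Rigid least-squares superposition (Kabsch) and database alignment."""

from __future__ import annotations

import numpy as np

from .types import Dataset, Molecule


def kabsch_superpose(
    ref_coords: np.ndarray,
    mov_coords: np.ndarray,
    atom_mapping: list[tuple[int, int]] | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid transform taking ``mov`` onto ``ref``.

    ``atom_mapping`` pairs ``(mov_index, ref_index)``; with ``None`` the
    arrays are matched row by row. Returns ``(rotation, translation, rmsd)``
    such that ``mov @ rotation.T + translation`` best fits ``ref`` over the
    mapped atoms; the rotation is proper (det = +1).
    """
    ref_coords = np.asarray(ref_coords, dtype=float)
    mov_coords = np.asarray(mov_coords, dtype=float)
    if atom_mapping is None:
        if ref_coords.shape != mov_coords.shape:
            raise ValueError("coordinate arrays differ in shape and no mapping given")
        mov_sel, ref_sel = mov_coords, ref_coords
    else:
        mi = [m for m, _ in atom_mapping]
        ri = [r for _, r in atom_mapping]
        mov_sel, ref_sel = mov_coords[mi], ref_coords[ri]
    if len(mov_sel) < 3:
        raise ValueError(f"need >= 3 mapped atom pairs, got {len(mov_sel)}")
    # collinearity check: rank of centered points must be >= 2
    centered = mov_sel - mov_sel.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ValueError("mapped atoms are collinear; superposition is underdetermined")

    mov_c = mov_sel.mean(axis=0)
    ref_c = ref_sel.mean(axis=0)
    H = (mov_sel - mov_c).T @ (ref_sel - ref_c)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ref_c - R @ mov_c
    fitted = mov_sel @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - ref_sel) ** 2, axis=1))))
    return R, t, rmsd


def apply_transform(mol: Molecule, rotation: np.ndarray, translation: np.ndarray) -> Molecule:
    mol.set_coords(mol.coords @ np.asarray(rotation).T + np.asarray(translation))
    return mol


def align_database(
    dataset: Dataset,
    template_id: str,
    core_mappings: dict[str, list[tuple[int, int]]],
) -> Dataset:
    """Rigidly fit every molecule's core onto the template molecule.

    ``core_mappings[mol_id]`` lists ``(mol_atom_index, template_atom_index)``
    pairs. The template itself is left untouched (an identity mapping for it
    is not required). Returns a new Dataset of transformed copies.
    """
    template = dataset.get(template_id)
    missing = [m.id for m in dataset
               if m.id != template_id and m.id not in core_mappings]
    if missing:
        raise ValueError(f"no core mapping for molecules: {missing}")
    ref = template.coords
    aligned = []
    for mol in dataset:
        out = mol.copy()
        if mol.id != template_id:
            R, t, _ = kabsch_superpose(ref, mol.coords, core_mappings[mol.id])
            apply_transform(out, R, t)
        aligned.append(out)
    return Dataset(aligned)


def core_rmsd(
    template: Molecule,
    mol: Molecule,
    mapping: list[tuple[int, int]],
) -> float:
    """RMSD over mapped core atoms in the current (already aligned) frame."""
    mi = [m for m, _ in mapping]
    ti = [t for _, t in mapping]
    diff = mol.coords[mi] - template.coords[ti]
    return float(np.sqrt(np.mean(np.sum(diff ** 2, axis=1))))
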