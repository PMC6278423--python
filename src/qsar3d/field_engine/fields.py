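"""Grid-field kernels: Lennard-Jones / Coulomb energies and Gaussian
similarity indices, evaluated per molecule over a shared lattice.

All kernels are plain atom sums, so fields are additive over fragments and
invariant under any rigid motion applied jointly to molecules and grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from qsar3d.chem_prep.types import Molecule
from .grid import COULOMB_CONSTANT, GridSpec, ProbeSpec, comfa_probe, comsia_probe

COMFA_KINDS = ("comfa_steric", "comfa_electrostatic")
COMSIA_KINDS = ("comsia_S", "comsia_E", "comsia_H", "comsia_D", "comsia_A")
ALL_KINDS = COMFA_KINDS + COMSIA_KINDS


def _distances(mol: Molecule, grid: GridSpec) -> np.ndarray:
    """(n_atoms, n_points) Euclidean distance matrix."""
    pts = grid.points()
    diff = mol.coords[:, None, :] - pts[None, :, :]
    return np.sqrt(np.sum(diff * diff, axis=2))


def comfa_steric(mol: Molecule, grid: GridSpec, probe: ProbeSpec | None = None) -> np.ndarray:
    """Lennard-Jones 12-6 probe energy at every lattice point (kcal/mol).

    E(q) = sum_i eps_ip * [(R_ip/r)^12 - 2 (R_ip/r)^6] with
    R_ip = r_i + r_probe and eps_ip = sqrt(eps_i * eps_probe); values are
    truncated to +/- cutoff and a probe placed exactly on an atom scores
    +cutoff.
    """
    probe = probe or comfa_probe()
    r = _distances(mol, grid)
    radii = np.array([a.vdw_radius for a in mol.atoms])
    eps = np.sqrt(np.array([a.well_depth for a in mol.atoms]) * probe.probe_well_depth)
    if np.any(radii <= 0):
        raise ValueError("all atoms need a positive vdW radius (assign parameters first)")
    R = radii + probe.probe_radius
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        ratio6 = (R[:, None] / r) ** 6
        energy = eps[:, None] * (ratio6 * ratio6 - 2.0 * ratio6)
    energy[r == 0.0] = np.inf
    total = energy.sum(axis=0)
    total[~np.isfinite(total)] = probe.energy_cutoff
    return np.clip(total, -probe.energy_cutoff, probe.energy_cutoff)


def comfa_electrostatic(
    mol: Molecule,
    grid: GridSpec,
    probe: ProbeSpec | None = None,
    steric_field: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Coulomb probe energy per lattice point, clamped to +/- cutoff.

    Returns ``(values, excluded)``: points whose companion steric value sits
    at +cutoff (probe inside the molecule) are flagged excluded; downstream
    assembly replaces them by the training-column mean over non-excluded
    molecules.
    """
    probe = probe or comfa_probe()
    if steric_field is None:
        steric_field = comfa_steric(mol, grid, probe)
    r = _distances(mol, grid)
    q = mol.charges()
    with np.errstate(divide="ignore", invalid="ignore"):
        energy = COULOMB_CONSTANT * probe.probe_charge * q[:, None] / r
    rows, cols = np.nonzero(r == 0.0)
    with np.errstate(invalid="ignore"):
        energy[rows, cols] = np.sign(q[rows] * probe.probe_charge) * np.inf
    energy = np.nan_to_num(energy, nan=0.0)   # zero charge at zero distance
    total = energy.sum(axis=0)
    total = np.nan_to_num(total, posinf=probe.energy_cutoff, neginf=-probe.energy_cutoff)
    values = np.clip(total, -probe.energy_cutoff, probe.energy_cutoff)
    excluded = steric_field >= probe.energy_cutoff
    return values, excluded


_COMSIA_PROPS = {
    "comsia_S": lambda a: a.vdw_radius ** 3,
    "comsia_E": lambda a: a.partial_charge,
    "comsia_H": lambda a: a.hydrophobicity,
    "comsia_D": lambda a: 1.0 if a.is_donor else 0.0,
    "comsia_A": lambda a: 1.0 if a.is_acceptor else 0.0,
}


def comsia_fields(
    mol: Molecule,
    grid: GridSpec,
    probe: ProbeSpec | None = None,
    kinds: tuple[str, ...] = COMSIA_KINDS,
) -> dict[str, np.ndarray]:
    """Gaussian-attenuated similarity indices for the requested property
    channels: value(q) = -sum_i w_probe * w_i * exp(-alpha * r_iq^2).

    The Gaussian needs no cutoff; values decay below 1e-10 within ~15 A at
    the default alpha.
    """
    probe = probe or comsia_probe()
    unknown = set(kinds) - set(_COMSIA_PROPS)
    if unknown:
        raise ValueError(f"unknown similarity field kinds: {sorted(unknown)}")
    r2 = _distances(mol, grid) ** 2
    g = np.exp(-probe.attenuation_alpha * r2)
    out = {}
    for kind in kinds:
        w = np.array([_COMSIA_PROPS[kind](a) for a in mol.atoms])
        out[kind] = -probe.probe_property * (w[:, None] * g).sum(axis=0)
    return out


@dataclass
class FieldBlock:
    """Per-kind field matrix: molecules x lattice points.

    ``excluded`` marks cells whose raw value is unusable (sterically buried
    probe for the Coulomb field); ``column_fill`` holds the training-column
    means substituted there, kept so prediction rows reuse training fills.
    """
    kind: str
    matrix: np.ndarray
    grid: GridSpec
    mol_ids: list[str]
    excluded: np.ndarray | None = None
    column_fill: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if np.isnan(self.matrix).any():
            raise ValueError(f"NaN in field block {self.kind}")

    @property
    def n_molecules(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_points(self) -> int:
        return self.matrix.shape[1]


def _fill_excluded(matrix: np.ndarray, excluded: np.ndarray,
                   fill: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Replace excluded cells by (training) column means over non-excluded
    molecules; a column excluded everywhere falls back to 0."""
    if fill is None:
        ok = ~excluded
        with np.errstate(invalid="ignore"):
            fill = np.where(ok.any(axis=0),
                            np.nansum(np.where(ok, matrix, np.nan), axis=0)
                            / np.maximum(ok.sum(axis=0), 1),
                            0.0)
    out = matrix.copy()
    idx = np.nonzero(excluded)
    out[idx] = fill[idx[1]]
    return out, fill


def compute_field_blocks(
    molecules,
    grid: GridSpec,
    kinds: tuple[str, ...] = ALL_KINDS,
    comfa: ProbeSpec | None = None,
    comsia: ProbeSpec | None = None,
    reference_blocks: dict[str, FieldBlock] | None = None,
) -> dict[str, FieldBlock]:
    """Evaluate the requested field kinds for every molecule.

    ``reference_blocks`` (from a training run) supplies the column fills for
    excluded electrostatic cells so prediction rows are imputed with
    training means.
    """
    mols = list(molecules)
    if not mols:
        raise ValueError("no molecules")
    comfa = comfa or comfa_probe()
    comsia = comsia or comsia_probe()
    ids = [m.id for m in mols]
    blocks: dict[str, FieldBlock] = {}

    want_steric = "comfa_steric" in kinds or "comfa_electrostatic" in kinds
    steric_rows = ([comfa_steric(m, grid, comfa) for m in mols]
                   if want_steric else None)
    if "comfa_steric" in kinds:
        blocks["comfa_steric"] = FieldBlock("comfa_steric", np.vstack(steric_rows),
                                            grid, ids)
    if "comfa_electrostatic" in kinds:
        rows, masks = [], []
        for m, s in zip(mols, steric_rows):
            v, ex = comfa_electrostatic(m, grid, comfa, steric_field=s)
            rows.append(v)
            masks.append(ex)
        raw = np.vstack(rows)
        excluded = np.vstack(masks)
        ref = reference_blocks.get("comfa_electrostatic") if reference_blocks else None
        filled, fill = _fill_excluded(raw, excluded,
                                      ref.column_fill if ref is not None else None)
        blocks["comfa_electrostatic"] = FieldBlock(
            "comfa_electrostatic", filled, grid, ids,
            excluded=excluded, column_fill=fill)

    comsia_kinds = tuple(k for k in kinds if k in COMSIA_KINDS)
    if comsia_kinds:
        per_mol = [comsia_fields(m, grid, comsia, comsia_kinds) for m in mols]
        for kind in comsia_kinds:
            blocks[kind] = FieldBlock(kind, np.vstack([d[kind] for d in per_mol]),
                                      grid, ids)
    return blocks
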