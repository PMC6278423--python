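"""Aligned toy molecule series with a known sparse generative model.

Molecules share a rigid pseudo-atom scaffold (seed-independent) and differ
only in randomized substituent atoms placed near designated sites, so the
series is pre-aligned by construction and every downstream stage — fields,
descriptor filtering, PLS, validation — can be exercised against known
ground truth. Activities are a sparse linear read-out of grid-field values
at chosen lattice columns plus Gaussian noise, affinely mapped onto a
realistic pIC50 span.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from qsar3d.chem_prep.types import Atom, Dataset, Molecule, assign_atom_parameters
from qsar3d.field_engine.fields import compute_field_blocks, FieldBlock
from qsar3d.field_engine.grid import GridSpec, build_grid

ACTIVITY_SPAN = (2.62, 8.523)   # realistic pIC50 span for the toy series
_SUBSTITUENT_ELEMENTS = ("C", "N", "O", "S", "F")


@dataclass
class SyntheticSpec:
    n_molecules: int = 30
    scaffold_size: int = 8
    n_sites: int = 3
    effect_columns: list[int] | None = None   # lattice indices; None = auto (nearest to sites)
    true_coefficients: list[float] = field(default_factory=lambda: [1.0, -0.8, 0.6])
    noise_sd: float = 0.1
    seed: int = 0
    field_kind: str = "comsia_S"
    margin: float = 4.0
    spacing: float = 2.0
    test_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.n_molecules < 8:
            raise ValueError("need at least 8 molecules")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.n_sites < 0 or self.scaffold_size < 2:
            raise ValueError("invalid geometry spec")


def scaffold_coords(spec: SyntheticSpec) -> np.ndarray:
    """Rigid scaffold geometry: a gentle helix, independent of the seed."""
    i = np.arange(spec.scaffold_size)
    return np.column_stack([1.45 * i,
                            1.2 * np.sin(0.9 * i),
                            1.2 * np.cos(0.9 * i)])


def site_positions(spec: SyntheticSpec) -> np.ndarray:
    """Substituent anchor points, offset from evenly spaced scaffold atoms."""
    if spec.n_sites == 0:
        return np.zeros((0, 3))
    scaf = scaffold_coords(spec)
    anchors = np.linspace(0, spec.scaffold_size - 1, spec.n_sites).astype(int)
    offsets = np.array([[0.0, 0.0, 3.0], [0.0, 3.0, 0.0], [0.0, -3.0, 0.0],
                        [0.0, 0.0, -3.0], [0.0, 2.2, 2.2]])
    sites = np.array([scaf[a] + offsets[k % len(offsets)]
                      for k, a in enumerate(anchors)])
    if spec.n_sites > 1:
        d = np.linalg.norm(sites[:, None] - sites[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        if d.min() < 1.0:
            raise ValueError("substituent sites overlap; adjust the geometry spec")
    return sites


def generate_toy_series(spec: SyntheticSpec) -> Dataset:
    """Deterministic (seeded) aligned series with charged pseudo-atoms."""
    rng = np.random.default_rng(spec.seed)
    scaf = scaffold_coords(spec)
    sites = site_positions(spec)
    scaf_charges = 0.05 * (-1.0) ** np.arange(spec.scaffold_size)
    molecules = []
    for m in range(spec.n_molecules):
        atoms = [Atom("C", xyz.copy(), partial_charge=float(qc))
                 for xyz, qc in zip(scaf, scaf_charges)]
        for s in sites:
            el = _SUBSTITUENT_ELEMENTS[rng.integers(len(_SUBSTITUENT_ELEMENTS))]
            pos = s + rng.uniform(-0.8, 0.8, size=3)
            atoms.append(Atom(el, pos, partial_charge=float(rng.normal(0.0, 0.2))))
        role = "test" if (m + 1) % round(1 / spec.test_fraction) == 0 else "train"
        mol = Molecule(id=f"syn{m:03d}", atoms=atoms, role=role)
        assign_atom_parameters(mol)
        molecules.append(mol)
    return Dataset(molecules)


def default_effect_columns(spec: SyntheticSpec, grid: GridSpec) -> list[int]:
    """Lattice indices nearest to the substituent sites (the informative
    columns by construction)."""
    pts = grid.points()
    cols = []
    for s in site_positions(spec):
        cols.append(int(np.argmin(np.sum((pts - s) ** 2, axis=1))))
    return cols


def generate_activities(
    dataset: Dataset,
    spec: SyntheticSpec,
    grid: GridSpec | None = None,
    field_block: FieldBlock | None = None,
) -> tuple[Dataset, dict]:
    """Attach activities: a sparse linear read-out of field columns plus
    noise, affinely rescaled onto the target pIC50 span.

    Returns the dataset (modified in place) and a ground-truth dict with the
    grid, effect columns and coefficients actually used.
    """
    mols = list(dataset)
    if grid is None:
        grid = build_grid(mols, margin=spec.margin, spacing=spec.spacing)
    if field_block is None:
        field_block = compute_field_blocks(mols, grid,
                                           kinds=(spec.field_kind,))[spec.field_kind]
    X = field_block.matrix
    cols = (spec.effect_columns if spec.effect_columns is not None
            else default_effect_columns(spec, grid))
    if any(c < 0 or c >= X.shape[1] for c in cols):
        raise ValueError(f"effect column outside grid (n_points={X.shape[1]})")
    coefs = np.asarray(spec.true_coefficients, dtype=float)[: len(cols)]
    if len(coefs) < len(cols):
        raise ValueError("fewer true coefficients than effect columns")
    signal = X[:, cols] @ coefs
    lo, hi = ACTIVITY_SPAN
    span = signal.max() - signal.min()
    if span > 0:
        y = lo + (signal - signal.min()) / span * (hi - lo)
    else:
        y = np.full(len(mols), (lo + hi) / 2.0)
    rng = np.random.default_rng([spec.seed, 7])
    y = y + rng.normal(0.0, spec.noise_sd, size=len(mols))
    for mol, yi in zip(mols, y):
        mol.pic50 = float(yi)
    truth = {"grid": grid, "effect_columns": list(cols),
             "coefficients": coefs.tolist(), "field_kind": spec.field_kind}
    return dataset, truth
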