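"""Iterative partial-equalization (PEOE) sigma charges.

Electronegativity is modelled per atom as a quadratic in charge,
``chi(q) = a + b*q + c*q**2``, and charge flows along each bond from the
less to the more electronegative atom, scaled by the damping factor
``(1/2)**k`` at iteration ``k``. Parameters are the original PEOE values
(Gasteiger & Marsili, Tetrahedron 36 (1980) 3219) keyed by element and
hybridization class; the hydrogen cation electronegativity is the special
published constant 20.02.

Only the sigma component is computed; pi systems receive plain PEOE charges.
"""

from __future__ import annotations

import numpy as np

from .types import Molecule

# (a, b, c) per (element, hybridization class)
PEOE_PARAMS: dict[tuple[str, str], tuple[float, float, float]] = {
    ("H", ""): (7.17, 6.24, -0.56),
    ("C", "sp3"): (7.98, 9.18, 1.88),
    ("C", "sp2"): (8.79, 9.32, 1.51),
    ("C", "sp"): (10.39, 9.45, 0.73),
    ("N", "sp3"): (11.54, 10.82, 1.36),
    ("N", "sp2"): (12.87, 11.15, 0.85),
    ("N", "sp"): (15.68, 11.70, -0.27),
    ("O", "sp3"): (14.18, 12.92, 1.39),
    ("O", "sp2"): (17.07, 13.79, 0.47),
    ("F", ""): (14.66, 13.85, 2.31),
    ("Cl", ""): (11.00, 9.69, 1.35),
    ("Br", ""): (10.08, 8.47, 1.16),
    ("I", ""): (9.90, 7.96, 0.96),
    ("S", ""): (10.14, 9.13, 1.38),
    ("P", ""): (8.90, 8.24, 0.96),
}

H_CATION_CHI = 20.02


def _hybridization(mol: Molecule, idx: int) -> str:
    el = mol.atoms[idx].element
    if el in ("H", "F", "Cl", "Br", "I", "S", "P"):
        return ""
    orders = [b.order for b in mol.bonds if idx in (b.i, b.j)]
    n_triple = sum(1 for o in orders if o == 3.0)
    n_double = sum(1 for o in orders if o == 2.0)
    n_arom = sum(1 for o in orders if o == 1.5)
    if n_triple or n_double >= 2:
        return "sp"
    if n_double or n_arom:
        return "sp2"
    return "sp3"


def gasteiger_charges(
    mol: Molecule,
    n_iter: int = 6,
    formal_charges: np.ndarray | None = None,
) -> Molecule:
    """Assign PEOE sigma charges in place (and return the molecule).

    ``formal_charges`` seeds the iteration (defaults to all zero); the total
    charge is conserved exactly by construction.
    """
    n = mol.n_atoms
    abc = []
    chi_plus = []
    for i, atom in enumerate(mol.atoms):
        key = (atom.element, _hybridization(mol, i))
        if key not in PEOE_PARAMS:
            raise ValueError(
                f"no PEOE electronegativity parameters for element "
                f"{atom.element!r} (class {key[1] or 'default'!r})"
            )
        a, b, c = PEOE_PARAMS[key]
        abc.append((a, b, c))
        chi_plus.append(H_CATION_CHI if atom.element == "H" else a + b + c)
    abc_arr = np.array(abc)
    chi_plus = np.array(chi_plus)

    q = (np.zeros(n) if formal_charges is None
         else np.asarray(formal_charges, dtype=float).copy())
    pairs = [(b.i, b.j) for b in mol.bonds]
    for k in range(1, n_iter + 1):
        damp = 0.5 ** k
        chi = abc_arr[:, 0] + abc_arr[:, 1] * q + abc_arr[:, 2] * q * q
        dq = np.zeros(n)
        for i, j in pairs:
            if chi[j] > chi[i]:
                donor, acceptor = i, j
            else:
                donor, acceptor = j, i
            transfer = (chi[acceptor] - chi[donor]) / chi_plus[donor] * damp
            dq[donor] += transfer
            dq[acceptor] -= transfer
        q += dq

    for atom, qi in zip(mol.atoms, q):
        atom.partial_charge = float(qi)
    return mol
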