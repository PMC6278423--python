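"""Lattice definition and probe parameters for grid-field computation."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from qsar3d._params import params_for

DEFAULT_MARGIN = 4.0     # Angstrom beyond every atom, each axis
DEFAULT_SPACING = 2.0    # Angstrom lattice interval
DEFAULT_CUTOFF = 30.0    # kcal/mol truncation for LJ/Coulomb fields
DEFAULT_ALPHA = 0.3      # 1/Angstrom^2 Gaussian attenuation (similarity fields)
COULOMB_CONSTANT = 332.0  # kcal*Angstrom/(mol*e^2), dielectric constant 1


@dataclass(frozen=True)
class GridSpec:
    origin: tuple[float, float, float]
    spacing: float
    dims: tuple[int, int, int]
    margin: float = DEFAULT_MARGIN

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if any(d < 2 for d in self.dims):
            raise ValueError("need at least 2 lattice points per axis")

    @property
    def n_points(self) -> int:
        return int(np.prod(self.dims))

    def points(self) -> np.ndarray:
        """All lattice points as an (n_points, 3) array. Ordering is C-order
        over (ix, iy, iz), i.e. z varies fastest."""
        axes = [np.asarray(self.origin)[k] + self.spacing * np.arange(self.dims[k])
                for k in range(3)]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    def to_dict(self) -> dict:
        return {"origin": list(self.origin), "spacing": self.spacing,
                "dims": list(self.dims), "margin": self.margin}

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(origin=tuple(d["origin"]), spacing=float(d["spacing"]),
                   dims=tuple(int(x) for x in d["dims"]),
                   margin=float(d.get("margin", DEFAULT_MARGIN)))


def build_grid(molecules, margin: float = DEFAULT_MARGIN,
               spacing: float = DEFAULT_SPACING) -> GridSpec:
    """Axis-aligned lattice covering every atom plus ``margin`` per axis.

    The origin is anchored to the spacing lattice
    (``floor((min - margin)/spacing) * spacing`` per axis) so that a
    translation of all molecules by a multiple of the spacing shifts the
    lattice by exactly that amount.
    """
    mols = list(molecules)
    if not mols:
        raise ValueError("cannot build a grid from an empty molecule list")
    allxyz = np.vstack([m.coords for m in mols])
    lo = allxyz.min(axis=0) - margin
    hi = allxyz.max(axis=0) + margin
    origin = np.floor(lo / spacing) * spacing
    dims = np.maximum(np.ceil((hi - origin) / spacing).astype(int) + 1, 2)
    return GridSpec(origin=tuple(float(x) for x in origin), spacing=float(spacing),
                    dims=tuple(int(d) for d in dims), margin=float(margin))


@dataclass(frozen=True)
class ProbeSpec:
    """Probe-atom parameters.

    The LJ/Coulomb probe mimics an sp3 carbon with +1 charge; the similarity
    probe carries +1 in every property channel with a 1 Angstrom radius.
    """
    probe_radius: float
    probe_well_depth: float
    probe_charge: float = 1.0
    probe_property: float = 1.0
    energy_cutoff: float = DEFAULT_CUTOFF
    attenuation_alpha: float = DEFAULT_ALPHA

    def __post_init__(self) -> None:
        if self.energy_cutoff <= 0:
            raise ValueError("energy_cutoff must be positive")
        if self.attenuation_alpha <= 0:
            raise ValueError("attenuation_alpha must be positive")


def comfa_probe(energy_cutoff: float = DEFAULT_CUTOFF) -> ProbeSpec:
    carbon = params_for("C")
    return ProbeSpec(probe_radius=carbon.vdw_radius,
                     probe_well_depth=carbon.well_depth,
                     probe_charge=1.0, energy_cutoff=energy_cutoff)


def comsia_probe(attenuation_alpha: float = DEFAULT_ALPHA) -> ProbeSpec:
    return ProbeSpec(probe_radius=1.0, probe_well_depth=0.0,
                     probe_charge=1.0, probe_property=1.0,
                     attenuation_alpha=attenuation_alpha)
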