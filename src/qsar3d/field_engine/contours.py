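"""StDev*Coefficient contour maps from a fitted model.

Each lattice point is scored by the training-column standard deviation times
the model coefficient for that column (on the raw field scale). The favored
region is the smallest set of top-scoring points carrying 80% of the total
positive score mass; the disfavored region is the analogue holding 20% of
the negative mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fields import FieldBlock
from .grid import GridSpec


@dataclass
class ContourMap:
    kind: str
    scores: np.ndarray            # per lattice point, stdev * coefficient
    grid: GridSpec
    favored_level: float
    disfavored_level: float
    favored_mask: np.ndarray
    disfavored_mask: np.ndarray
    degenerate: bool = False      # all-zero score vector

    def __post_init__(self) -> None:
        if not self.degenerate and self.favored_level < self.disfavored_level:
            raise ValueError("favored level below disfavored level")

    def favored_points(self) -> np.ndarray:
        return self.favored_mask

    def disfavored_points(self) -> np.ndarray:
        return self.disfavored_mask


def contribution_levels(
    scores: np.ndarray,
    favored_fraction: float = 0.8,
    disfavored_fraction: float = 0.2,
) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Contour levels and point sets by cumulative score mass.

    Favored: take positive scores in descending order until their cumulative
    sum first reaches ``favored_fraction`` of the total positive mass; the
    level is the last score taken. Disfavored mirrors this on negative
    scores (most negative first, ``disfavored_fraction`` of negative mass).
    Returns ``(favored_level, disfavored_level, favored_mask, disfavored_mask)``.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.size
    favored_mask = np.zeros(n, dtype=bool)
    disfavored_mask = np.zeros(n, dtype=bool)
    favored_level = disfavored_level = 0.0

    pos_idx = np.nonzero(scores > 0)[0]
    if pos_idx.size:
        order = pos_idx[np.argsort(-scores[pos_idx], kind="stable")]
        cum = np.cumsum(scores[order])
        m = int(np.searchsorted(cum, favored_fraction * cum[-1] - 1e-12)) + 1
        favored_mask[order[:m]] = True
        favored_level = float(scores[order[m - 1]])

    neg_idx = np.nonzero(scores < 0)[0]
    if neg_idx.size:
        order = neg_idx[np.argsort(scores[neg_idx], kind="stable")]
        cum = np.cumsum(-scores[order])
        m = int(np.searchsorted(cum, disfavored_fraction * cum[-1] - 1e-12)) + 1
        disfavored_mask[order[:m]] = True
        disfavored_level = float(scores[order[m - 1]])

    return favored_level, disfavored_level, favored_mask, disfavored_mask


def contour_maps(model, field_blocks: dict[str, FieldBlock],
                 favored_fraction: float = 0.8,
                 disfavored_fraction: float = 0.2) -> list[ContourMap]:
    """Build a contour map per field block from a fitted PLS model.

    ``model`` must expose ``coefficients_for_block(kind) -> (point_indices,
    coefs)`` on the raw descriptor scale (see PLSModel).
    """
    maps = []
    for kind, block in field_blocks.items():
        scores = np.zeros(block.n_points)
        cols, coefs = model.coefficients_for_block(kind)
        stdev = block.matrix.std(axis=0)
        scores[cols] = stdev[cols] * coefs
        if np.allclose(scores, 0.0):
            empty = np.zeros(block.n_points, dtype=bool)
            maps.append(ContourMap(kind, scores, block.grid, 0.0, 0.0,
                                   empty, empty.copy(), degenerate=True))
            continue
        fav, dis, fmask, dmask = contribution_levels(
            scores, favored_fraction, disfavored_fraction)
        maps.append(ContourMap(kind, scores, block.grid, fav, dis, fmask, dmask))
    return maps


def write_cube(cmap: ContourMap, path: str, comment: str = "") -> None:
    """Write scores as a Gaussian-cube-style volumetric text file (Bohr
    header units, as viewers expect)."""
    bohr = 1.0 / 0.529177210903
    g = cmap.grid
    with open(path, "w") as fh:
        fh.write(f"{cmap.kind} stdev*coeff contour\n{comment}\n")
        ox, oy, oz = (c * bohr for c in g.origin)
        fh.write(f"{0:5d} {ox:12.6f} {oy:12.6f} {oz:12.6f}\n")
        step = g.spacing * bohr
        fh.write(f"{g.dims[0]:5d} {step:12.6f} {0.0:12.6f} {0.0:12.6f}\n")
        fh.write(f"{g.dims[1]:5d} {0.0:12.6f} {step:12.6f} {0.0:12.6f}\n")
        fh.write(f"{g.dims[2]:5d} {0.0:12.6f} {0.0:12.6f} {step:12.6f}\n")
        vol = cmap.scores.reshape(g.dims)
        for ix in range(g.dims[0]):
            for iy in range(g.dims[1]):
                row = vol[ix, iy, :]
                for start in range(0, len(row), 6):
                    fh.write(" ".join(f"{v:12.5e}" for v in row[start:start + 6]))
                    fh.write("\n")
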