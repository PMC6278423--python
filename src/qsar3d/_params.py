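"""Element parameter table shared by charge assignment and field kernels."""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from functools import lru_cache


@dataclass(frozen=True)
class ElementParams:
    element: str
    vdw_radius: float        # Angstrom
    well_depth: float        # kcal/mol
    hydrophobicity: float    # dimensionless atomic contribution


@lru_cache(maxsize=1)
def element_table() -> dict[str, ElementParams]:
    """Load the packaged per-element parameter table (keyed by symbol)."""
    path = resources.files("qsar3d.data").joinpath("element_params.csv")
    table: dict[str, ElementParams] = {}
    with path.open() as fh:
        rows = (r for r in fh if not r.startswith("#"))
        for rec in csv.DictReader(rows):
            table[rec["element"]] = ElementParams(
                element=rec["element"],
                vdw_radius=float(rec["vdw_radius"]),
                well_depth=float(rec["well_depth"]),
                hydrophobicity=float(rec["hydrophobicity"]),
            )
    return table


def params_for(element: str) -> ElementParams:
    try:
        return element_table()[element]
    except KeyError:
        raise KeyError(
            f"no element parameters for {element!r}; supported: "
            f"{sorted(element_table())}"
        ) from None
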