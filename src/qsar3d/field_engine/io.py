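"""Delimited export/import of field matrices with a grid sidecar."""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd

from .fields import FieldBlock
from .grid import GridSpec


def write_field_block(block: FieldBlock, prefix: str) -> tuple[str, str]:
    """Write ``<prefix>.<kind>.tsv`` (molecules x points, id-indexed) and a
    ``<prefix>.<kind>.grid.json`` sidecar; returns the two paths."""
    mat_path = f"{prefix}.{block.kind}.tsv"
    side_path = f"{prefix}.{block.kind}.grid.json"
    df = pd.DataFrame(block.matrix, index=block.mol_ids)
    df.index.name = "id"
    df.to_csv(mat_path, sep="\t", float_format="%.10g")
    sidecar = {"kind": block.kind, "grid": block.grid.to_dict()}
    if block.column_fill is not None:
        sidecar["column_fill"] = [float(x) for x in block.column_fill]
    with open(side_path, "w") as fh:
        json.dump(sidecar, fh, indent=1)
    return mat_path, side_path


def read_field_block(prefix: str, kind: str) -> FieldBlock:
    mat_path = f"{prefix}.{kind}.tsv"
    side_path = f"{prefix}.{kind}.grid.json"
    for p in (mat_path, side_path):
        if not os.path.exists(p):
            raise FileNotFoundError(p)
    df = pd.read_csv(mat_path, sep="\t", index_col="id")
    with open(side_path) as fh:
        sidecar = json.load(fh)
    fill = sidecar.get("column_fill")
    return FieldBlock(kind=kind, matrix=df.to_numpy(dtype=float),
                      grid=GridSpec.from_dict(sidecar["grid"]),
                      mol_ids=[str(i) for i in df.index],
                      column_fill=None if fill is None else np.asarray(fill))
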