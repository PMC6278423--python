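"""Field blocks -> scaled descriptor matrix.

Columns with tiny variance are dropped (minimum-sigma filter), then each
block is rescaled so all blocks carry equal total variance ("standard"
block scaling: every field gets the same potential influence). Scale
factors and column masks are stored so prediction rows go through the
identical transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from qsar3d.field_engine.fields import FieldBlock

DEFAULT_MIN_SIGMA = 2.0


@dataclass
class DescriptorMatrix:
    values: np.ndarray                 # molecules x retained columns (scaled)
    block_labels: list[str]            # block order
    column_block: np.ndarray           # per column: index into block_labels
    column_point: np.ndarray           # per column: lattice point index
    scale_factors: dict[str, float]    # per block multiplier
    masks: dict[str, np.ndarray]       # per block: retained-point boolean mask
    min_sigma: float

    def __post_init__(self) -> None:
        if np.isnan(self.values).any():
            raise ValueError("NaN in descriptor matrix")

    @property
    def n_molecules(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    def columns_of(self, label: str) -> np.ndarray:
        b = self.block_labels.index(label)
        return np.nonzero(self.column_block == b)[0]

    def transform(self, blocks: dict[str, FieldBlock]) -> np.ndarray:
        """Build descriptor rows for new molecules with the training masks
        and scale factors."""
        parts = []
        for label in self.block_labels:
            if label not in blocks:
                raise ValueError(f"missing field block {label!r} for prediction")
            block = blocks[label]
            mask = self.masks[label]
            if block.n_points != mask.size:
                raise ValueError(
                    f"block {label!r} has {block.n_points} points, expected {mask.size}")
            parts.append(block.matrix[:, mask] * self.scale_factors[label])
        return np.hstack(parts)


def assemble_descriptors(
    field_blocks: dict[str, FieldBlock],
    min_sigma: float = DEFAULT_MIN_SIGMA,
) -> DescriptorMatrix:
    """Filter, block-scale and concatenate training field blocks."""
    if not field_blocks:
        raise ValueError("no field blocks")
    n_mols = {b.n_molecules for b in field_blocks.values()}
    if len(n_mols) != 1:
        raise ValueError("field blocks disagree on the molecule axis")

    labels, parts, col_block, col_point = [], [], [], []
    scale_factors: dict[str, float] = {}
    masks: dict[str, np.ndarray] = {}
    for bi, (label, block) in enumerate(field_blocks.items()):
        sigma = block.matrix.std(axis=0)
        mask = sigma >= min_sigma
        masks[label] = mask
        if not mask.any():
            scale_factors[label] = 1.0
            labels.append(label)
            continue
        sub = block.matrix[:, mask]
        total_var = float((sub.std(axis=0) ** 2).sum())
        factor = 1.0 / np.sqrt(total_var)
        scale_factors[label] = factor
        labels.append(label)
        parts.append(sub * factor)
        col_block.extend([bi] * int(mask.sum()))
        col_point.extend(np.nonzero(mask)[0].tolist())
    if not parts:
        raise ValueError(
            f"minimum-sigma filter ({min_sigma}) removed every column")
    return DescriptorMatrix(
        values=np.hstack(parts),
        block_labels=labels,
        column_block=np.asarray(col_block, dtype=int),
        column_point=np.asarray(col_point, dtype=int),
        scale_factors=scale_factors,
        masks=masks,
        min_sigma=min_sigma,
    )
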