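"""Pareto ranking of candidate models on (q2, r2, SEE, F)."""

from __future__ import annotations

import numpy as np


def _dominates(a, b) -> bool:
    """a dominates b: >= on q2, r2, F, <= on SEE, strict somewhere."""
    ge = (a[0] >= b[0]) and (a[1] >= b[1]) and (a[2] <= b[2]) and (a[3] >= b[3])
    strict = (a[0] > b[0]) or (a[1] > b[1]) or (a[2] < b[2]) or (a[3] > b[3])
    return ge and strict


def pareto_rank(models: list[tuple[float, float, float, float]]) -> list[list[int]]:
    """Non-dominated sorting of (q2, r2, SEE, F) tuples.

    Returns fronts of model indices: front 0 is the non-dominated set, each
    later front is non-dominated once earlier fronts are removed. Within a
    front, indices are ordered by q2 descending (ties keep input order).
    """
    if not models:
        raise ValueError("need at least one model")
    remaining = list(range(len(models)))
    fronts: list[list[int]] = []
    while remaining:
        front = [i for i in remaining
                 if not any(_dominates(models[j], models[i])
                            for j in remaining if j != i)]
        front.sort(key=lambda i: -models[i][0])
        fronts.append(front)
        remaining = [i for i in remaining if i not in front]
    return fronts
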