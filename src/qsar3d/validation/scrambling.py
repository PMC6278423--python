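"""Progressive y-scrambling robustness check.

Activities are perturbed in a controlled way: y is sorted into a number of
contiguous bins and permuted within each bin, so a large bin count means a
mild scramble (coarse structure preserved) and a small count approaches a
full randomization. For every scramble the correlation r2_yy' between the
scrambled and original activities is recorded together with the LOO q2 of a
model refit on the scrambled response. A quadratic of q2' against r2_yy'
is then extrapolated to the critical perturbation level (default 0.85),
giving the corrected Q2 and the local slope dq2'/dr2_yy'.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from qsar3d.pls_engine.crossval import loo_q2

CRITICAL_POINT = 0.85
DEFAULT_BIN_COUNTS = (2, 3, 4, 6, 8, 10)


@dataclass
class ScramblingResult:
    q2_critical: float                       # corrected Q2 at the critical point
    slope: float                             # dq2'/dr2_yy' at the critical point
    levels: list[tuple[float, float]]        # (r2_yy', q2') pairs, sorted
    critical_point: float = CRITICAL_POINT
    coefficients: tuple[float, float, float] = (0.0, 0.0, 0.0)


def _scramble_within_bins(y: np.ndarray, n_bins: int,
                          rng: np.random.Generator) -> np.ndarray:
    order = np.argsort(y, kind="stable")
    edges = np.array_split(order, n_bins)
    out = y.copy()
    for bin_idx in edges:
        out[bin_idx] = y[rng.permutation(bin_idx)]
    return out


def progressive_scrambling(
    X: np.ndarray,
    y: np.ndarray,
    c: int,
    n_bins_list=DEFAULT_BIN_COUNTS,
    reps: int = 10,
    seed: int = 0,
    critical_point: float = CRITICAL_POINT,
    loo_method: str = "sampls",
) -> ScramblingResult:
    """Run the binned-scramble schedule and extrapolate to the critical point."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if len(np.unique(y)) < max(n_bins_list):
        raise ValueError(
            f"too few distinct y values ({len(np.unique(y))}) for "
            f"{max(n_bins_list)} bins")
    rng = np.random.default_rng(seed)
    yvar = y.var()
    levels: list[tuple[float, float]] = []
    for n_bins in n_bins_list:
        for _ in range(reps):
            ys = _scramble_within_bins(y, n_bins, rng)
            if np.allclose(ys, y):
                r2yy = 1.0
            else:
                r2yy = float(np.corrcoef(y, ys)[0, 1] ** 2)
            q2s = float(loo_q2(X, ys, c, method=loo_method)[c - 1])
            levels.append((r2yy, q2s))
    levels.sort(key=lambda t: t[0])
    r = np.array([lv[0] for lv in levels])
    q = np.array([lv[1] for lv in levels])
    if np.ptp(r) < 1e-12:
        coeffs = np.array([0.0, 0.0, float(q.mean())])
    else:
        deg = 2 if len(np.unique(r)) >= 3 else 1
        coeffs = np.polyfit(r, q, deg)
        if deg == 1:
            coeffs = np.array([0.0, coeffs[0], coeffs[1]])
    a, b, c0 = (float(v) for v in coeffs)
    q2_critical = a * critical_point ** 2 + b * critical_point + c0
    slope = 2 * a * critical_point + b
    return ScramblingResult(q2_critical=float(q2_critical), slope=float(slope),
                            levels=levels, critical_point=critical_point,
                            coefficients=(a, b, c0))
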