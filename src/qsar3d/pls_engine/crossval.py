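"""Leave-one-out cross-validation: explicit refits and the fast
covariance-matrix (sample-distance) path.

The fast path runs NIPALS entirely in the space of sample inner products:
with K = X X' precomputed once, every fold costs O(c n^2) regardless of the
number of descriptor columns, which is the property that makes LOO on grid
fields practical. Both paths agree to machine precision.
"""

from __future__ import annotations

import numpy as np

from .model import nipals_components, pls_coefficients


def _press_refit(X: np.ndarray, y: np.ndarray, c_max: int) -> np.ndarray:
    """PRESS per component count by explicitly refitting each fold."""
    n = len(y)
    press = np.zeros(c_max)
    for i in range(n):
        keep = np.arange(n) != i
        Xt, yt = X[keep], y[keep]
        xm, ym = Xt.mean(axis=0), yt.mean()
        W, P, Q = nipals_components(Xt - xm, yt - ym, c_max)
        for c in range(1, c_max + 1):
            beta = pls_coefficients(W, P, Q, c)
            pred = (X[i] - xm) @ beta + ym
            press[c - 1] += (y[i] - pred) ** 2
    return press


def _press_sampls(X: np.ndarray, y: np.ndarray, c_max: int) -> np.ndarray:
    """PRESS per component count from the precomputed Gram matrix.

    Kernel NIPALS: each fold centers its sub-Gram matrix, extracts scores
    t = K_d y_res (normalized), deflates K_d on both sides and carries the
    left-out sample's kernel row through the same deflations, accumulating
    its prediction component by component.
    """
    n = len(y)
    K = X @ X.T
    press = np.zeros(c_max)
    idx = np.arange(n)
    for i in range(n):
        S = idx[idx != i]
        Ks = K[np.ix_(S, S)]
        krow = K[i, S]
        m = n - 1
        rowmean = Ks.mean(axis=0)
        allmean = Ks.mean()
        Kd = Ks - rowmean[None, :] - rowmean[:, None] + allmean
        kd = krow - krow.mean() - rowmean + allmean
        ym = y[S].mean()
        yres = y[S] - ym
        pred = ym
        for c in range(1, c_max + 1):
            s2 = yres @ Kd @ yres            # = ||X_d' y_res||^2
            if s2 < 1e-28:
                press[c - 1:] += (y[i] - pred) ** 2
                break
            s = np.sqrt(s2)
            t = Kd @ yres / s                # training scores
            t_test = kd @ yres / s           # left-out sample's score
            tt = t @ t
            q = (yres @ t) / tt
            pred = pred + t_test * q
            press[c - 1] += (y[i] - pred) ** 2
            # deflate X_d <- X_d - t p' in kernel space (both sides)
            tK = t @ Kd
            Kd = Kd - np.outer(t, tK) / tt - np.outer(tK, t) / tt \
                + np.outer(t, t) * (t @ tK) / tt ** 2
            kd = kd - t_test * tK / tt
            yres = yres - t * q
    return press


def loo_q2(X: np.ndarray, y: np.ndarray, c_max: int,
           method: str = "sampls") -> np.ndarray:
    """q2 per component count (1..c_max) from LOO cross-validation.

    q2(c) = 1 - PRESS(c) / sum((y - mean(y))^2), the mean taken over the
    full training set (not fold-wise) to match the covariance-matrix
    formulation.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n < 4:
        raise ValueError("LOO needs at least 4 samples")
    if c_max < 1:
        raise ValueError("c_max must be >= 1")
    if c_max > n - 2:
        raise ValueError(f"c_max={c_max} too large for n={n}")
    if method == "sampls":
        press = _press_sampls(X, y, c_max)
    elif method == "refit":
        press = _press_refit(X, y, c_max)
    else:
        raise ValueError(f"unknown LOO method {method!r}")
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:
        raise ValueError("y has zero variance")
    return 1.0 - press / tss


def select_onc(q2_by_c) -> int:
    """Optimal number of components: the smallest count achieving the
    maximum q2 (1-based)."""
    q2 = np.asarray(list(q2_by_c), dtype=float)
    if q2.size == 0:
        raise ValueError("empty q2 sequence")
    return int(np.argmax(q2)) + 1
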