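"""NIPALS partial-least-squares regression and the fitted-model container."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .descriptors import DescriptorMatrix

NIPALS_TOL = 1e-12
NIPALS_MAX_ITER = 500


def nipals_components(Xc: np.ndarray, yc: np.ndarray, c: int,
                      tol: float = NIPALS_TOL,
                      max_iter: int = NIPALS_MAX_ITER):
    """Extract ``c`` latent components from centered X, y.

    Returns (W, P, Q): weight, loading and y-loading arrays with one column
    (or entry) per component. Initialization is deterministic (the y vector
    serves as the starting score); for a single y column the inner loop
    converges in one pass but the tolerance check is kept for form.
    """
    X = Xc.copy()
    y = yc.copy()
    n, p = X.shape
    W = np.zeros((p, c))
    P = np.zeros((p, c))
    Q = np.zeros(c)
    for a in range(c):
        # With a single y column the NIPALS inner iteration is exact after
        # one pass (u = y residual, w proportional to X'y), so the tol /
        # max_iter knobs are kept for interface stability but never cycle.
        u = y
        w = X.T @ u
        norm = np.linalg.norm(w)
        if norm < 1e-14:
            raise ValueError(
                f"component {a + 1} exceeds the rank of X (weight collapsed)")
        w = w / norm
        t = X @ w
        tt = t @ t
        if tt < 1e-28:
            raise ValueError(
                f"component {a + 1} exceeds the rank of X (score collapsed)")
        q = (y @ t) / tt
        p_load = (X.T @ t) / tt
        W[:, a] = w
        P[:, a] = p_load
        Q[a] = q
        X = X - np.outer(t, p_load)
        y = y - t * q
    return W, P, Q


def pls_coefficients(W: np.ndarray, P: np.ndarray, Q: np.ndarray,
                     n_components: int | None = None) -> np.ndarray:
    """Regression vector on the centered-X scale for the first ``c``
    components: B = W (P'W)^-1 q."""
    c = n_components if n_components is not None else W.shape[1]
    Wc, Pc, Qc = W[:, :c], P[:, :c], Q[:c]
    return Wc @ np.linalg.solve(Pc.T @ Wc, Qc)


@dataclass
class PLSModel:
    """Latent-variable linear model with fit statistics.

    ``coefficients``/``intercept`` act on the scaled descriptor space (the
    output of DescriptorMatrix.transform); ``coefficients_for_block`` maps
    them back to raw field values per lattice point.
    """
    n_components: int
    coefficients: np.ndarray
    intercept: float
    r2: float
    see: float
    f_stat: float
    field_contributions: dict[str, float]
    q2: float | None = None
    q2_by_components: list[float] | None = None
    block_labels: list[str] = field(default_factory=list)
    column_block: np.ndarray | None = None
    column_point: np.ndarray | None = None
    scale_factors: dict[str, float] = field(default_factory=dict)
    masks: dict[str, list[bool]] = field(default_factory=dict)
    column_fills: dict[str, list[float]] = field(default_factory=dict)
    grid: dict | None = None
    min_sigma: float | None = None

    def __post_init__(self) -> None:
        if self.q2 is not None and self.q2 > self.r2 + 1e-9:
            raise ValueError("q2 cannot exceed r2")
        if self.field_contributions:
            total = sum(self.field_contributions.values())
            if abs(total - 1.0) > 1e-9 or min(self.field_contributions.values()) < 0:
                raise ValueError("field contributions must be >= 0 and sum to 1")

    def predict(self, rows: np.ndarray) -> np.ndarray:
        rows = np.atleast_2d(np.asarray(rows, dtype=float))
        if rows.shape[1] != self.coefficients.size:
            raise ValueError(
                f"descriptor rows have {rows.shape[1]} columns, "
                f"model expects {self.coefficients.size}")
        return rows @ self.coefficients + self.intercept

    def coefficients_for_block(self, kind: str) -> tuple[np.ndarray, np.ndarray]:
        """(lattice point indices, coefficients on the raw field scale)."""
        if kind not in self.block_labels:
            return np.array([], dtype=int), np.array([])
        bi = self.block_labels.index(kind)
        cols = np.nonzero(self.column_block == bi)[0]
        raw = self.coefficients[cols] * self.scale_factors[kind]
        return self.column_point[cols], raw

    def to_json(self) -> str:
        d = {
            "n_components": self.n_components,
            "coefficients": self.coefficients.tolist(),
            "intercept": self.intercept,
            "r2": self.r2, "see": self.see, "f_stat": self.f_stat,
            "q2": self.q2, "q2_by_components": self.q2_by_components,
            "field_contributions": self.field_contributions,
            "block_labels": self.block_labels,
            "column_block": None if self.column_block is None else self.column_block.tolist(),
            "column_point": None if self.column_point is None else self.column_point.tolist(),
            "scale_factors": self.scale_factors,
            "masks": {k: [bool(b) for b in v] for k, v in self.masks.items()},
            "column_fills": self.column_fills,
            "grid": self.grid,
            "min_sigma": self.min_sigma,
        }
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PLSModel":
        d = json.loads(text)
        return cls(
            n_components=d["n_components"],
            coefficients=np.asarray(d["coefficients"], dtype=float),
            intercept=float(d["intercept"]),
            r2=d["r2"], see=d["see"], f_stat=d["f_stat"],
            q2=d.get("q2"), q2_by_components=d.get("q2_by_components"),
            field_contributions=d.get("field_contributions", {}),
            block_labels=d.get("block_labels", []),
            column_block=None if d.get("column_block") is None
            else np.asarray(d["column_block"], dtype=int),
            column_point=None if d.get("column_point") is None
            else np.asarray(d["column_point"], dtype=int),
            scale_factors=d.get("scale_factors", {}),
            masks=d.get("masks", {}),
            column_fills=d.get("column_fills", {}),
            grid=d.get("grid"),
            min_sigma=d.get("min_sigma"),
        )


def fit_pls(
    X: np.ndarray,
    y: np.ndarray,
    c: int,
    block_columns: dict[str, np.ndarray] | None = None,
) -> PLSModel:
    """Fit a ``c``-component PLS model (no cross-validation).

    r2 is the non-cross-validated squared correlation of fit,
    SEE = sqrt(RSS / (n - c - 1)) and F = [r2/(1-r2)] * [(n-c-1)/c]. Field
    contributions (optional ``block_columns`` mapping label -> column index
    array) are sum_j |beta_j| * sd(X_j) per block, normalized to 1.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < 3:
        raise ValueError("need at least 3 training samples")
    if c < 1:
        raise ValueError("need at least one component")
    if c >= n - 1:
        raise ValueError(f"c={c} too large for n={n} (need c <= n-2)")
    if np.std(y) == 0:
        raise ValueError("y has zero variance")
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    W, P, Q = nipals_components(X - x_mean, y - y_mean, c)
    beta = pls_coefficients(W, P, Q)
    intercept = float(y_mean - x_mean @ beta)
    y_hat = X @ beta + intercept
    rss = float(((y - y_hat) ** 2).sum())
    tss = float(((y - y_mean) ** 2).sum())
    r2 = 1.0 - rss / tss
    see = float(np.sqrt(rss / (n - c - 1)))
    f_stat = float((r2 / (1.0 - r2)) * ((n - c - 1) / c)) if r2 < 1.0 else np.inf

    contributions: dict[str, float] = {}
    if block_columns:
        sd = X.std(axis=0)
        raw = {label: float(np.sum(np.abs(beta[cols]) * sd[cols]))
               for label, cols in block_columns.items()}
        total = sum(raw.values())
        if total > 0:
            contributions = {k: v / total for k, v in raw.items()}

    return PLSModel(n_components=c, coefficients=beta, intercept=intercept,
                    r2=r2, see=see, f_stat=f_stat,
                    field_contributions=contributions)


def fit_from_descriptors(desc: DescriptorMatrix, y: np.ndarray, c: int,
                         grid: dict | None = None) -> PLSModel:
    """Fit on an assembled DescriptorMatrix, carrying block metadata so the
    model can be serialized, used for prediction and contoured."""
    block_columns = {label: desc.columns_of(label) for label in desc.block_labels
                     if desc.columns_of(label).size}
    model = fit_pls(desc.values, y, c, block_columns=block_columns)
    model.block_labels = desc.block_labels
    model.column_block = desc.column_block
    model.column_point = desc.column_point
    model.scale_factors = desc.scale_factors
    model.masks = {k: [bool(b) for b in v] for k, v in desc.masks.items()}
    model.grid = grid
    model.min_sigma = desc.min_sigma
    return model


def predict(model: PLSModel, descriptor_rows: np.ndarray) -> np.ndarray:
    """Deterministic linear evaluation of a fitted model."""
    return model.predict(descriptor_rows)
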