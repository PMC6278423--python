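"""Observed/predicted activity tables."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

ROLE_TRAIN = "train"
ROLE_TEST = "test"


@dataclass
class PredictionTable:
    ids: list[str]
    y_obs: np.ndarray
    y_pred: np.ndarray
    roles: list[str]

    def __post_init__(self) -> None:
        self.y_obs = np.asarray(self.y_obs, dtype=float)
        self.y_pred = np.asarray(self.y_pred, dtype=float)
        n = len(self.ids)
        if not (len(self.y_obs) == len(self.y_pred) == len(self.roles) == n):
            raise ValueError("prediction table columns differ in length")
        if len(set(self.ids)) != n:
            raise ValueError("duplicate ids in prediction table")
        bad = set(self.roles) - {ROLE_TRAIN, ROLE_TEST}
        if bad:
            raise ValueError(f"unknown roles: {sorted(bad)}")

    def _sel(self, role: str) -> np.ndarray:
        return np.array([r == role for r in self.roles])

    @property
    def train_obs(self) -> np.ndarray:
        return self.y_obs[self._sel(ROLE_TRAIN)]

    @property
    def train_pred(self) -> np.ndarray:
        return self.y_pred[self._sel(ROLE_TRAIN)]

    @property
    def test_obs(self) -> np.ndarray:
        return self.y_obs[self._sel(ROLE_TEST)]

    @property
    def test_pred(self) -> np.ndarray:
        return self.y_pred[self._sel(ROLE_TEST)]

    @property
    def residuals(self) -> np.ndarray:
        return self.y_obs - self.y_pred

    @property
    def training_range(self) -> float:
        tr = self.train_obs
        if tr.size == 0:
            raise ValueError("no training rows; training range undefined")
        return float(tr.max() - tr.min())

    def subset(self, role: str) -> "PredictionTable":
        sel = self._sel(role)
        return PredictionTable(
            ids=[i for i, s in zip(self.ids, sel) if s],
            y_obs=self.y_obs[sel], y_pred=self.y_pred[sel],
            roles=[r for r, s in zip(self.roles, sel) if s])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"id": self.ids, "y_obs": self.y_obs,
                             "y_pred": self.y_pred, "role": self.roles})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PredictionTable":
        cols = {c.strip().lower() for c in df.columns}
        missing = {"id", "y_obs", "y_pred", "role"} - cols
        if missing:
            raise ValueError(f"prediction table missing columns: {sorted(missing)}")
        df = df.rename(columns={c: c.strip().lower() for c in df.columns})
        return cls(ids=[str(i) for i in df["id"]],
                   y_obs=df["y_obs"].to_numpy(dtype=float),
                   y_pred=df["y_pred"].to_numpy(dtype=float),
                   roles=[str(r).strip().lower() for r in df["role"]])

    @classmethod
    def read(cls, path: str) -> "PredictionTable":
        return cls.from_frame(pd.read_csv(path, sep=None, engine="python"))

    def write(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)
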