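"""Packaged reference prediction tables (35 compounds, 28 train / 7 test)."""

from __future__ import annotations

from importlib import resources

import pandas as pd

from qsar3d.validation.table import PredictionTable

MODEL_COLUMNS = {
    "comfa": "comfa",
    "comsia": "comsia",
    "topomercomfa": "topomer",
    "topomer": "topomer",
}

FIXTURE_MODELS = ("CoMFA", "CoMSIA", "TopomerCoMFA")


def fixture_frame() -> pd.DataFrame:
    path = resources.files("qsar3d.data").joinpath("prediction_table.csv")
    with path.open() as fh:
        return pd.read_csv(fh, dtype={"id": str})


def paper_fixture(model_name: str) -> PredictionTable:
    """Observed/predicted table for one of the three reference models.

    Residuals are recomputed from the stored observed and predicted values
    (the authoritative columns) rather than shipped separately.
    """
    key = model_name.replace(" ", "").replace("_", "").lower()
    if key not in MODEL_COLUMNS:
        raise ValueError(
            f"unknown model {model_name!r}; choose from {FIXTURE_MODELS}")
    df = fixture_frame()
    col = MODEL_COLUMNS[key]
    return PredictionTable(ids=df["id"].tolist(),
                           y_obs=df["pic50"].to_numpy(),
                           y_pred=df[col].to_numpy(),
                           roles=df["role"].tolist())
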