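"""External-validation statistics for observed/predicted activity tables.

Two details follow the arithmetic that the reference outputs actually obey
rather than the more common literature conventions, both switchable:

* the through-origin determination coefficients use the "as-printed" form
  R0^2 = 1 - sum((Yp - k*Yp)^2) / sum((Yp - mean(Yp))^2) (and the primed
  analogue on observed values); ``gt_standard=True`` computes the classical
  Golbraikh-Tropsha definitions instead;
* the penalized external metric restores the radical,
  rm^2 = R2 * (1 - sqrt(|R2 - R0^2|));
* sigma of the absolute errors uses the population divisor n.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .table import PredictionTable


def r2pred(table: PredictionTable) -> dict[str, float]:
    """Predictive r^2 of the test set against the training-mean reference.

    r2pred = (SD - PRESS) / SD with PRESS the test-set squared residual sum
    and SD the squared deviation of test observations from the mean
    *training* activity.
    """
    yo, yp = table.test_obs, table.test_pred
    if yo.size < 1:
        raise ValueError("need at least one test row")
    tr = table.train_obs
    if tr.size < 1:
        raise ValueError("need at least one training row")
    sd = float(((yo - tr.mean()) ** 2).sum())
    if sd == 0:
        raise ValueError("degenerate test set: zero deviation from training mean")
    press = float(((yo - yp) ** 2).sum())
    return {"SD": sd, "PRESS": press, "r2pred": (sd - press) / sd}


def origin_regression(table: PredictionTable, gt_standard: bool = False) -> dict[str, float]:
    """Through-origin slopes and determination coefficients over test rows.

    Returns R2test (squared Pearson with intercept), k, k' and R0^2/R'0^2.
    """
    yo, yp = table.test_obs, table.test_pred
    if yo.size < 3:
        raise ValueError("need at least 3 test rows")
    so, sp = yo.std(), yp.std()
    if so == 0 or sp == 0:
        raise ValueError("zero variance in observed or predicted test values")
    r2test = float(np.corrcoef(yo, yp)[0, 1] ** 2)
    sum_op = float((yo * yp).sum())
    denom_p = float((yp ** 2).sum())
    denom_o = float((yo ** 2).sum())
    if denom_p == 0 or denom_o == 0:
        raise ValueError("zero denominator in through-origin slope")
    k = sum_op / denom_p
    k_prime = sum_op / denom_o
    if gt_standard:
        # classical definitions: residual of y about the origin line in x
        r02 = 1.0 - float(((yo - k * yp) ** 2).sum()) / float(((yo - yo.mean()) ** 2).sum())
        r02_prime = 1.0 - float(((yp - k_prime * yo) ** 2).sum()) / float(((yp - yp.mean()) ** 2).sum())
    else:
        r02 = 1.0 - float(((yp - k * yp) ** 2).sum()) / float(((yp - yp.mean()) ** 2).sum())
        r02_prime = 1.0 - float(((yo - k_prime * yo) ** 2).sum()) / float(((yo - yo.mean()) ** 2).sum())
    return {"R2test": r2test, "k": k, "k_prime": k_prime,
            "R02": r02, "R02_prime": r02_prime}


def rm2_metrics(r2test: float, r02: float, r02_prime: float) -> dict[str, float]:
    """Penalized external metrics (radical form) and their summary pair."""
    rm2 = r2test * (1.0 - np.sqrt(abs(r2test - r02)))
    rm2_prime = r2test * (1.0 - np.sqrt(abs(r2test - r02_prime)))
    return {"rm2": float(rm2), "rm2_prime": float(rm2_prime),
            "rm2_avg": float((rm2 + rm2_prime) / 2.0),
            "delta_rm2": float(abs(rm2 - rm2_prime))}


def mae_criteria(table: PredictionTable, which: str = "test") -> dict[str, float | bool]:
    """Mean absolute error, population sigma of absolute errors, and the
    two range-based acceptance rules for the chosen set.

    Rules: MAE <= 0.1 * training range and MAE + 3*sigma <= 0.2 * training
    range.
    """
    sub = table.subset(which)
    if len(sub.ids) < 2:
        raise ValueError(f"need at least 2 {which} rows for MAE criteria")
    abs_err = np.abs(sub.y_obs - sub.y_pred)
    mae = float(abs_err.mean())
    sigma = float(abs_err.std())    # population divisor n
    rng = table.training_range
    return {"MAE": mae, "sigma": sigma, "training_range": rng,
            "mae_rule": mae <= 0.1 * rng,
            "mae_sigma_rule": mae + 3.0 * sigma <= 0.2 * rng,
            "passes": (mae <= 0.1 * rng) and (mae + 3.0 * sigma <= 0.2 * rng)}


def gt_criteria(report: dict[str, float], q2: float) -> dict[str, bool]:
    """The six published external-acceptance inequalities plus their
    conjunction.

    ``report`` must contain R2test, k, k_prime, R02, R02_prime.
    """
    r2t = report["R2test"]
    checks = {
        "q2_gt_0.5": q2 > 0.500,
        "r2test_gt_0.6": r2t > 0.600,
        "r2_r02_ratio_lt_0.1": (r2t - report["R02"]) / r2t < 0.100,
        "r2_r02prime_ratio_lt_0.1": (r2t - report["R02_prime"]) / r2t < 0.100,
        "k_in_0.85_1.15": 0.850 <= report["k"] <= 1.150,
        "k_prime_in_0.85_1.15": 0.850 <= report["k_prime"] <= 1.150,
    }
    checks["overall"] = all(checks.values())
    return checks


def rm2_overall(loo_train_table: PredictionTable,
                test_table: PredictionTable,
                gt_standard: bool = False) -> dict[str, float]:
    """rm^2 battery over the union of LOO-predicted training rows and
    model-predicted test rows."""
    if not loo_train_table.ids or not test_table.ids:
        raise ValueError("both training and test tables must be non-empty")
    collision = set(loo_train_table.ids) & set(test_table.ids)
    if collision:
        raise ValueError(f"id collision between tables: {sorted(collision)}")
    union = PredictionTable(
        ids=list(loo_train_table.ids) + list(test_table.ids),
        y_obs=np.concatenate([loo_train_table.y_obs, test_table.y_obs]),
        y_pred=np.concatenate([loo_train_table.y_pred, test_table.y_pred]),
        roles=["test"] * (len(loo_train_table.ids) + len(test_table.ids)))
    reg = origin_regression(union, gt_standard=gt_standard)
    return rm2_metrics(reg["R2test"], reg["R02"], reg["R02_prime"])


@dataclass
class ValidationReport:
    """The full external-validation statistic set with criteria flags."""
    stats: dict[str, float] = field(default_factory=dict)
    criteria: dict[str, bool] = field(default_factory=dict)
    q2: float | None = None

    def rounded(self, ndigits: int = 3) -> dict[str, float]:
        """Display rounding: half-up at ``ndigits`` decimals."""
        out = {}
        for key, val in self.stats.items():
            shift = 10 ** ndigits
            out[key] = np.floor(abs(val) * shift + 0.5) / shift * np.sign(val)
        return out

    def to_dict(self) -> dict:
        return {"stats": self.stats, "criteria": self.criteria, "q2": self.q2}


def validate_table(table: PredictionTable, q2: float | None = None,
                   gt_standard: bool = False) -> ValidationReport:
    """Run the whole battery on one observed/predicted table."""
    if len(table.subset("test").ids) < 2:
        raise ValueError("need at least 2 test rows for validation")
    rp = r2pred(table)
    reg = origin_regression(table, gt_standard=gt_standard)
    rm = rm2_metrics(reg["R2test"], reg["R02"], reg["R02_prime"])
    mae_test = mae_criteria(table, "test")
    mae_train = mae_criteria(table, "train")
    r2t = reg["R2test"]
    stats = {
        "r2pred": rp["r2pred"],
        "R2test": r2t,
        "R02": reg["R02"],
        "R02_prime": reg["R02_prime"],
        "r2_r02_ratio": (r2t - reg["R02"]) / r2t,
        "r2_r02prime_ratio": (r2t - reg["R02_prime"]) / r2t,
        "k": reg["k"],
        "k_prime": reg["k_prime"],
        "MAE_test": mae_test["MAE"],
        "MAE_train": mae_train["MAE"],
        "sigma_test": mae_test["sigma"],
        "sigma_train": mae_train["sigma"],
        "rm2": rm["rm2"],
        "rm2_prime": rm["rm2_prime"],
        "rm2_avg": rm["rm2_avg"],
        "delta_rm2": rm["delta_rm2"],
        "training_range": table.training_range,
    }
    criteria = {
        "rm2_avg_gt_0.5": rm["rm2_avg"] > 0.500,
        "delta_rm2_lt_0.2": rm["delta_rm2"] < 0.200,
        "mae_test_rules": bool(mae_test["passes"]),
        "mae_train_rules": bool(mae_train["passes"]),
    }
    report = ValidationReport(stats=stats, criteria=criteria, q2=q2)
    if q2 is not None:
        report.criteria.update(gt_criteria(reg, q2))
    return report
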