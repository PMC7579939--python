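"""Cross-validated performance metrics and subgroup accuracy tables.

The prediction harness mirrors common practice in clinical biometry studies:
5-fold cross-validation with every record predicted exactly once out-of-fold,
five indices (R², Pearson R, RMSE, MAE, MSE) computed on the pooled
out-of-fold predictions, and per-subgroup error summaries (SER, K-mean and
age-by-sex strata) with paired t-tests of predicted versus measured axial
length.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .features import FeatureMap
from .model import ALGrowthModel, ALGrowthResults, RobustConfig

#: Presentation order: traditional least squares first, then the alternatives.
METHOD_ORDER = ["ols", "robust", "svr_linear", "svr_quadratic", "svr_cubic", "bagged_trees"]


@dataclass(frozen=True)
class MetricSet:
    """The five regression indices for one model evaluation.

    By construction ``rmse == sqrt(mse)`` and ``mae <= rmse``.  ``r2`` and
    ``r`` are NaN (undefined) when the measured values have zero variance.
    """

    r2: float
    r: float
    rmse: float
    mae: float
    mse: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def compute_metrics(true_al: Sequence[float], pred_al: Sequence[float]) -> MetricSet:
    y = np.asarray(true_al, dtype=float)
    p = np.asarray(pred_al, dtype=float)
    if y.shape != p.shape or y.size == 0:
        raise ValueError("true and predicted vectors must be equal-length and non-empty")
    err = p - y
    mae = float(np.mean(np.abs(err)))
    mse = float(np.mean(err**2))
    rmse = float(np.sqrt(mse))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = float("nan")
        r = float("nan")
    else:
        r2 = 1.0 - float(np.sum(err**2)) / ss_tot
        r = float(stats.pearsonr(y, p).statistic) if np.std(p) > 0 else float("nan")
    return MetricSet(r2=r2, r=r, rmse=rmse, mae=mae, mse=mse)


def kfold_split(n: int, k: int = 5, seed: int = 0) -> np.ndarray:
    """Random k-fold assignment: fold index per record, sizes differing by ≤ 1."""
    if k < 2:
        raise ValueError("need at least 2 folds")
    if n < k:
        raise ValueError(f"cannot split {n} records into {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    assignment = np.empty(n, dtype=int)
    for fold, idx in enumerate(np.array_split(perm, k)):
        assignment[idx] = fold
    return assignment


def cross_validate(
    records: pd.DataFrame,
    methods: Sequence[str] = tuple(METHOD_ORDER),
    feature_map: FeatureMap | None = None,
    k: int = 5,
    seed: int = 0,
    robust_config: RobustConfig | None = None,
    feature_maps: dict[str, FeatureMap] | None = None,
    per_fold: bool = False,
) -> pd.DataFrame:
    """Out-of-fold metrics per method, in the order given.

    Every method sees the same fold assignment.  Each fold's model is trained
    on the other k−1 folds and predicts the held-out fold; the k held-out
    prediction vectors are pooled into one vector of length n and a single
    metric set per method is computed on it (the presentation used in
    algorithm-comparison tables).  ``per_fold=True`` returns fold-level
    metrics instead, for readers who prefer fold-averaged summaries.  A
    method whose fit raises is reported as a NaN row with the message in the
    ``error`` column; the other methods continue.
    """
    records = records.reset_index(drop=True)
    folds = kfold_split(len(records), k=k, seed=seed)
    rows: list[dict] = []
    fold_rows: list[dict] = []
    for tag in methods:
        fm = (feature_maps or {}).get(tag, feature_map)
        pooled = np.full(len(records), np.nan)
        try:
            for fold in range(k):
                train = records.loc[folds != fold]
                test = records.loc[folds == fold]
                res = ALGrowthModel(train, fm, method=tag).fit(robust_config=robust_config)
                pooled[folds == fold] = np.asarray(res.predict(test))
                if per_fold:
                    fold_rows.append(
                        {"method": tag, "fold": fold, "n": len(test),
                         **compute_metrics(test["al"], pooled[folds == fold]).as_dict()}
                    )
        except Exception as exc:
            rows.append({"method": tag, "r2": np.nan, "r": np.nan, "rmse": np.nan,
                         "mae": np.nan, "mse": np.nan, "error": str(exc)})
            continue
        rows.append({"method": tag, **compute_metrics(records["al"], pooled).as_dict(),
                     "error": ""})
    if per_fold:
        return pd.DataFrame(fold_rows).set_index(["method", "fold"])
    return pd.DataFrame(rows).set_index("method")


# -- subgroup accuracy ------------------------------------------------------

#: Stratum families.  Interval edges go to the more-myopic SER bin (−3.00 D
#: falls in the middle bin) and the K-mean edges are inclusive in the middle
#: bin; age strata are crossed with sex.
def _subgroup_masks(df: pd.DataFrame) -> list[tuple[str, str, pd.Series]]:
    ser, k, age, sex = df["ser"], df["k_mean"], df["age"], df["sex"]
    groups: list[tuple[str, str, pd.Series]] = [
        ("ser", "0 to -3.00", (ser > -3.0) & (ser <= 0.0)),
        ("ser", "-3.00 to -6.00", (ser > -6.0) & (ser <= -3.0)),
        ("ser", "< -6.00", ser <= -6.0),
        ("k_mean", "< 42.00", k < 42.0),
        ("k_mean", "42.00 to 44.00", (k >= 42.0) & (k <= 44.0)),
        ("k_mean", "> 44.00", k > 44.0),
    ]
    age_bins = [("6-10", (age >= 6.0) & (age < 11.0)),
                ("11-14", (age >= 11.0) & (age < 15.0)),
                ("15-18", (age >= 15.0) & (age <= 18.0))]
    for label, mask in age_bins:
        for sex_code, sex_label in ((1.0, "M"), (0.0, "F")):
            groups.append(("age_sex", f"{label} {sex_label}", mask & (sex == sex_code)))
    return groups


def subgroup_table(records: pd.DataFrame, model: ALGrowthResults) -> pd.DataFrame:
    """Per-stratum accuracy rows: n, %, mean predicted/measured AL, error, CIs, p.

    ``ci_error`` is the t-based 95% confidence interval of the per-eye error
    mean.  ``ci_al`` is a population range interval, mean ± 1.96·SD of the
    predicted AL — it describes the spread of eyes in the stratum, not the
    precision of its mean.  Empty strata yield an ``n = 0`` row flagged
    ``empty`` with NaN statistics.
    """
    records = records.reset_index(drop=True)
    pred = np.asarray(model.predict(records))
    true = records["al"].to_numpy(dtype=float)
    total = len(records)
    rows = []
    for family, label, mask in _subgroup_masks(records):
        m = mask.to_numpy()
        n = int(m.sum())
        if n == 0:
            rows.append({"family": family, "label": label, "n": 0, "pct": 0.0,
                         "mean_pred": np.nan, "mean_true": np.nan, "error": np.nan,
                         "ci_error_lo": np.nan, "ci_error_hi": np.nan,
                         "ci_al_lo": np.nan, "ci_al_hi": np.nan,
                         "p_value": np.nan, "flag": "empty"})
            continue
        p_g, t_g = pred[m], true[m]
        err = p_g - t_g
        mean_err = float(err.mean())
        if n > 1 and np.std(err, ddof=1) > 0:
            lo, hi = stats.t.interval(0.95, n - 1, loc=mean_err,
                                      scale=stats.sem(err))
            p_val = float(stats.ttest_rel(p_g, t_g).pvalue)
        else:
            # Zero-variance differences: identical vectors get p = 1 by
            # convention; a constant nonzero offset is certain, p = 0.
            lo = hi = mean_err
            p_val = 1.0 if np.allclose(err, 0.0) else 0.0
        sd_pred = float(np.std(p_g, ddof=1)) if n > 1 else 0.0
        rows.append({
            "family": family, "label": label, "n": n, "pct": 100.0 * n / total,
            "mean_pred": float(p_g.mean()), "mean_true": float(t_g.mean()),
            "error": mean_err, "ci_error_lo": float(lo), "ci_error_hi": float(hi),
            "ci_al_lo": float(p_g.mean() - 1.96 * sd_pred),
            "ci_al_hi": float(p_g.mean() + 1.96 * sd_pred),
            "p_value": p_val, "flag": "",
        })
    return pd.DataFrame(rows)
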