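"""Validation statistics for one-variable QSAR models.

All statistics follow the conventions of the Monte Carlo correlation-weight
modeling literature:

* ``R²`` is the squared Pearson correlation between observed and predicted
  values (not 1 − RSS/TSS), consistent with the F-ratio reconstruction
  F = R²(n−2)/(1−R²) for a one-predictor model.
* ``Q²`` is the leave-one-out cross-validated determination coefficient of
  the one-variable least-squares fit, 1 − PRESS/Σ(y−ȳ)².
* ``Q²F3`` is the external-predictivity criterion
  1 − [Σ(y_ext−ŷ_ext)²/n_ext] / [Σ(y_tr−ȳ_tr)²/n_tr], anchored on the
  active-training set's variance.
* ``CCC`` is Lin's concordance correlation coefficient with population
  (1/n) moments.
* ``IIC``, the index of ideality of correlation, penalizes the correlation
  coefficient by residual-sign asymmetry:
  r(y, ŷ) · min(MAE⁻, MAE⁺)/max(MAE⁻, MAE⁺), where MAE⁻/MAE⁺ are mean
  absolute residuals over negative / non-negative residuals (y−ŷ).  If
  either class is empty the ratio — hence the IIC — is defined as 0.
* ``CII``, the correlation intensity index, is 1 − Σ_k max(0, R²₋ₖ − R²):
  one minus the summed "protests", the R² gains obtained by refitting with
  single compounds excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "UndefinedMetricError",
    "MetricReport",
    "r2",
    "q2_loo",
    "q2_f3",
    "ccc",
    "iic",
    "cii",
    "f_ratio",
    "mae",
    "rmse",
    "subset_report",
    "write_metrics_tsv",
]


class UndefinedMetricError(ValueError):
    """Raised when a statistic is undefined for the given input."""


def _asarray(v) -> np.ndarray:
    a = np.asarray(v, dtype=float)
    if a.ndim != 1:
        raise ValueError("expected a 1-d vector")
    return a


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) != len(y):
        raise ValueError("length mismatch")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(xc @ xc)
    sy = float(yc @ yc)
    if sx <= 0.0 or sy <= 0.0:
        raise UndefinedMetricError("correlation undefined for a constant vector")
    return float(xc @ yc) / math.sqrt(sx * sy)


def r2(y, yhat) -> float:
    """Squared Pearson correlation between observed and predicted values."""
    y, yhat = _asarray(y), _asarray(yhat)
    if len(y) < 3:
        raise UndefinedMetricError("r2 requires n >= 3")
    return _pearson(y, yhat) ** 2


def q2_loo(x, y) -> float:
    """Leave-one-out Q² of the one-variable OLS of y on x: 1 − PRESS/Σ(y−ȳ)²."""
    x, y = _asarray(x), _asarray(y)
    n = len(x)
    if n < 4:
        raise UndefinedMetricError("q2_loo requires n >= 4")
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx <= 0.0:
        raise UndefinedMetricError("q2_loo undefined for a constant descriptor")
    c1 = float(xc @ (y - y.mean())) / sxx
    c0 = float(y.mean() - c1 * x.mean())
    resid = y - (c0 + c1 * x)
    leverage = 1.0 / n + xc**2 / sxx
    press = float(np.sum((resid / (1.0 - leverage)) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss <= 0.0:
        raise UndefinedMetricError("q2_loo undefined for constant y")
    return 1.0 - press / tss


def q2_f3(y_ext, yhat_ext, y_train) -> float:
    """External predictivity anchored on the training-set variance."""
    y_ext, yhat_ext, y_train = _asarray(y_ext), _asarray(yhat_ext), _asarray(y_train)
    if len(y_ext) < 2:
        raise UndefinedMetricError("q2_f3 requires n_ext >= 2")
    sst = float(np.sum((y_train - y_train.mean()) ** 2))
    if sst <= 0.0:
        raise UndefinedMetricError("q2_f3 undefined for constant training values")
    sse = float(np.sum((y_ext - yhat_ext) ** 2))
    return 1.0 - (sse / len(y_ext)) / (sst / len(y_train))


def ccc(y, yhat) -> float:
    """Lin's concordance correlation coefficient (population moments)."""
    y, yhat = _asarray(y), _asarray(yhat)
    my, mp = y.mean(), yhat.mean()
    vy = float(np.mean((y - my) ** 2))
    vp = float(np.mean((yhat - mp) ** 2))
    cov = float(np.mean((y - my) * (yhat - mp)))
    denom = vy + vp + (my - mp) ** 2
    if denom <= 0.0:
        raise UndefinedMetricError("ccc undefined for two identical constants")
    return 2.0 * cov / denom


def iic(y, yhat) -> float:
    """Index of ideality of correlation.

    Returns 0 when all residuals share one sign (the asymmetry ratio is
    taken as 0 by convention), which includes the degenerate case of a
    perfect fit.
    """
    y, yhat = _asarray(y), _asarray(yhat)
    resid = y - yhat
    neg = np.abs(resid[resid < 0])
    pos = np.abs(resid[resid >= 0])
    if len(neg) == 0 or len(pos) == 0:
        return 0.0
    mae_neg = float(neg.mean())
    mae_pos = float(pos.mean())
    hi = max(mae_neg, mae_pos)
    if hi == 0.0:
        return 0.0
    ratio = min(mae_neg, mae_pos) / hi
    return _pearson(y, yhat) * ratio


def cii(x, y) -> float:
    """Correlation intensity index of the one-variable fit of y on x.

    1 − Σ_k max(0, R²₋ₖ − R²) where R²₋ₖ is the squared correlation of the
    refit excluding compound k.  For a one-variable OLS the refit R² equals
    the squared Pearson correlation of the remaining (x, y) pairs, computed
    here by downdating the moment sums.
    """
    x, y = _asarray(x), _asarray(y)
    n = len(x)
    if n < 5:
        raise UndefinedMetricError("cii requires n >= 5")
    r2_full = _pearson(x, y) ** 2
    sx, sy = float(x.sum()), float(y.sum())
    sxx, syy, sxy = float(x @ x), float(y @ y), float(x @ y)
    protest_sum = 0.0
    m = n - 1
    for k in range(n):
        tx, ty = sx - x[k], sy - y[k]
        txx = sxx - x[k] ** 2
        tyy = syy - y[k] ** 2
        txy = sxy - x[k] * y[k]
        vx = txx - tx * tx / m
        vy = tyy - ty * ty / m
        if vx <= 0.0 or vy <= 0.0:
            continue
        r2_k = (txy - tx * ty / m) ** 2 / (vx * vy)
        protest_sum += max(0.0, r2_k - r2_full)
    return 1.0 - protest_sum


def f_ratio(r2_value: float, n: int) -> float:
    """Fisher F-ratio of a one-predictor regression: R²(n−2)/(1−R²)."""
    if not 0.0 <= r2_value <= 1.0:
        raise ValueError(f"r2 must be in [0, 1], got {r2_value}")
    if r2_value >= 1.0:
        return math.inf
    return r2_value * (n - 2) / (1.0 - r2_value)


def mae(y, yhat) -> float:
    y, yhat = _asarray(y), _asarray(yhat)
    return float(np.mean(np.abs(y - yhat)))


def rmse(y, yhat) -> float:
    y, yhat = _asarray(y), _asarray(yhat)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


@dataclass
class MetricReport:
    """One row of a model-statistics table for a single subset."""

    set_name: str
    n: int
    r2: float
    ccc: float
    iic: float
    mae: float
    rmse: float
    f: float
    q2: float | None = None
    q2f3: float | None = None
    cii: float | None = None


def subset_report(
    set_name: str,
    y,
    yhat,
    dcw=None,
    y_train=None,
) -> MetricReport:
    """Assemble the statistics row for one subset.

    ``dcw`` enables the leave-one-out Q² (internal subsets); ``y_train``
    enables Q²F3 (external subsets: calibration and validation).
    """
    y, yhat = _asarray(y), _asarray(yhat)
    report = MetricReport(
        set_name=set_name,
        n=len(y),
        r2=r2(y, yhat),
        ccc=ccc(y, yhat),
        iic=iic(y, yhat),
        mae=mae(y, yhat),
        rmse=rmse(y, yhat),
        f=f_ratio(r2(y, yhat), len(y)),
    )
    if dcw is not None:
        report.q2 = q2_loo(dcw, y)
        if len(y) >= 5:
            report.cii = cii(dcw, y)
    if y_train is not None:
        report.q2f3 = q2_f3(y, yhat, y_train)
    return report


def write_metrics_tsv(reports: list[MetricReport], path) -> None:
    """Write rows in the conventional column order of model-statistics tables."""
    cols = ["set", "n", "R2", "CCC", "IIC", "Q2", "Q2F3", "RMSE", "MAE", "F"]

    def fmt(v):
        return "" if v is None else f"{v:.4f}"

    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in reports:
            fh.write(
                "\t".join(
                    [
                        r.set_name,
                        str(r.n),
                        fmt(r.r2),
                        fmt(r.ccc),
                        fmt(r.iic),
                        fmt(r.q2),
                        fmt(r.q2f3),
                        fmt(r.rmse),
                        fmt(r.mae),
                        fmt(r.f),
                    ]
                )
                + "\n"
            )
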