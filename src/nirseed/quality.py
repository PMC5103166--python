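"""Calibration and validation statistics for NIRS predictive equations.

All errors are in concentration units (% dry weight):

* SEC  — standard error of calibration, sqrt(SSE / (n - k - 1)) with k the
  number of PLS factors (degrees of freedom spent on the model).
* SECV — standard error of cross-validation, sqrt(SSE / n) over the
  leave-one-out residuals.
* SEP  — standard error of prediction for the external validation set.  The
  default convention is bias-corrected (the SD of the validation residuals,
  with the mean residual reported separately as bias); the RMSEP convention
  (no bias correction) is available via ``convention="rmsep"``.
* RPD  — ratio of performance deviation: the calibration-set reference SD
  divided by SEP.  Interpretation bands follow AACC Method 39-00.01:
  RPD >= 2.5 screening, >= 5 quality control, >= 8 process control.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CalibrationReport",
    "sec",
    "secv",
    "sep",
    "r_squared",
    "rpd",
    "interpret_rpd",
    "build_report",
    "RPD_BANDS",
]

RPD_BANDS = (
    (8.0, "process-control"),
    (5.0, "quality-control"),
    (2.5, "screening"),
)


def sec(residuals: np.ndarray, n_factors: int) -> float:
    """Standard error of calibration: sqrt(sum(e^2) / (n - k - 1))."""
    e = np.asarray(residuals, float)
    n, k = e.size, int(n_factors)
    if n <= k + 1:
        raise ValueError(f"SEC needs n > k + 1 (n={n}, k={k})")
    return float(np.sqrt((e**2).sum() / (n - k - 1)))


def secv(loo_residuals: np.ndarray) -> float:
    """Standard error of cross-validation: sqrt(sum(e^2) / n)."""
    e = np.asarray(loo_residuals, float)
    if e.size < 2:
        raise ValueError("SECV needs n >= 2 residuals")
    return float(np.sqrt((e**2).mean()))


def sep(validation_residuals: np.ndarray, convention: str = "bias-corrected"):
    """Standard error of prediction; returns (sep, bias).

    bias-corrected: sqrt(sum((e - mean(e))^2) / (n - 1)); rmsep: sqrt(mean e^2).
    """
    e = np.asarray(validation_residuals, float)
    if e.size < 2:
        raise ValueError("SEP needs n >= 2 residuals")
    bias = float(e.mean())
    if convention == "bias-corrected":
        return float(np.sqrt(((e - bias) ** 2).sum() / (e.size - 1))), bias
    if convention == "rmsep":
        return float(np.sqrt((e**2).mean())), bias
    raise ValueError(f"unknown SEP convention {convention!r}")


def r_squared(predicted, reference, convention: str = "pearson") -> float:
    """Coefficient of determination between predicted and reference values.

    Default is the squared Pearson correlation (chemometrics convention);
    ``convention="explained"`` gives 1 - SSE/SST instead.
    """
    p = np.asarray(predicted, float)
    r = np.asarray(reference, float)
    if p.size < 3:
        raise ValueError("r^2 needs n >= 3")
    if np.std(r) == 0 or (convention == "pearson" and np.std(p) == 0):
        raise ValueError("constant input — r^2 undefined")
    if convention == "pearson":
        return float(np.corrcoef(p, r)[0, 1] ** 2)
    if convention == "explained":
        return float(1.0 - ((r - p) ** 2).sum() / ((r - r.mean()) ** 2).sum())
    raise ValueError(f"unknown r^2 convention {convention!r}")


def rpd(sd_reference: float, sep_value: float) -> float:
    """Ratio of performance deviation: calibration-set reference SD / SEP."""
    if sep_value <= 0:
        raise ValueError("RPD requires SEP > 0")
    return float(sd_reference) / float(sep_value)


def interpret_rpd(value: float) -> str:
    """Map an RPD value onto its usefulness band (half-open upward)."""
    if value <= 0:
        raise ValueError("RPD must be positive")
    for threshold, label in RPD_BANDS:
        if value >= threshold:
            return label
    return "below-screening"


@dataclass
class CalibrationReport:
    """One calibration-summary row for one seed component."""

    component: str
    n_cal: int
    mean_cal: float
    range_cal: tuple[float, float]
    sd_cal: float
    n_factors: int
    sec: float
    r2_cal: float
    secv: float
    r2_cv: float
    n_val: int | None = None
    mean_val: float | None = None
    sd_val: float | None = None
    sep: float | None = None
    bias_val: float | None = None
    r2_val: float | None = None
    rpd: float | None = None
    interpretation: str | None = None
    negative_slope: bool = False

    def to_row(self) -> dict:
        d = asdict(self)
        lo, hi = d.pop("range_cal")
        d["range_cal"] = f"{lo:.2f}-{hi:.2f}"
        return d

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "CalibrationReport":
        d = json.loads(s)
        d["range_cal"] = tuple(d["range_cal"])
        return cls(**d)


def build_report(
    component: str,
    y_cal: np.ndarray,
    cal_predictions: np.ndarray,
    n_factors: int,
    loo_residuals: np.ndarray,
    y_val: np.ndarray | None = None,
    val_predictions: np.ndarray | None = None,
    sep_convention: str = "bias-corrected",
) -> CalibrationReport:
    """Assemble the full statistics row for one component.

    Validation fields stay empty when no external validation set is given.
    """
    y_cal = np.asarray(y_cal, float)
    cal_predictions = np.asarray(cal_predictions, float)
    e_cal = y_cal - cal_predictions
    loo_residuals = np.asarray(loo_residuals, float)
    sd_cal = float(np.std(y_cal, ddof=1))
    report = CalibrationReport(
        component=component,
        n_cal=y_cal.size,
        mean_cal=float(y_cal.mean()),
        range_cal=(float(y_cal.min()), float(y_cal.max())),
        sd_cal=sd_cal,
        n_factors=int(n_factors),
        sec=sec(e_cal, n_factors),
        r2_cal=r_squared(cal_predictions, y_cal),
        secv=secv(loo_residuals),
        r2_cv=r_squared(y_cal - loo_residuals, y_cal),
    )
    if y_val is not None and val_predictions is not None:
        y_val = np.asarray(y_val, float)
        val_predictions = np.asarray(val_predictions, float)
        e_val = y_val - val_predictions
        sep_value, bias = sep(e_val, sep_convention)
        report.n_val = y_val.size
        report.mean_val = float(y_val.mean())
        report.sd_val = float(np.std(y_val, ddof=1))
        report.sep = sep_value
        report.bias_val = bias
        report.r2_val = r_squared(val_predictions, y_val)
        slope = float(np.polyfit(y_val, val_predictions, 1)[0])
        report.negative_slope = slope < 0
        if sep_value > 0:
            report.rpd = rpd(sd_cal, sep_value)
            report.interpretation = interpret_rpd(report.rpd)
    return report


def reports_to_table(reports) -> pd.DataFrame:
    """Stack reports into the standard calibration-summary column order."""
    cols = [
        "component", "n_cal", "mean_cal", "range_cal", "sd_cal", "n_factors",
        "sec", "r2_cal", "secv", "r2_cv", "n_val", "mean_val", "sd_val",
        "sep", "r2_val", "rpd", "interpretation",
    ]
    rows = [r.to_row() for r in reports]
    return pd.DataFrame(rows)[cols]
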