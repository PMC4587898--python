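"""Agreement statistics between actual and predicted walk distances.

For one (actual, predicted) pairing the report carries Pearson's r with its
two-sided p-value, the paired t-test (equivalent to a one-sample t on the
per-subject differences), the bias (mean of predicted - actual), the sample
SD of the differences (n-1 denominator), and a coefficient of variation

    CV% = 100 * SD(differences) / mean(predicted)

which expresses the per-subject prediction error relative to the typical
predicted distance. No multiple-testing correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["AgreementReport", "agreement_report", "cv_percent", "reports_to_frame", "format_report_table"]


@dataclass(frozen=True)
class AgreementReport:
    n: int
    mean_actual: float  # m
    mean_predicted: float  # m
    bias: float  # m, mean(predicted - actual)
    sd_diff: float  # m, SD of per-subject differences (n-1)
    cv_percent: float
    pearson_r: float
    r_p_value: float
    t_statistic: float
    t_p_value: float

    def to_dict(self) -> dict:
        return asdict(self)


def cv_percent(sd_diff: float, mean_predicted: float) -> float:
    """Coefficient of variation (%) of prediction error: 100*sd_diff/mean_predicted."""
    if sd_diff < 0:
        raise ValueError("sd_diff must be non-negative")
    if not mean_predicted > 0:
        raise ValueError(f"mean predicted distance must be positive, got {mean_predicted}")
    return 100.0 * sd_diff / mean_predicted


def agreement_report(actual: Sequence[float], predicted: Sequence[float]) -> AgreementReport:
    """All agreement statistics for one (actual, predicted) pairing.

    Requires equal lengths, n >= 3 and no missing values; a zero-variance
    vector makes Pearson's r undefined and raises rather than returning NaN.
    The degenerate identical-vectors case is well-defined: bias 0, sd 0,
    r = 1, t = 0 with p = 1.
    """
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape or a.ndim != 1:
        raise ValueError(f"length mismatch: actual {a.shape}, predicted {p.shape}")
    n = a.size
    if n < 3:
        raise ValueError(f"need at least 3 paired observations, got {n}")
    if np.isnan(a).any() or np.isnan(p).any():
        raise ValueError("missing values are not allowed")
    if np.ptp(a) == 0 or np.ptp(p) == 0:
        raise ValueError("zero variance in actual or predicted: Pearson's r is undefined")

    diff = p - a
    bias = float(diff.mean())
    sd_diff = float(diff.std(ddof=1))

    r, r_p = stats.pearsonr(a, p)
    if sd_diff == 0.0:
        # all differences identical: t is 0/0 when bias is 0, +/-inf otherwise
        t_stat, t_p = (0.0, 1.0) if bias == 0.0 else (math.copysign(math.inf, bias), 0.0)
    else:
        t_stat = bias / (sd_diff / math.sqrt(n))
        t_p = float(2.0 * stats.t.sf(abs(t_stat), df=n - 1))

    return AgreementReport(
        n=n,
        mean_actual=float(a.mean()),
        mean_predicted=float(p.mean()),
        bias=bias,
        sd_diff=sd_diff,
        cv_percent=cv_percent(sd_diff, float(p.mean())),
        pearson_r=float(r),
        r_p_value=float(r_p),
        t_statistic=float(t_stat),
        t_p_value=float(t_p),
    )


def reports_to_frame(reports: dict[str, AgreementReport]) -> pd.DataFrame:
    """One row per equation name, columns in the standard report order."""
    rows = [{"equation": name, **rep.to_dict()} for name, rep in reports.items()]
    cols = [
        "equation", "n", "mean_actual", "mean_predicted", "bias", "sd_diff",
        "cv_percent", "pearson_r", "r_p_value", "t_statistic", "t_p_value",
    ]
    return pd.DataFrame(rows, columns=cols)


def format_report_table(frame: pd.DataFrame) -> str:
    """Human-readable table: metres and CV% at 1 decimal, r at 3 decimals."""
    disp = frame.copy()
    for col in ("mean_actual", "mean_predicted", "bias", "sd_diff", "cv_percent"):
        disp[col] = disp[col].map(lambda v: f"{v:.1f}")
    disp["pearson_r"] = disp["pearson_r"].map(lambda v: f"{v:.3f}")
    for col in ("r_p_value", "t_p_value"):
        disp[col] = disp[col].map(lambda v: f"{v:.3g}")
    disp["t_statistic"] = disp["t_statistic"].map(lambda v: f"{v:.2f}")
    return disp.to_string(index=False)
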