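"""Method-agreement statistics between two paired sets of gait parameters.

The validation battery used to compare a candidate measurement system
against a reference, per parameter across walks: a paired two-sample
t-test with Cohen's d, simple linear regression with an F-test and R²,
the Pearson correlation with a Fisher-z 95% confidence interval, and
Bland-Altman limits of agreement. Two-sided tests throughout at
significance level 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AgreementReport",
    "paired_ttest",
    "simple_regression",
    "pearson_ci",
    "bland_altman",
    "compare_parameters",
    "bland_altman_plot",
    "regression_plot",
]


@dataclass
class AgreementReport:
    """All agreement statistics for one gait parameter across paired walks."""

    parameter_name: str
    n: int
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t_stat: float
    dof: int
    p_value: float
    cohens_d: float
    slope: float
    intercept: float
    r_squared: float
    f_stat: float
    f_p: float
    pearson_r: float
    r_se: float
    r_ci_low: float
    r_ci_high: float
    ba_bias: float
    ba_loa_low: float
    ba_loa_high: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D arrays")
    return a, b


def paired_ttest(a, b) -> tuple[float, int, float, float]:
    """Paired two-sample t-test; returns ``(t, dof, p, cohens_d)``.

    ``t = mean(a-b) / (sd(a-b)/sqrt(n))`` with ``dof = n - 1`` and a
    two-sided p-value. Cohen's d for paired data is ``|mean(d)| / sd(d)``
    (reported as a magnitude). Degenerate cases: identical pairs give
    ``t = 0, p = 1, d = 0``; a constant nonzero difference has zero
    variance and is flagged with an infinite t.
    """
    a, b = _pair(a, b)
    n = a.size
    if n < 2:
        raise ValueError("need n >= 2 pairs")
    d = a - b
    dof = n - 1
    sd = float(d.std(ddof=1))
    md = float(d.mean())
    if sd == 0.0:
        if md == 0.0:
            return 0.0, dof, 1.0, 0.0
        return math.copysign(math.inf, md), dof, 0.0, math.inf
    res = stats.ttest_rel(a, b)
    return float(res.statistic), dof, float(res.pvalue), abs(md) / sd


def simple_regression(x, y) -> tuple[float, float, float, float, float]:
    """Ordinary least squares of y on x; ``(slope, intercept, r2, F, p)``.

    The F-statistic for the necessity of the linear model is
    ``F = (n - 2) * R^2 / (1 - R^2)`` on (1, n-2) degrees of freedom;
    its p-value equals the two-sided slope t-test p-value.
    """
    x, y = _pair(x, y)
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3 for regression")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; regression undefined")
    res = stats.linregress(x, y)
    r2 = float(res.rvalue**2)
    if r2 >= 1.0:
        f = math.inf
    else:
        f = (n - 2) * r2 / (1.0 - r2)
    return float(res.slope), float(res.intercept), r2, f, float(res.pvalue)


def pearson_ci(x, y, level: float = 0.95) -> tuple[float, float, float, float, float]:
    """Pearson r with Fisher-z confidence interval; ``(r, se, lo, hi, p)``.

    The CI uses the Fisher transform with ``se_z = 1/sqrt(n-3)``; the
    reported SE of r itself is ``sqrt((1 - r^2)/(n - 2))``.
    """
    x, y = _pair(x, y)
    n = x.size
    if n < 4:
        raise ValueError("need n >= 4 for a Fisher CI")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input; correlation undefined")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    if abs(r) >= 1.0:
        return r, 0.0, r, r, float(res.pvalue)
    ci = res.confidence_interval(confidence_level=level)
    se_r = math.sqrt((1.0 - r**2) / (n - 2))
    return r, se_r, float(ci.low), float(ci.high), float(res.pvalue)


def bland_altman(a, b, k: float = 1.96) -> tuple[float, float, float, pd.DataFrame]:
    """Bland-Altman agreement: ``(bias, loa_low, loa_high, table)``.

    Differences ``d = a - b``; bias is their mean and the limits of
    agreement are ``bias ± k*sd(d)`` (sample sd, n-1 denominator),
    expected to contain ~95% of differences at k = 1.96. The table holds
    per-pair means and differences for plotting.
    """
    a, b = _pair(a, b)
    if a.size < 2:
        raise ValueError("need n >= 2 pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    table = pd.DataFrame({"mean": (a + b) / 2.0, "diff": d})
    return bias, bias - k * sd, bias + k * sd, table


def compare_parameters(
    df_a: pd.DataFrame, df_b: pd.DataFrame, parameters: list[str] | None = None
) -> dict[str, AgreementReport]:
    """Run the full battery on each shared parameter column of two paired tables.

    Rows are walks; walks where either system lacks a value (NaN) are
    dropped pairwise per parameter.
    """
    if parameters is None:
        parameters = [c for c in df_a.columns if c in df_b.columns and c != "n_steps"]
    out: dict[str, AgreementReport] = {}
    for name in parameters:
        a = df_a[name].to_numpy(dtype=float)
        b = df_b[name].to_numpy(dtype=float)
        ok = np.isfinite(a) & np.isfinite(b)
        a, b = a[ok], b[ok]
        t, dof, p, d = paired_ttest(a, b)
        slope, intercept, r2, f, f_p = simple_regression(b, a)
        r, se, lo, hi, _ = pearson_ci(b, a)
        bias, loa_lo, loa_hi, _tab = bland_altman(a, b)
        out[name] = AgreementReport(
            parameter_name=name,
            n=int(a.size),
            mean_a=float(a.mean()),
            sd_a=float(a.std(ddof=1)),
            mean_b=float(b.mean()),
            sd_b=float(b.std(ddof=1)),
            t_stat=t,
            dof=dof,
            p_value=p,
            cohens_d=d,
            slope=slope,
            intercept=intercept,
            r_squared=r2,
            f_stat=f,
            f_p=f_p,
            pearson_r=r,
            r_se=se,
            r_ci_low=lo,
            r_ci_high=hi,
            ba_bias=bias,
            ba_loa_low=loa_lo,
            ba_loa_high=loa_hi,
        )
    return out


def bland_altman_plot(a, b, name: str, path: str, k: float = 1.96) -> None:
    """Save a Bland-Altman plot (mean vs difference with bias and LoA lines)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    bias, lo, hi, table = bland_altman(a, b, k=k)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(table["mean"], table["diff"], s=12, alpha=0.7)
    for y, style, label in ((bias, "-", "bias"), (lo, "--", "LoA"), (hi, "--", None)):
        ax.axhline(y, color="k", linestyle=style, linewidth=1, label=label)
    ax.set_xlabel(f"mean of methods — {name}")
    ax.set_ylabel("difference (a − b)")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def regression_plot(x, y, name: str, path: str) -> None:
    """Save a scatter plot with the fitted regression line and R² annotation."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    slope, intercept, r2, f, _ = simple_regression(x, y)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(x, y, s=12, alpha=0.7)
    xs = np.array([np.min(x), np.max(x)])
    ax.plot(xs, slope * xs + intercept, "k-", linewidth=1)
    ax.set_title(f"{name}: y = {slope:.3f}x + {intercept:.3g}, R² = {r2:.3f}", fontsize=9)
    ax.set_xlabel("reference")
    ax.set_ylabel("seismograph")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
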