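"""Per-element summary statistics, Pearson correlation with p-values,
and the blank-based method detection limit.

Conventions: standard deviation is the sample (n-1) estimator, CV is
sd/mean, skewness is the adjusted Fisher–Pearson sample coefficient and
kurtosis is sample excess kurtosis (flat series come out negative).
Statistics that need more sites than supplied are reported as NaN rather
than raising.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .tables import BlankSeries, ConcentrationTable

__all__ = [
    "SummaryStats",
    "CorrelationResult",
    "DetectionLimit",
    "summarize",
    "correlation_matrix",
    "method_detection_limit",
]

SUMMARY_ROWS = ["min", "max", "mean", "median", "sd", "cv", "skewness", "kurtosis"]


@dataclasses.dataclass(frozen=True)
class SummaryStats:
    """Summary statistics, one column per element, rows in SUMMARY_ROWS order."""

    table: pd.DataFrame

    def __getitem__(self, element: str) -> pd.Series:
        return self.table[element]


@dataclasses.dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation matrix and matching two-sided p-values."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: int


@dataclasses.dataclass(frozen=True)
class DetectionLimit:
    """Method detection limit from replicate blanks: MDL = X + t * SD."""

    element: str
    blank_mean: float
    blank_sd: float
    multiplier: float
    value: float


def summarize(table: ConcentrationTable) -> SummaryStats:
    """Per-element min/max/mean/median/sd/CV/skewness/kurtosis.

    sd and CV need >= 2 sites, skewness >= 3, kurtosis >= 4; below those
    counts the statistic is NaN.
    """
    df = table.data
    n = df.shape[0]
    out = pd.DataFrame(index=SUMMARY_ROWS, columns=df.columns, dtype=float)
    out.loc["min"] = df.min()
    out.loc["max"] = df.max()
    out.loc["mean"] = df.mean()
    out.loc["median"] = df.median()
    out.loc["sd"] = df.std(ddof=1) if n >= 2 else np.nan
    out.loc["cv"] = out.loc["sd"] / out.loc["mean"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out.loc["skewness"] = (
            sps.skew(df.to_numpy(), axis=0, bias=False) if n >= 3 else np.nan
        )
        out.loc["kurtosis"] = (
            sps.kurtosis(df.to_numpy(), axis=0, bias=False) if n >= 4 else np.nan
        )
    return SummaryStats(out)


def correlation_matrix(table: ConcentrationTable) -> CorrelationResult:
    """Pairwise Pearson r with two-sided p-values.

    p comes from the t transform t = r sqrt((n-2)/(1-r^2)) on n-2 degrees
    of freedom.  A zero-variance column yields NaN for every pair that
    involves it, with a warning naming the element.
    """
    df = table.data
    n = df.shape[0]
    if n < 3:
        raise ValueError("correlation needs at least 3 sites")
    elements = list(df.columns)
    sd = df.std(ddof=1)
    degenerate = [e for e in elements if sd[e] == 0]
    if degenerate:
        warnings.warn(f"zero-variance elements, correlations undefined: {degenerate}")

    r = df.corr(method="pearson")
    p = pd.DataFrame(np.nan, index=elements, columns=elements)
    for i, a in enumerate(elements):
        p.at[a, a] = 0.0 if a not in degenerate else np.nan
        for b in elements[i + 1 :]:
            if a in degenerate or b in degenerate:
                r.at[a, b] = r.at[b, a] = np.nan
                continue
            rv = r.at[a, b]
            if abs(rv) >= 1.0:
                pv = 0.0
            else:
                t = rv * np.sqrt((n - 2) / (1.0 - rv * rv))
                pv = 2.0 * sps.t.sf(abs(t), df=n - 2)
            p.at[a, b] = p.at[b, a] = pv
    return CorrelationResult(r=r, p=p, n=n)


def holm_adjust(p: pd.DataFrame) -> pd.DataFrame:
    """Holm step-down adjustment of the off-diagonal p-values (optional;
    the default report leaves p-values unadjusted)."""
    elements = list(p.columns)
    pairs = [(a, b) for i, a in enumerate(elements) for b in elements[i + 1 :]]
    raw = np.array([p.at[a, b] for a, b in pairs])
    order = np.argsort(raw)
    m = len(raw)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * raw[idx])
        adj[idx] = min(1.0, running)
    out = pd.DataFrame(np.nan, index=elements, columns=elements)
    np.fill_diagonal(out.to_numpy(), 0.0)
    for (a, b), v in zip(pairs, adj):
        out.at[a, b] = out.at[b, a] = v
    return out


def method_detection_limit(
    blanks: BlankSeries,
    confidence: float = 0.99,
    multiplier_override: float | None = None,
) -> DetectionLimit:
    """MDL = blank mean + t * blank sd.

    t is the one-sided Student quantile at *confidence* on n-1 degrees of
    freedom (2.896 for nine replicates at 99%), unless overridden to
    reproduce a fixed published multiplier.
    """
    if not (0.5 < confidence < 1.0):
        raise ValueError("confidence must lie in (0.5, 1)")
    x = float(np.mean(blanks.measurements))
    sd = float(np.std(blanks.measurements, ddof=1))
    if multiplier_override is not None:
        t = float(multiplier_override)
        if t <= 0:
            raise ValueError("multiplier override must be > 0")
    else:
        t = float(sps.t.ppf(confidence, df=blanks.n - 1))
    return DetectionLimit(
        element=blanks.element,
        blank_mean=x,
        blank_sd=sd,
        multiplier=t,
        value=x + t * sd,
    )
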