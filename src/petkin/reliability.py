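"""Test–retest reliability and between-method agreement statistics.

Absolute test–retest variability (aTRV) for a paired quantity is

    aTRV = 100 · |test − retest| / mean(test, retest)   [percent]

and is symmetric and scale-invariant.  Reliability is summarized by the
intra-class correlation coefficient from a two-way (subject × session) mixed
model; the default flavor is single-measure absolute agreement (ICC(A,1)),
with consistency (ICC(C,1)) available as a switch.  Region summaries average
per-subject aTRV over subjects with both sessions present and reliable
(%SE < 25% upstream), not the aTRV of region averages.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .errors import DomainError, InsufficientDataError

__all__ = [
    "atrv",
    "icc",
    "icc_from_table",
    "method_agreement",
    "region_reliability",
    "reliability_report",
]

#: columns of the long-format method/region table
TABLE_COLUMNS = ["subject", "session", "region", "method", "VT", "reliable"]


def atrv(test: float, retest: float) -> float:
    """Absolute test–retest variability in percent."""
    if test <= 0 or retest <= 0:
        raise DomainError("test and retest values must be positive")
    return 100.0 * abs(test - retest) / ((test + retest) / 2.0)


def icc_from_table(table: np.ndarray, kind: str = "absolute") -> float:
    """ICC of an n_subjects × n_sessions matrix of complete measurements.

    Two-way mixed model, single measures.  ``kind`` selects absolute
    agreement, ICC(A,1), or consistency, ICC(C,1).  Returns NaN (with a
    warning) when the between-subject variance is degenerate.
    """
    x = np.asarray(table, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise DomainError("table must be 2-D with >= 2 sessions")
    if np.any(~np.isfinite(x)):
        raise DomainError("table must be complete (no missing cells)")
    n, k = x.shape
    if n < 2:
        raise InsufficientDataError("need at least 2 subjects with complete pairs")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((x - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    if kind == "absolute":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    elif kind == "consistency":
        denom = msr + (k - 1) * mse
    else:
        raise DomainError(f"unknown ICC kind {kind!r}")
    if abs(denom) < 1e-300 or (msr < 1e-300 and mse < 1e-300):
        warnings.warn("degenerate variance structure; ICC undefined", stacklevel=2)
        return float("nan")
    return float((msr - mse) / denom)


def icc(table: pd.DataFrame, region: str, method: str | None = None, kind: str = "absolute") -> float:
    """ICC for one region of a long-format table (see ``TABLE_COLUMNS``).

    Only subjects with both a reliable test and a reliable retest enter;
    fewer than 2 complete pairs yields NaN (reported missing).
    """
    wide = _complete_pairs(table, region, method)
    if wide is None or len(wide) < 2:
        return float("nan")
    return icc_from_table(wide.to_numpy(), kind=kind)


def _complete_pairs(table: pd.DataFrame, region: str, method: str | None):
    df = table[table["region"] == region]
    if method is not None and "method" in df.columns:
        df = df[df["method"] == method]
    if "reliable" in df.columns:
        df = df[df["reliable"].astype(bool)]
    if df.empty:
        return None
    wide = df.pivot_table(index="subject", columns="session", values="VT", aggfunc="first")
    for col in ("test", "retest"):
        if col not in wide.columns:
            return None
    wide = wide[["test", "retest"]].dropna()
    return wide if len(wide) else None


def region_reliability(
    table: pd.DataFrame, region: str, method: str | None = None, kind: str = "absolute"
) -> dict:
    """Region summary: mean per-subject aTRV, ICC and the pair count."""
    wide = _complete_pairs(table, region, method)
    if wide is None or len(wide) == 0:
        return {"region": region, "atrv": float("nan"), "icc": float("nan"), "n": 0}
    atrvs = [atrv(t, r) for t, r in wide.to_numpy()]
    icc_val = icc_from_table(wide.to_numpy(), kind=kind) if len(wide) >= 2 else float("nan")
    return {
        "region": region,
        "atrv": float(np.mean(atrvs)),
        "icc": icc_val,
        "n": int(len(wide)),
    }


def reliability_report(
    table: pd.DataFrame, method: str | None = None, kind: str = "absolute"
) -> pd.DataFrame:
    """Per-region aTRV/ICC table over every region present in the input."""
    rows = [
        region_reliability(table, region, method, kind)
        for region in sorted(table["region"].unique())
    ]
    return pd.DataFrame(rows).set_index("region")


def method_agreement(x, y) -> dict:
    """OLS agreement of method y against reference x plus mean percent bias."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DomainError("paired V_T lists must have equal length")
    if len(x) < 3:
        raise InsufficientDataError("need at least 3 pairs")
    if np.any(x <= 0):
        raise DomainError("reference values must be positive")
    fit = linregress(x, y)
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r_squared": float(fit.rvalue**2),
        "mean_percent_bias": float(np.mean(100.0 * (y - x) / x)),
    }
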