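"""Table-style summary statistics for groups of lag values.

Implements the battery used to characterise right-skewed lag distributions:
min, mean, SD, 10% trimmed mean, median, MAD, max, range, skewness,
excess kurtosis, standard error and a normal-theory 95% CI half-width.

Skewness and kurtosis follow the three classical estimator families
(Joanes & Gill):

* type 1: g1 = m3/m2^{3/2};            g2 = m4/m2^2 - 3
* type 2: G1 = g1 sqrt(n(n-1))/(n-2);  G2 = ((n+1)g2 + 6)(n-1)/((n-2)(n-3))
* type 3: b1 = g1 ((n-1)/n)^{3/2};     b2 = (g2+3)(1-1/n)^2 - 3

where m_k are the 1/n central moments.  Type 3 — the convention of the
standard R descriptive routines — is the default.  MAD defaults to the
normal-consistent scaled variant (x 1.4826); the raw median of absolute
deviations is available via ``mad_scale=1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MAD_NORMAL_SCALE = 1.4826
CI_MULTIPLIER = 1.96  # normal-theory 95% interval


@dataclass(frozen=True)
class SummaryStats:
    n: int
    min_y: float
    mean_y: float
    sd_y: float
    trimmed_mean_y: float
    median_y: float
    mad_y: float
    max_y: float
    range_y: float
    skew: float
    kurtosis: float
    se_y: float
    ci_halfwidth_y: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def trimmed_mean(values: Sequence[float], trim: float = 0.10) -> float:
    """Mean after dropping floor(trim*n) values from each end (sorted)."""
    x = np.sort(np.asarray(values, dtype=float))
    k = math.floor(trim * x.size)
    if 2 * k >= x.size:
        raise ValueError("trimming removes every value")
    return float(np.mean(x[k:x.size - k]))


def mad(values: Sequence[float], scale: float = MAD_NORMAL_SCALE) -> float:
    x = np.asarray(values, dtype=float)
    med = np.median(x)
    return float(scale * np.median(np.abs(x - med)))


def skewness(values: Sequence[float], moment_type: int = 3) -> float:
    x = np.asarray(values, dtype=float)
    n = x.size
    m2 = float(np.mean((x - x.mean()) ** 2))
    m3 = float(np.mean((x - x.mean()) ** 3))
    if m2 == 0:
        return 0.0
    g1 = m3 / m2 ** 1.5
    if moment_type == 1:
        return g1
    if moment_type == 2:
        if n < 3:
            raise ValueError("type-2 skewness requires n >= 3")
        return g1 * math.sqrt(n * (n - 1)) / (n - 2)
    if moment_type == 3:
        return g1 * ((n - 1) / n) ** 1.5
    raise ValueError(f"unknown skewness type {moment_type}")


def kurtosis(values: Sequence[float], moment_type: int = 3) -> float:
    """Excess kurtosis (normal distribution -> 0)."""
    x = np.asarray(values, dtype=float)
    n = x.size
    m2 = float(np.mean((x - x.mean()) ** 2))
    m4 = float(np.mean((x - x.mean()) ** 4))
    if m2 == 0:
        return 0.0
    g2 = m4 / m2 ** 2 - 3.0
    if moment_type == 1:
        return g2
    if moment_type == 2:
        if n < 4:
            raise ValueError("type-2 kurtosis requires n >= 4")
        return ((n + 1) * g2 + 6) * (n - 1) / ((n - 2) * (n - 3))
    if moment_type == 3:
        return (g2 + 3.0) * (1 - 1 / n) ** 2 - 3.0
    raise ValueError(f"unknown kurtosis type {moment_type}")


def describe(values: Iterable[float], trim: float = 0.10,
             mad_scale: float = MAD_NORMAL_SCALE,
             moment_type: int = 3) -> SummaryStats:
    """Full statistic battery for one group of values (n >= 2)."""
    x = np.asarray(list(values), dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("describe requires n >= 2 (SD undefined)")
    sd = float(np.std(x, ddof=1))
    se = sd / math.sqrt(n)
    return SummaryStats(
        n=n,
        min_y=float(x.min()),
        mean_y=float(x.mean()),
        sd_y=sd,
        trimmed_mean_y=trimmed_mean(x, trim),
        median_y=float(np.median(x)),
        mad_y=mad(x, mad_scale),
        max_y=float(x.max()),
        range_y=float(x.max() - x.min()),
        skew=skewness(x, moment_type),
        kurtosis=kurtosis(x, moment_type),
        se_y=se,
        ci_halfwidth_y=CI_MULTIPLIER * se,
    )


PERIODS = {"overall": "overall_y", "collection": "collection_y",
           "description": "description_y"}


def summary_table(lag_df: pd.DataFrame, group_by: str = "region",
                  trim: float = 0.10, mad_scale: float = MAD_NORMAL_SCALE,
                  moment_type: int = 3) -> pd.DataFrame:
    """Statistic battery per (group, period), plus a pooled "GLOBAL" block.

    ``group_by`` is "region", "genus", or "global" (pooled only).  Groups
    with fewer than two species are emitted with statistics set to NaN.
    """
    if lag_df.empty:
        raise ValueError("empty lag table")
    groups: list[tuple[str, pd.DataFrame]] = [("GLOBAL", lag_df)]
    if group_by != "global":
        if group_by not in lag_df.columns:
            raise KeyError(f"unknown grouping column {group_by!r}")
        groups += [(str(k), g) for k, g in lag_df.groupby(group_by, sort=True)]
    rows = []
    for name, g in groups:
        for period, col in PERIODS.items():
            vals = g[col].to_numpy(dtype=float)
            if vals.size >= 2:
                stats = describe(vals, trim, mad_scale, moment_type).as_dict()
            else:
                stats = {f.name: float("nan") for f in fields(SummaryStats)}
                stats["n"] = vals.size
            rows.append({"group": name, "period": period, **stats})
    return pd.DataFrame(rows)
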