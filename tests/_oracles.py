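"""Independent brute-force oracles shared by unit and acceptance tests.

These deliberately avoid the package's own code paths (and numpy where
practical) so they can serve as cross-checks.
"""

from __future__ import annotations

import datetime as dt
import math


def midpoint_by_enumeration(first: dt.date, last: dt.date) -> dt.date:
    """Midpoint as the floor-middle element of the enumerated day list."""
    days = []
    d = first
    while d <= last:
        days.append(d)
        d += dt.timedelta(days=1)
    return days[(len(days) - 1) // 2]


def trips_by_components(dates, gap_days: int = 30):
    """Field trips as connected components of the 'consecutive dates at
    most gap_days apart' adjacency relation."""
    dates = sorted(dates)
    comps = []
    for d in dates:
        linked = [c for c in comps
                  if any(abs((d - e).days) <= gap_days for e in c)]
        if not linked:
            comps.append([d])
        else:
            merged = [d]
            for c in linked:
                merged.extend(c)
                comps.remove(c)
            comps.append(sorted(merged))
    comps.sort(key=lambda c: c[0])
    return comps


def naive_describe(values, trim=0.10, mad_scale=1.4826, moment_type=3):
    """Two-pass pure-Python implementation of the summary battery."""
    x = sorted(float(v) for v in values)
    n = len(x)
    mean = sum(x) / n
    var = sum((v - mean) ** 2 for v in x) / (n - 1)
    sd = math.sqrt(var)

    k = math.floor(trim * n)
    core = x[k:n - k]
    tmean = sum(core) / len(core)

    def med(vals):
        v = sorted(vals)
        m = len(v)
        return v[m // 2] if m % 2 else 0.5 * (v[m // 2 - 1] + v[m // 2])

    median = med(x)
    mad = mad_scale * med([abs(v - median) for v in x])

    m2 = sum((v - mean) ** 2 for v in x) / n
    m3 = sum((v - mean) ** 3 for v in x) / n
    m4 = sum((v - mean) ** 4 for v in x) / n
    g1 = m3 / m2 ** 1.5 if m2 > 0 else 0.0
    g2 = m4 / m2 ** 2 - 3.0 if m2 > 0 else 0.0
    if moment_type == 1:
        skew, kurt = g1, g2
    elif moment_type == 2:
        skew = g1 * math.sqrt(n * (n - 1)) / (n - 2)
        kurt = ((n + 1) * g2 + 6) * (n - 1) / ((n - 2) * (n - 3))
    else:
        skew = g1 * ((n - 1) / n) ** 1.5
        kurt = (g2 + 3.0) * (1 - 1 / n) ** 2 - 3.0

    se = sd / math.sqrt(n)
    return {
        "n": n, "min_y": x[0], "mean_y": mean, "sd_y": sd,
        "trimmed_mean_y": tmean, "median_y": median, "mad_y": mad,
        "max_y": x[-1], "range_y": x[-1] - x[0], "skew": skew,
        "kurtosis": kurt, "se_y": se, "ci_halfwidth_y": 1.96 * se,
    }
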