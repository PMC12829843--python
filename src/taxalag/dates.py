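"""Parsing of verbatim collection-date strings with midpoint imputation.

Type-series metadata report collection dates at mixed precision: exact days
("12 March 2010", "2010-03-12"), day ranges ("5–7 December 2008",
possibly crossing a month or year boundary), month only ("February 2007"),
or year only ("1925").  Every string is resolved to the *midpoint* of the
calendar interval it implies, defined as the floor of the arithmetic mean of
the first and last day of the interval, so an even-length interval resolves
to the earlier of the two central days (e.g. "February 2007" -> 2007-02-14).

The original precision class is preserved so downstream analyses can audit
or drop low-precision events.  Ambiguous all-numeric forms such as
"03/04/2010" are rejected rather than guessed.
"""

from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass
from enum import Enum


class DatePrecision(str, Enum):
    DAY = "day"
    DAY_RANGE = "day_range"
    MONTH = "month"
    YEAR = "year"


class DateParseError(ValueError):
    """Raised when a verbatim date string matches no supported dialect."""

    def __init__(self, raw_text: str, message: str | None = None):
        self.raw_text = raw_text
        super().__init__(message or f"unparseable date string: {raw_text!r}")


_MONTHS = {
    name.lower(): i + 1
    for i, name in enumerate(
        ["January", "February", "March", "April", "May", "June", "July",
         "August", "September", "October", "November", "December"]
    )
}
_MONTHS.update({name[:3]: num for name, num in list(_MONTHS.items())})
_MONTH_NAMES = ["January", "February", "March", "April", "May", "June",
                "July", "August", "September", "October", "November",
                "December"]

# en dash, em dash, hyphen, or the word "to" separate range endpoints
_RANGE_SEP = r"(?:–|—|-|\bto\b)"


@dataclass(frozen=True)
class CollectionDate:
    """A verbatim date string resolved to a midpoint calendar date.

    ``span_days`` is the length of the uncertainty interval minus one, i.e.
    0 for an exact day, 27-30 for a month, 364-365 for a year.
    """

    raw_text: str
    resolved: dt.date
    precision: DatePrecision
    span_days: int

    def __post_init__(self):
        if self.span_days < 0:
            raise ValueError("span_days must be >= 0")
        if self.precision is DatePrecision.DAY and self.span_days != 0:
            raise ValueError("day precision implies span_days == 0")

    def to_text(self) -> str:
        """Canonical serialization; re-parsing it returns an equal value."""
        first, last = interval_from_midpoint(self)
        if self.precision is DatePrecision.DAY:
            return self.resolved.isoformat()
        if self.precision is DatePrecision.MONTH:
            return f"{_MONTH_NAMES[first.month - 1]} {first.year}"
        if self.precision is DatePrecision.YEAR:
            return str(first.year)
        if first.year == last.year and first.month == last.month:
            return (f"{first.day}–{last.day} "
                    f"{_MONTH_NAMES[first.month - 1]} {first.year}")
        return (f"{first.day} {_MONTH_NAMES[first.month - 1]} {first.year} "
                f"– {last.day} {_MONTH_NAMES[last.month - 1]} {last.year}")


def _month_num(token: str) -> int | None:
    return _MONTHS.get(token.strip().lower())


def days_in_month(year: int, month: int) -> int:
    if month == 12:
        nxt = dt.date(year + 1, 1, 1)
    else:
        nxt = dt.date(year, month + 1, 1)
    return (nxt - dt.date(year, month, 1)).days


def midpoint(first: dt.date, last: dt.date) -> dt.date:
    """Floor of the arithmetic mean of the interval endpoints, in days."""
    if last < first:
        raise ValueError("interval endpoints out of order")
    return first + dt.timedelta(days=(last - first).days // 2)


def _classify(first: dt.date, last: dt.date) -> DatePrecision:
    if first == last:
        return DatePrecision.DAY
    if (first.day == 1 and first.month == 1 and last.month == 12
            and last.day == 31 and first.year == last.year):
        return DatePrecision.YEAR
    if (first.day == 1 and first.year == last.year
            and first.month == last.month
            and last.day == days_in_month(first.year, first.month)):
        return DatePrecision.MONTH
    return DatePrecision.DAY_RANGE


def _build(raw: str, first: dt.date, last: dt.date) -> CollectionDate:
    return CollectionDate(
        raw_text=raw,
        resolved=midpoint(first, last),
        precision=_classify(first, last),
        span_days=(last - first).days,
    )


_ISO_RE = re.compile(r"^(\d{4})-(\d{2})-(\d{2})$")
_DMY_RE = re.compile(r"^(\d{1,2})\s+([A-Za-z]+)\s+(\d{4})$")
_DAY_RANGE_RE = re.compile(
    rf"^(\d{{1,2}})\s*{_RANGE_SEP}\s*(\d{{1,2}})\s+([A-Za-z]+)\s+(\d{{4}})$")
_CROSS_MONTH_RE = re.compile(
    rf"^(\d{{1,2}})\s+([A-Za-z]+)\s*(?:(\d{{4}})\s*)?{_RANGE_SEP}"
    rf"\s*(\d{{1,2}})\s+([A-Za-z]+)\s+(\d{{4}})$")
_MONTH_YEAR_RE = re.compile(r"^([A-Za-z]+)\s+(\d{4})$")
_YEAR_RE = re.compile(r"^(\d{4})$")


def parse_date_text(raw: str) -> CollectionDate:
    """Resolve a verbatim date string to its midpoint :class:`CollectionDate`.

    Supported dialects: ISO ``2010-03-12``; ``12 March 2010``;
    ``5–7 December 2008``; cross-month/year ranges
    ``28 February – 3 March 2008``; ``February 2007``; ``1925``.
    Anything else raises :class:`DateParseError`.
    """
    if raw is None:
        raise DateParseError("", "empty date string")
    text = str(raw).strip()
    if not text:
        raise DateParseError(text, "empty date string")

    m = _ISO_RE.match(text)
    if m:
        try:
            d = dt.date(int(m[1]), int(m[2]), int(m[3]))
        except ValueError as exc:
            raise DateParseError(text, str(exc)) from exc
        return _build(text, d, d)

    m = _DMY_RE.match(text)
    if m:
        mon = _month_num(m[2])
        if mon is None:
            raise DateParseError(text, f"unknown month {m[2]!r}")
        try:
            d = dt.date(int(m[3]), mon, int(m[1]))
        except ValueError as exc:
            raise DateParseError(text, str(exc)) from exc
        return _build(text, d, d)

    m = _DAY_RANGE_RE.match(text)
    if m:
        mon = _month_num(m[3])
        if mon is None:
            raise DateParseError(text, f"unknown month {m[3]!r}")
        try:
            first = dt.date(int(m[4]), mon, int(m[1]))
            last = dt.date(int(m[4]), mon, int(m[2]))
        except ValueError as exc:
            raise DateParseError(text, str(exc)) from exc
        if last < first:
            raise DateParseError(text, "range endpoints out of order")
        return _build(text, first, last)

    m = _CROSS_MONTH_RE.match(text)
    if m:
        mon1, mon2 = _month_num(m[2]), _month_num(m[5])
        if mon1 is None or mon2 is None:
            raise DateParseError(text, "unknown month name")
        year2 = int(m[6])
        year1 = int(m[3]) if m[3] else year2
        try:
            first = dt.date(year1, mon1, int(m[1]))
            last = dt.date(year2, mon2, int(m[4]))
        except ValueError as exc:
            raise DateParseError(text, str(exc)) from exc
        if last < first:
            raise DateParseError(text, "range endpoints out of order")
        return _build(text, first, last)

    m = _MONTH_YEAR_RE.match(text)
    if m:
        mon = _month_num(m[1])
        if mon is None:
            raise DateParseError(text, f"unknown month {m[1]!r}")
        year = int(m[2])
        first = dt.date(year, mon, 1)
        last = dt.date(year, mon, days_in_month(year, mon))
        return _build(text, first, last)

    m = _YEAR_RE.match(text)
    if m:
        year = int(m[1])
        return _build(text, dt.date(year, 1, 1), dt.date(year, 12, 31))

    raise DateParseError(text)


def interval_from_midpoint(cd: CollectionDate) -> tuple[dt.date, dt.date]:
    """Reconstruct the (first, last) interval a CollectionDate covers."""
    if cd.precision is DatePrecision.DAY:
        return cd.resolved, cd.resolved
    if cd.precision is DatePrecision.MONTH:
        first = cd.resolved.replace(day=1)
        return first, first.replace(
            day=days_in_month(first.year, first.month))
    if cd.precision is DatePrecision.YEAR:
        y = cd.resolved.year
        return dt.date(y, 1, 1), dt.date(y, 12, 31)
    # day_range: midpoint is first + span//2
    first = cd.resolved - dt.timedelta(days=cd.span_days // 2)
    return first, first + dt.timedelta(days=cd.span_days)
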