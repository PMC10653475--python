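"""Date parsing and the decimal-year convention used throughout the package.

All durations are expressed in 365.25-day years: the calendar-day difference
between two dates divided by 365.25. This reproduces one-decimal year
reporting without the ambiguities of month arithmetic.
"""

from __future__ import annotations

import datetime as _dt

DAYS_PER_YEAR = 365.25

#: Accepted input dialects: Orange Book data files print "Apr 20, 2000";
#: internal/canonical files use ISO-8601.
_OB_FORMAT = "%b %d, %Y"


class DateParseError(ValueError):
    """A date string matched neither accepted dialect."""


def parse_date(text: str) -> _dt.date:
    """Parse an ISO-8601 (``2000-04-20``) or Orange Book (``Apr 20, 2000``) date."""
    s = text.strip()
    try:
        return _dt.date.fromisoformat(s)
    except ValueError:
        pass
    try:
        return _dt.datetime.strptime(s, _OB_FORMAT).date()
    except ValueError:
        raise DateParseError(
            f"unparseable date {text!r}: expected ISO-8601 or 'Mon DD, YYYY'"
        ) from None


def format_date(d: _dt.date) -> str:
    """Canonical (ISO-8601) serialization."""
    return d.isoformat()


def years_between(start: _dt.date, end: _dt.date) -> float:
    """Signed duration from *start* to *end* in 365.25-day years."""
    return (end - start).days / DAYS_PER_YEAR
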