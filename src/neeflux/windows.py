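"""8-day compositing-window arithmetic.

Windows are anchored at day-of-year 1, 9, 17, ..., 361 within each calendar
year (the MOD09A1 grid).  The last window of a year (DOY 361) absorbs the
remaining 5-6 days, so every date maps to exactly one window start.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Number of days per composite window.
WINDOW_DAYS = 8

#: Day-of-year of the last window start in any calendar year.
LAST_SLOT_DOY = 361


def window_start(timestamps) -> pd.Series | pd.Timestamp:
    """Map timestamps to the start date of their 8-day window.

    Accepts a single timestamp-like value or an array/Series; returns a
    normalized (midnight) ``Timestamp`` or a Series thereof.
    """
    scalar = np.isscalar(timestamps) or isinstance(timestamps, pd.Timestamp)
    ts = pd.to_datetime(pd.Series(np.atleast_1d(timestamps)))
    doy = ts.dt.dayofyear
    slot_doy = ((doy - 1) // WINDOW_DAYS) * WINDOW_DAYS + 1
    slot_doy = slot_doy.clip(upper=LAST_SLOT_DOY)
    year_start = ts.dt.normalize() - pd.to_timedelta(doy - 1, unit="D")
    starts = year_start + pd.to_timedelta(slot_doy - 1, unit="D")
    if scalar:
        return starts.iloc[0]
    starts.index = getattr(timestamps, "index", starts.index)
    return starts


def window_range(start, end) -> pd.DatetimeIndex:
    """All window starts from the window containing ``start`` through the
    window containing ``end`` (inclusive)."""
    first = window_start(pd.Timestamp(start))
    last = window_start(pd.Timestamp(end))
    if last < first:
        raise ValueError("end precedes start")
    out = []
    cur = first
    while cur <= last:
        out.append(cur)
        doy = cur.dayofyear
        if doy >= LAST_SLOT_DOY:
            cur = pd.Timestamp(year=cur.year + 1, month=1, day=1)
        else:
            cur = cur + pd.Timedelta(days=WINDOW_DAYS)
    return pd.DatetimeIndex(out)


def window_end(start: pd.Timestamp) -> pd.Timestamp:
    """Exclusive end of the window beginning at ``start``."""
    start = pd.Timestamp(start)
    if start.dayofyear >= LAST_SLOT_DOY:
        return pd.Timestamp(year=start.year + 1, month=1, day=1)
    return start + pd.Timedelta(days=WINDOW_DAYS)
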