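"""Occasion calendar for a biannual (May/October) trapping design.

Sessions fall in May and October.  The period between consecutive sessions
is a "season": the 7-month cool wet winter (October through April, closing
with a May session) or the 5-month warm dry summer (May through September,
closing with an October session).  Interval lengths are integer months and
are the exponents used to scale monthly vital rates to interval scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

SESSION_MONTHS = (5, 10)  # May, October

#: months until the next session in the biannual design
_MONTHS_AFTER = {10: 7, 5: 5}

_WINTER_MONTHS = {10, 11, 12, 1, 2, 3, 4}


def season_of_month(month: int) -> str:
    """Season containing a calendar month: wet winter is October-April."""
    return "winter" if month in _WINTER_MONTHS else "summer"


@dataclass(frozen=True)
class Occasion:
    """A single trapping session.

    ``season_preceding`` names the season that ended at this session
    ("winter" for May sessions, "summer" for October sessions); it is the
    seasonal covariate attached to occasion-level parameters such as p.
    """

    index: int  # 1-based
    date: pd.Period  # month resolution
    season_preceding: str
    interval_to_next_months: int | None


class OccasionCalendar:
    """Ordered trapping occasions with interval lengths in months."""

    def __init__(self, occasions: Sequence[Occasion]):
        if len(occasions) < 2:
            raise ValueError("calendar needs at least two occasions")
        idx = [o.index for o in occasions]
        if idx != list(range(1, len(occasions) + 1)):
            raise ValueError("occasion indices must be 1..T contiguous")
        self.occasions = list(occasions)

    # -- basic geometry ------------------------------------------------
    @property
    def n_occasions(self) -> int:
        return len(self.occasions)

    @property
    def n_intervals(self) -> int:
        return self.n_occasions - 1

    @property
    def interval_months(self) -> np.ndarray:
        """Length in months of interval t -> t+1, t = 1..T-1."""
        return np.array(
            [o.interval_to_next_months for o in self.occasions[:-1]], dtype=float
        )

    @property
    def interval_seasons(self) -> list[str]:
        """Season spanned by interval t -> t+1 (season of its opening month)."""
        return [season_of_month(o.date.month) for o in self.occasions[:-1]]

    @property
    def occasion_seasons(self) -> list[str]:
        """Season preceding each session (the seasonal covariate for p)."""
        return [o.season_preceding for o in self.occasions]

    @property
    def dates(self) -> list[pd.Period]:
        return [o.date for o in self.occasions]

    def occasion_years(self) -> list[int]:
        return [o.date.year for o in self.occasions]

    def interval_years(self) -> list[int]:
        """Calendar year of the session opening each interval."""
        return [o.date.year for o in self.occasions[:-1]]

    def area_indicator(self, changeover: pd.Period | str = "1997-10") -> np.ndarray:
        """Binary sampling-area covariate: 1 from the changeover session on."""
        ch = pd.Period(changeover, freq="M")
        if not (self.dates[0] <= ch <= self.dates[-1]):
            raise ValueError(f"changeover {ch} outside calendar range")
        return np.array([1.0 if o.date >= ch else 0.0 for o in self.occasions])

    def occasion_of_date(self, date: pd.Period | str) -> int:
        d = pd.Period(date, freq="M")
        for o in self.occasions:
            if o.date == d:
                return o.index
        raise KeyError(f"no trapping occasion in {d}")

    # -- interval windows for climate aggregation ----------------------
    def interval_window(self, t: int) -> tuple[pd.Period, pd.Period]:
        """Month range (inclusive) covered by interval ``t`` (1-based).

        The window opens with the month of the opening session and closes
        with the month before the closing session, e.g. a winter interval
        opened in October 2007 covers October 2007 through April 2008.
        """
        if not 1 <= t <= self.n_intervals:
            raise IndexError(f"interval {t} out of range")
        start = self.occasions[t - 1].date
        end = self.occasions[t].date - 1
        return start, end

    # -- I/O -----------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "occasion": [o.index for o in self.occasions],
                "date": [str(o.date) for o in self.occasions],
                "season": [o.season_preceding for o in self.occasions],
                "interval_months": [
                    o.interval_to_next_months if o.interval_to_next_months else ""
                    for o in self.occasions
                ],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "OccasionCalendar":
        df = pd.read_csv(path)
        dates = [pd.Period(d, freq="M") for d in df["date"]]
        return calendar_from_dates(dates)

    def __len__(self) -> int:
        return self.n_occasions

    def __repr__(self) -> str:
        return (
            f"OccasionCalendar({self.dates[0]}..{self.dates[-1]}, "
            f"T={self.n_occasions})"
        )


def occasion_calendar(
    start_session: str | pd.Period, end_session: str | pd.Period
) -> OccasionCalendar:
    """Build the biannual calendar from first to last session (inclusive).

    Sessions occur only in May and October; intervals alternate 7 months
    (October -> May, a winter) and 5 months (May -> October, a summer).

    >>> cal = occasion_calendar("1993-10", "2014-05")
    >>> cal.n_occasions
    42
    """
    start = pd.Period(start_session, freq="M")
    end = pd.Period(end_session, freq="M")
    for d, nm in ((start, "start"), (end, "end")):
        if d.month not in SESSION_MONTHS:
            raise ValueError(f"{nm} session {d} not in May or October")
    if not start < end:
        raise ValueError("start session must precede end session")

    dates = [start]
    d = start
    while d < end:
        d = d + _MONTHS_AFTER[d.month]
        dates.append(d)
    if dates[-1] != end:
        raise ValueError("end session not reachable from start by May/October steps")
    return calendar_from_dates(dates)


def calendar_from_dates(dates: Sequence[pd.Period | str]) -> OccasionCalendar:
    """Calendar from explicit monthly session dates (strictly increasing).

    Interval lengths are the month differences; each occasion's preceding
    season is the season of the month before the session.  Supports designs
    other than the biannual May/October one (e.g. monthly sessions with
    every Delta t = 1 for simulation studies).
    """
    ds = [pd.Period(d, freq="M") for d in dates]
    if any(b <= a for a, b in zip(ds, ds[1:])):
        raise ValueError("session dates must be strictly increasing")
    occasions = []
    for i, d in enumerate(ds):
        nxt = (ds[i + 1] - d).n if i + 1 < len(ds) else None
        occasions.append(
            Occasion(
                index=i + 1,
                date=d,
                season_preceding=season_of_month((d - 1).month),
                interval_to_next_months=nxt,
            )
        )
    return OccasionCalendar(occasions)


def regular_calendar(
    start: str | pd.Period, n_occasions: int, step_months: int = 1
) -> OccasionCalendar:
    """Equally spaced monthly calendar, handy for Delta t = 1 studies."""
    start = pd.Period(start, freq="M")
    return calendar_from_dates([start + i * step_months for i in range(n_occasions)])
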