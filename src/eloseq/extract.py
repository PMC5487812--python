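"""Daily rating/rank snapshots and burn-in detection.

Because Elo-ratings change only at events, the rating series is piecewise
constant between interactions: a day's snapshot is each individual's rating
after the last event at or before the end of that day (or its starting
rating if it has not yet interacted).  Ordinal ranks are assigned by
descending rating with competition ranking (tied ratings share the smaller
rank, so the pattern 1, 2, 2, 4 is possible).

When all individuals start from a common rating, the early part of a
sequence — the burn-in period — carries ratings that have not yet caught up
with the real hierarchy and should be discarded.  :func:`detect_burn_in`
flags the earliest date from which the top-rated individual is stable: same
identity across a trailing window and a day-over-day rating change no larger
than a tolerance.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .sequence import SequenceResult

__all__ = [
    "DailySnapshot",
    "snapshot",
    "daily_ratings",
    "detect_burn_in",
    "ranks_on_dates",
    "competition_ranks",
    "plot_trajectory",
]


@dataclass(frozen=True)
class DailySnapshot:
    date: _dt.date
    ratings: dict[str, float]
    ordinal_ranks: dict[str, int]


def competition_ranks(ratings: dict[str, float]) -> dict[str, int]:
    """Ordinal ranks by descending rating; ties share the smaller rank (1, 2, 2, 4)."""
    ordered = sorted(ratings.items(), key=lambda kv: (-kv[1], kv[0]))
    ranks: dict[str, int] = {}
    for pos, (sid, rating) in enumerate(ordered, start=1):
        if pos > 1 and rating == ordered[pos - 2][1]:
            ranks[sid] = ranks[ordered[pos - 2][0]]
        else:
            ranks[sid] = pos
    return ranks


def _coerce_date(date) -> _dt.date:
    if isinstance(date, _dt.datetime):
        return date.date()
    if isinstance(date, _dt.date):
        return date
    if isinstance(date, str):
        try:
            return _dt.date.fromisoformat(date.strip())
        except ValueError:
            raise ValueError(f"unparseable date {date!r} (expected YYYY-MM-DD)") from None
    raise ValueError(f"unknown date format: {date!r}")


def snapshot(
    result: SequenceResult, date, include_same_day: bool = True
) -> DailySnapshot:
    """Ratings and ordinal ranks as of the end of ``date``.

    ``include_same_day`` controls whether that day's own events count
    (default on — end-of-day semantics).  With it off, the snapshot reflects
    the state going *into* the day.
    """
    date = _coerce_date(date)
    ratings = dict(result.starting_ratings)
    for row in result.trajectory:
        if row.date > date or (not include_same_day and row.date == date):
            break
        ratings[row.id] = row.rating_after
    return DailySnapshot(date=date, ratings=ratings, ordinal_ranks=competition_ranks(ratings))


def daily_ratings(result: SequenceResult, include_same_day: bool = True) -> pd.DataFrame:
    """Per-day rating table (rows = calendar dates spanning the sequence, cols = ids).

    One pass over the trajectory; days without events repeat the previous
    day's values (the series is piecewise constant).
    """
    if not result.trajectory:
        raise ValueError("sequence has no events")
    first, last = result.first_date, result.last_date
    ratings = dict(result.starting_ratings)
    rows = []
    dates = []
    traj = result.trajectory
    i = 0
    day = first
    while day <= last:
        if not include_same_day:
            rows.append(dict(ratings))
        while i < len(traj) and traj[i].date <= day:
            ratings[traj[i].id] = traj[i].rating_after
            i += 1
        if include_same_day:
            rows.append(dict(ratings))
        dates.append(day)
        day += _dt.timedelta(days=1)
    return pd.DataFrame(rows, index=pd.Index(dates, name="date"))


def detect_burn_in(
    result: SequenceResult,
    window_days: int = 30,
    tolerance: float = 25.0,
    include_same_day: bool = True,
) -> _dt.date | None:
    """Earliest date from which the top-rated individual has a stable trajectory.

    Scans windows of ``window_days`` days: within ``[d, d + window_days]``
    the identity of the top-rated individual must not change and its largest
    absolute day-over-day rating change must be at most ``tolerance`` rating
    points.  Returns the earliest such ``d``, or ``None`` if the trajectory
    never stabilizes.  If the whole sequence is shorter than one window, the
    single window spanning it is evaluated instead.

    The defaults (30 days, 25 points = 1/8 of the usual K) are pragmatic
    conventions, not estimates; tune them to the organism's interaction rate.
    """
    if window_days < 1:
        raise ValueError(f"window_days must be >= 1, got {window_days}")
    if tolerance < 0:
        raise ValueError(f"tolerance must be >= 0, got {tolerance}")
    table = daily_ratings(result, include_same_day=include_same_day)
    values = table.to_numpy()
    ids = list(table.columns)
    n_days = len(table)

    # per-day top id (ties broken by id order, consistent with competition ranks)
    top = values.argmax(axis=1)
    top_rating = values[range(n_days), top]

    span = min(window_days, n_days - 1)
    last_start = n_days - 1 - span
    for start in range(last_start + 1):
        stop = start + span
        window_top = top[start : stop + 1]
        if (window_top != window_top[0]).any():
            continue
        series = top_rating[start : stop + 1]
        if span == 0 or abs(pd.Series(series).diff().iloc[1:]).max() <= tolerance:
            return table.index[start]
    return None


def ranks_on_dates(
    result: SequenceResult,
    events: Sequence[tuple],
    include_same_day: bool = True,
) -> list[tuple]:
    """Join daily snapshot ratings/ranks onto a (date, id) event list.

    Returns one ``(date, id, rating, ordinal_rank)`` tuple per input event,
    preserving input order.  Snapshots are cached per date.
    """
    cache: dict[_dt.date, DailySnapshot] = {}
    out = []
    for date, sid in events:
        date = _coerce_date(date)
        if sid not in result.roster:
            raise ValueError(f"id {sid!r} not in roster")
        if date not in cache:
            cache[date] = snapshot(result, date, include_same_day=include_same_day)
        snap = cache[date]
        out.append((date, sid, snap.ratings[sid], snap.ordinal_ranks[sid]))
    return out


def plot_trajectory(result: SequenceResult, path=None, ax=None):
    """Minimal rating-trajectory plot (one line per individual).

    Requires matplotlib (optional dependency); returns the axes.
    """
    import matplotlib

    if path is not None and ax is None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = daily_ratings(result)
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 5))
    for sid in sorted(table.columns):
        ax.plot(table.index, table[sid], label=sid)
    ax.set_xlabel("date")
    ax.set_ylabel("Elo-rating")
    ax.legend(fontsize="small", ncol=2)
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight")
    return ax
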