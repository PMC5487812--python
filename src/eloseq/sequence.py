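"""Read interaction logs and run the sequential Elo analysis.

The interaction datafile is a CSV with header ``Date,Time,Winner,Loser,K,
Outcome``: ISO dates, optional times, case-sensitive ids, a per-row K
factor (blank cells fall back to a run-wide default) and Outcome coded
1 = decided, 0 = draw.  Rows are stably sorted by (date, time) — a missing
time sorts to the end of its day — and processed in that order, so
same-timestamp ties keep file order.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .core import Interaction, Outcome, RatingState, update
from .priors import PriorSpec, derive_starting_ratings

__all__ = [
    "TrajectoryRow",
    "SequenceResult",
    "read_interactions",
    "run_sequence",
    "write_trajectory",
    "read_trajectory",
    "write_interactions",
]

_REQUIRED_COLUMNS = ("Date", "Winner", "Loser", "Outcome")
_TRAJECTORY_COLUMNS = ("date", "time", "event_index", "id", "rating_before", "rating_after")


@dataclass(frozen=True)
class TrajectoryRow:
    """One participant's rating change at one processed event."""

    date: _dt.date
    time: _dt.time | None
    event_index: int
    id: str
    rating_before: float
    rating_after: float


@dataclass
class SequenceResult:
    """Everything a sequential Elo run produced.

    ``trajectory`` holds two rows per processed event (winner first, then
    loser) in chronological order; ids that never interact appear only in
    ``starting_ratings`` / ``final_state`` and keep their starting rating
    throughout.
    """

    final_state: RatingState
    starting_ratings: dict[str, float]
    trajectory: list[TrajectoryRow]
    roster: set[str]
    n_processed: int
    events: list[Interaction] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Trajectory as a long-format DataFrame (one row per participant per event)."""
        return pd.DataFrame(
            [
                (
                    r.date.isoformat(),
                    "" if r.time is None else r.time.strftime("%H:%M"),
                    r.event_index,
                    r.id,
                    r.rating_before,
                    r.rating_after,
                )
                for r in self.trajectory
            ],
            columns=list(_TRAJECTORY_COLUMNS),
        )

    @property
    def first_date(self) -> _dt.date | None:
        return self.trajectory[0].date if self.trajectory else None

    @property
    def last_date(self) -> _dt.date | None:
        return self.trajectory[-1].date if self.trajectory else None


def _parse_date(value: str, row: int) -> _dt.date:
    try:
        return _dt.date.fromisoformat(value.strip())
    except ValueError:
        raise ValueError(f"row {row}: unparseable date {value!r} (expected YYYY-MM-DD)") from None


def _parse_time(value: str, row: int) -> _dt.time | None:
    value = value.strip()
    if not value:
        return None
    for fmt in ("%H:%M", "%H:%M:%S"):
        try:
            return _dt.datetime.strptime(value, fmt).time()
        except ValueError:
            continue
    raise ValueError(f"row {row}: unparseable time {value!r} (expected HH:MM[:SS])")


def read_interactions(path: str | Path, default_k: float = 200.0) -> list[Interaction]:
    """Parse an interaction CSV into a chronologically sorted event list.

    Blank K cells take ``default_k`` (the run-wide constant); Outcome must
    be 1 (decided) or 0 (draw).  Rows are read in file order, then stably
    sorted by (date, time), so within-timestamp order is preserved.
    """
    if not (default_k > 0):
        raise ValueError(f"default_k must be positive, got {default_k}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    has_time = "Time" in df.columns
    has_k = "K" in df.columns

    interactions: list[Interaction] = []
    for i, rec in enumerate(df.itertuples(index=False), start=2):  # row 1 is the header
        rec = rec._asdict()
        date = _parse_date(rec["Date"], i)
        time = _parse_time(rec["Time"], i) if has_time else None
        winner = rec["Winner"].strip()
        loser = rec["Loser"].strip()
        if winner == loser:
            raise ValueError(f"row {i}: winner equals loser ({winner!r})")
        k_raw = rec["K"].strip() if has_k else ""
        if k_raw:
            try:
                k = float(k_raw)
            except ValueError:
                raise ValueError(f"row {i}: unparseable K {k_raw!r}") from None
        else:
            k = default_k
        outcome_raw = rec["Outcome"].strip()
        if outcome_raw == "1":
            outcome = Outcome.DECIDED
        elif outcome_raw == "0":
            outcome = Outcome.DRAW
        else:
            raise ValueError(f"row {i}: Outcome must be 0 or 1, got {outcome_raw!r}")
        interactions.append(
            Interaction(date=date, time=time, winner_id=winner, loser_id=loser, k=k, outcome=outcome)
        )
    interactions.sort(key=lambda it: it.sort_key)  # stable: ties keep file order
    return interactions


def run_sequence(
    interactions: Sequence[Interaction],
    spec: PriorSpec | None = None,
    model: str = "normal",
    roster_override: Iterable[str] | None = None,
) -> SequenceResult:
    """Initialize ratings from priors and apply every interaction in order.

    The roster is ``roster_override`` if given, else the union of ids seen
    in the interactions and in the prior mappings.  With no priors every id
    starts at the baseline rating, reproducing the classic
    everyone-starts-equal behavior.
    """
    if spec is None:
        spec = PriorSpec()
    interaction_ids: set[str] = set()
    for it in interactions:
        interaction_ids.add(it.winner_id)
        interaction_ids.add(it.loser_id)
    roster = interaction_ids | spec.prior_ids()
    if roster_override is not None:
        override = set(roster_override)
        stray = interaction_ids - override
        if stray:
            raise ValueError(
                f"interactions reference ids outside roster_override: {sorted(stray)}"
            )
        roster = override

    keys = [it.sort_key for it in interactions]
    if any(a > b for a, b in zip(keys, keys[1:])):
        raise ValueError("interactions are not in chronological order")

    starting = derive_starting_ratings(spec, roster) if roster else {}
    state = RatingState(ratings=dict(starting))
    trajectory: list[TrajectoryRow] = []
    for idx, it in enumerate(interactions):
        before_w = state.ratings[it.winner_id]
        before_l = state.ratings[it.loser_id]
        update(state, it, model=model, event_index=idx)
        trajectory.append(
            TrajectoryRow(it.date, it.time, idx, it.winner_id, before_w, state.ratings[it.winner_id])
        )
        trajectory.append(
            TrajectoryRow(it.date, it.time, idx, it.loser_id, before_l, state.ratings[it.loser_id])
        )
    return SequenceResult(
        final_state=state,
        starting_ratings=starting,
        trajectory=trajectory,
        roster=roster,
        n_processed=len(interactions),
        events=list(interactions),
    )


def write_trajectory(result: SequenceResult, path: str | Path) -> None:
    """Write the per-event trajectory as long-format CSV.

    Columns: date, time, event_index, id, rating_before, rating_after; one
    row per participant per event, ordered by event index with the winner
    before the loser (bit-stable across runs).
    """
    result.to_frame().to_csv(path, index=False)


def read_trajectory(path: str | Path) -> SequenceResult:
    """Rebuild a :class:`SequenceResult` from a trajectory CSV.

    The reconstruction covers every id that appears in the file (starting
    rating = its first ``rating_before``); individuals that never interacted
    are not representable in the long format and are absent.
    """
    df = pd.read_csv(path, dtype={"date": str, "time": str, "id": str}, keep_default_na=False)
    missing = [c for c in _TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing trajectory column(s) {missing}")
    trajectory: list[TrajectoryRow] = []
    starting: dict[str, float] = {}
    state = RatingState()
    for i, rec in enumerate(df.itertuples(index=False), start=2):
        rec = rec._asdict()
        row = TrajectoryRow(
            date=_parse_date(rec["date"], i),
            time=_parse_time(rec["time"], i),
            event_index=int(rec["event_index"]),
            id=rec["id"],
            rating_before=float(rec["rating_before"]),
            rating_after=float(rec["rating_after"]),
        )
        trajectory.append(row)
        starting.setdefault(row.id, row.rating_before)
        state.ratings[row.id] = row.rating_after
        state.last_event[row.id] = (row.date, row.time)
    n_events = (max(r.event_index for r in trajectory) + 1) if trajectory else 0
    return SequenceResult(
        final_state=state,
        starting_ratings=starting,
        trajectory=trajectory,
        roster=set(starting),
        n_processed=n_events,
    )


def write_interactions(interactions: Sequence[Interaction], path: str | Path) -> None:
    """Write interactions in the standard datafile dialect (Date,Time,Winner,Loser,K,Outcome)."""
    df = pd.DataFrame(
        [
            (
                it.date.isoformat(),
                "" if it.time is None else it.time.strftime("%H:%M:%S"),
                it.winner_id,
                it.loser_id,
                f"{it.k:g}",
                1 if it.outcome is Outcome.DECIDED else 0,
            )
            for it in interactions
        ],
        columns=["Date", "Time", "Winner", "Loser", "K", "Outcome"],
    )
    df.to_csv(path, index=False)
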