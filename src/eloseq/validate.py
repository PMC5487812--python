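"""Check a modeled hierarchy against directional subordination signals.

Many species have a behavior whose direction unambiguously marks the
subordinate member of a dyad (the chimpanzee pant-grunt is the canonical
example: only the subordinate gives it).  If the Elo model is accurate, a
signal travelling from a *higher*-rated individual to a lower-rated one is a
categorical error — unless the two ratings are within the same "class
interval", the band of rating similarity inside which dominance is
considered undecided.  The report counts such inconsistencies, the number of
distinct dyads involved, and the mean +/- SD of the offending rating
differences, so hierarchies built under different assumptions can be
compared on the same signal record.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .extract import snapshot
from .sequence import SequenceResult, _parse_date, _parse_time

__all__ = [
    "SignalRecord",
    "ConsistencyReport",
    "read_signals",
    "write_signals",
    "consistency_report",
]


@dataclass(frozen=True)
class SignalRecord:
    """One directional subordination signal (signaller acknowledges recipient)."""

    date: _dt.date
    signaller: str
    recipient: str
    time: _dt.time | None = None

    def __post_init__(self) -> None:
        if self.signaller == self.recipient:
            raise ValueError(f"signaller equals recipient ({self.signaller!r}) on {self.date}")

    @property
    def sort_key(self) -> tuple:
        return (self.date, self.time if self.time is not None else _dt.time.max)


@dataclass
class ConsistencyReport:
    """Inconsistency statistics for one hierarchy against one signal record.

    An inconsistency is a signal whose signaller out-rates its recipient by
    more than ``class_interval`` on the signal's date.  ``diff_mean`` and
    ``diff_sd`` summarize the positive rating differences of inconsistent
    signals (``None`` when undefined: mean needs >= 1, SD needs >= 2).
    ``details`` lists one (date, signaller, recipient, signaller_rating,
    recipient_rating, difference) tuple per inconsistent signal.
    """

    n_signals: int
    n_inconsistencies: int
    n_inconsistent_dyads: int
    diff_mean: float | None
    diff_sd: float | None
    class_interval: float
    details: list[tuple] = field(default_factory=list)

    def summary(self) -> str:
        """One-line 'N (D)  mean +/- sd' summary."""
        if self.n_inconsistencies == 0:
            return "0 (0)"
        mean = f"{self.diff_mean:.2f}"
        if self.diff_sd is None:
            return f"{self.n_inconsistencies} ({self.n_inconsistent_dyads})  {mean}"
        return (
            f"{self.n_inconsistencies} ({self.n_inconsistent_dyads})  "
            f"{mean} ± {self.diff_sd:.2f}"
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (d.isoformat(), s, r, sr, rr, diff)
                for d, s, r, sr, rr, diff in self.details
            ],
            columns=[
                "date",
                "signaller",
                "recipient",
                "signaller_rating",
                "recipient_rating",
                "difference",
            ],
        )


def read_signals(path: str | Path) -> list[SignalRecord]:
    """Parse a signals CSV (Date,Time,Signaller,Recipient) into sorted records."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in ("Date", "Signaller", "Recipient") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    has_time = "Time" in df.columns
    records: list[SignalRecord] = []
    for i, rec in enumerate(df.itertuples(index=False), start=2):
        rec = rec._asdict()
        signaller = rec["Signaller"].strip()
        recipient = rec["Recipient"].strip()
        if signaller == recipient:
            raise ValueError(f"row {i}: signaller equals recipient ({signaller!r})")
        records.append(
            SignalRecord(
                date=_parse_date(rec["Date"], i),
                time=_parse_time(rec["Time"], i) if has_time else None,
                signaller=signaller,
                recipient=recipient,
            )
        )
    records.sort(key=lambda s: s.sort_key)
    return records


def write_signals(signals: Sequence[SignalRecord], path: str | Path) -> None:
    """Write signals in the standard CSV dialect."""
    df = pd.DataFrame(
        [
            (
                s.date.isoformat(),
                "" if s.time is None else s.time.strftime("%H:%M:%S"),
                s.signaller,
                s.recipient,
            )
            for s in signals
        ],
        columns=["Date", "Time", "Signaller", "Recipient"],
    )
    df.to_csv(path, index=False)


def consistency_report(
    result: SequenceResult,
    signals: Sequence[SignalRecord],
    class_interval: float = 0.0,
    include_same_day: bool = True,
) -> ConsistencyReport:
    """Count signals that contradict the modeled hierarchy.

    For each signal, both ids' ratings are looked up with day-snapshot
    semantics on the signal's date.  The signal is inconsistent iff
    ``signaller_rating - recipient_rating > class_interval``; two ids with
    exactly equal ratings are never inconsistent.  Dyads are counted as
    unordered pairs among the inconsistent signals.  The default
    ``class_interval`` of 0 counts every reversed-direction signal; the
    traditional chess value of 200 is a documented alternative.
    """
    if class_interval < 0:
        raise ValueError(f"class_interval must be >= 0, got {class_interval}")
    cache: dict[_dt.date, dict[str, float]] = {}
    details: list[tuple] = []
    dyads: set[frozenset] = set()
    for sig in signals:
        if sig.signaller not in result.roster:
            raise ValueError(f"unknown id {sig.signaller!r} in signals")
        if sig.recipient not in result.roster:
            raise ValueError(f"unknown id {sig.recipient!r} in signals")
        if sig.date not in cache:
            cache[sig.date] = snapshot(
                result, sig.date, include_same_day=include_same_day
            ).ratings
        ratings = cache[sig.date]
        diff = ratings[sig.signaller] - ratings[sig.recipient]
        if diff > class_interval:
            details.append(
                (sig.date, sig.signaller, sig.recipient,
                 ratings[sig.signaller], ratings[sig.recipient], diff)
            )
            dyads.add(frozenset((sig.signaller, sig.recipient)))
    diffs = np.array([d[-1] for d in details], dtype=float)
    diff_mean = float(diffs.mean()) if len(diffs) >= 1 else None
    diff_sd = float(diffs.std(ddof=1)) if len(diffs) >= 2 else None
    return ConsistencyReport(
        n_signals=len(signals),
        n_inconsistencies=len(details),
        n_inconsistent_dyads=len(dyads),
        diff_mean=diff_mean,
        diff_sd=diff_sd,
        class_interval=class_interval,
        details=details,
    )
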