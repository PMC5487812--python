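"""Single-interaction Elo updates for dyadic dominance data.

An Elo-rating is an interval-scale estimate of competitive ability that is
updated after every contest.  The winner gains, and the loser loses,
``(1 - p) * k`` points, where ``p`` is the winner's expected probability of
winning given the pre-contest rating difference and ``k`` scales how much a
single contest can move the ratings.  Here ``k`` is carried by each
interaction, so contests of different aggression intensity can be weighted
differently within one sequence.

Two expectation models are offered: the normal model (standard normal CDF of
the rating difference scaled by ``200 * sqrt(2)``, the Albers & de Vries
convention) and the classical logistic chess model (base-10 logistic with
scale 400).  Both give p = 0.5 at equal ratings and are strictly increasing
in the rating difference.
"""

from __future__ import annotations

import datetime as _dt
import enum
import math
from dataclasses import dataclass, field

__all__ = [
    "Outcome",
    "Interaction",
    "LogEntry",
    "RatingState",
    "expected_win_prob",
    "update",
]

_NORMAL_SCALE = 200.0 * math.sqrt(2.0)
_SQRT2 = math.sqrt(2.0)


class Outcome(str, enum.Enum):
    """Result of a dyadic agonistic interaction."""

    DECIDED = "decided"
    DRAW = "draw"


@dataclass(frozen=True)
class Interaction:
    """One dated win/loss (or draw) event with its own K factor.

    Parameters
    ----------
    date :
        Calendar date of the interaction.
    winner_id, loser_id :
        Case-sensitive individual identifiers.  For a draw the labels are
        arbitrary; the update rule is symmetric.
    k :
        Per-interaction K factor (> 0), typically reflecting the intensity
        of aggression displayed.
    outcome :
        ``Outcome.DECIDED`` (clear winner) or ``Outcome.DRAW``.
    time :
        Optional time of day, used only for chronological ordering.
    """

    date: _dt.date
    winner_id: str
    loser_id: str
    k: float = 200.0
    outcome: Outcome = Outcome.DECIDED
    time: _dt.time | None = None

    def __post_init__(self) -> None:
        if self.winner_id == self.loser_id:
            raise ValueError(
                f"winner and loser must differ (got {self.winner_id!r} on {self.date})"
            )
        if not (self.k > 0):
            raise ValueError(f"k must be positive, got {self.k!r}")
        if not isinstance(self.outcome, Outcome):
            raise ValueError(f"invalid outcome: {self.outcome!r}")

    @property
    def sort_key(self) -> tuple:
        """Chronological key; a missing time sorts to the end of its day."""
        return (self.date, self.time if self.time is not None else _dt.time.max)


@dataclass(frozen=True)
class LogEntry:
    """One participant's rating change at one event."""

    event_index: int
    id: str
    rating_before: float
    rating_after: float


@dataclass
class RatingState:
    """Current rating per individual plus the full update log."""

    ratings: dict[str, float] = field(default_factory=dict)
    last_event: dict[str, tuple] = field(default_factory=dict)
    log: list[LogEntry] = field(default_factory=list)

    def copy(self) -> "RatingState":
        return RatingState(dict(self.ratings), dict(self.last_event), list(self.log))


def expected_win_prob(rating_diff: float, model: str = "normal") -> float:
    """Expected probability that the higher-context individual wins.

    Parameters
    ----------
    rating_diff :
        Rating of the focal individual minus that of its opponent.
    model :
        ``"normal"``: standard normal CDF of ``rating_diff / (200 * sqrt(2))``.
        ``"logistic"``: ``1 / (1 + 10 ** (-rating_diff / 400))``.

    Both forms satisfy p(0) = 0.5 and p(d) + p(-d) = 1.
    """
    if not math.isfinite(rating_diff):
        raise ValueError(f"rating_diff must be finite, got {rating_diff!r}")
    if model == "normal":
        z = rating_diff / _NORMAL_SCALE
        return 0.5 * (1.0 + math.erf(z / _SQRT2))
    if model == "logistic":
        return 1.0 / (1.0 + 10.0 ** (-rating_diff / 400.0))
    raise ValueError(f"unknown expectation model: {model!r}")


def update(
    state: RatingState,
    interaction: Interaction,
    model: str = "normal",
    event_index: int = 0,
) -> RatingState:
    """Apply one interaction to the rating state (in place) and return it.

    For a decided outcome the winner gains ``(1 - p) * k`` and the loser
    loses the same amount, where ``p`` is the winner's expected win
    probability.  For a draw each participant moves by ``k * (0.5 - p_self)``;
    the two changes are exact negatives, so every update is zero-sum.

    Both participants must already hold ratings in ``state`` (initialization
    is the sequence runner's job).  Two log records are appended, winner
    first.
    """
    w, l = interaction.winner_id, interaction.loser_id
    try:
        rw = state.ratings[w]
        rl = state.ratings[l]
    except KeyError as exc:
        raise KeyError(f"participant {exc.args[0]!r} has no rating; initialize first") from None

    p_w = expected_win_prob(rw - rl, model)
    if interaction.outcome is Outcome.DECIDED:
        delta_w = (1.0 - p_w) * interaction.k
    elif interaction.outcome is Outcome.DRAW:
        delta_w = interaction.k * (0.5 - p_w)
    else:  # pragma: no cover - Interaction validates outcome
        raise ValueError(f"invalid outcome: {interaction.outcome!r}")

    state.ratings[w] = rw + delta_w
    state.ratings[l] = rl - delta_w
    stamp = (interaction.date, interaction.time)
    state.last_event[w] = stamp
    state.last_event[l] = stamp
    state.log.append(LogEntry(event_index, w, rw, state.ratings[w]))
    state.log.append(LogEntry(event_index, l, rl, state.ratings[l]))
    return state
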