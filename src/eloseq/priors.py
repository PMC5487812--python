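"""Starting Elo-ratings from prior dominance history.

When subjects were observed before the analysis window, that history can be
injected as starting ratings instead of launching everyone from a common
value (which forces a burn-in period).  Three forms of prior are supported,
processed in order of decreasing precision:

1. explicit Elo-ratings (used verbatim),
2. ordinal ranks (1 = most dominant, ties allowed),
3. ordered rank categories (alpha / high / medium / low), converted to
   ordinal ranks as alpha -> 1, high -> N/4, medium -> N/2, low -> N - N/4.

Rank-based priors are mapped to ratings by

    E_i = S_e + (x_r - S_ri) * K * S_ri ** (-I_r)

where ``S_e`` is the baseline starting rating, ``x_r`` the median of the
supplied ranks, ``S_ri`` individual *i*'s prior rank, ``K`` the rating-step
constant and ``I_r >= 0`` a reciprocal-power spreading index.  At ``I_r = 0``
consecutive ranks are spaced exactly ``K`` apart; larger ``I_r`` stretches
the top-ranked individual away from the rest while compressing the low
ranks.  The resulting ratings are recentered so that their mean over ranked
ids equals ``S_e``; unranked ids start at ``S_e`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

__all__ = [
    "RANK_CATEGORIES",
    "PriorSpec",
    "categorical_to_ordinal",
    "derive_starting_ratings",
    "load_prior_config",
]

#: Ordered rank categories, most dominant first.
RANK_CATEGORIES = ("alpha", "high", "medium", "low")


@dataclass
class PriorSpec:
    """Prior-history inputs plus the initialization parameters.

    At most one of the three prior mappings is consulted per run; explicit
    Elo-ratings take precedence over ordinal ranks, which take precedence
    over rank categories.
    """

    prior_elo: dict[str, float] = field(default_factory=dict)
    prior_ranks: dict[str, float] = field(default_factory=dict)
    prior_categories: dict[str, str] = field(default_factory=dict)
    starting_value: float = 1000.0  # S_e
    k: float = 200.0  # K in the initialization formula
    rank_index: float = 0.0  # I_r, reciprocal-power spreading index

    def __post_init__(self) -> None:
        if self.rank_index < 0:
            raise ValueError(f"rank_index (I_r) must be >= 0, got {self.rank_index}")
        if not (self.k > 0):
            raise ValueError(f"k must be positive, got {self.k}")
        for sid, rank in self.prior_ranks.items():
            if rank < 1:
                raise ValueError(f"ordinal rank for {sid!r} must be >= 1, got {rank}")
        for sid, cat in self.prior_categories.items():
            if cat not in RANK_CATEGORIES:
                raise ValueError(
                    f"unknown rank category {cat!r} for {sid!r}; "
                    f"expected one of {RANK_CATEGORIES}"
                )

    @property
    def has_priors(self) -> bool:
        return bool(self.prior_elo or self.prior_ranks or self.prior_categories)

    def prior_ids(self) -> set[str]:
        return set(self.prior_elo) | set(self.prior_ranks) | set(self.prior_categories)


def categorical_to_ordinal(
    categories: Mapping[str, str], n_subjects: int
) -> dict[str, float]:
    """Map ordered rank categories to (possibly fractional) ordinal ranks.

    alpha -> 1, high -> N/4, medium -> N/2, low -> N - N/4, with N the total
    number of subjects in the analysis.  Fractional ranks are kept unrounded
    so that the spacing of the four categories stays even regardless of N.
    Ids absent from ``categories`` are omitted (they later start at the
    baseline rating exactly).
    """
    if n_subjects < 1:
        raise ValueError(f"n_subjects must be >= 1, got {n_subjects}")
    if not categories:
        raise ValueError("categories mapping is empty")
    n = float(n_subjects)
    table = {"alpha": 1.0, "high": n / 4.0, "medium": n / 2.0, "low": n - n / 4.0}
    out: dict[str, float] = {}
    for sid, cat in categories.items():
        if cat not in table:
            raise ValueError(
                f"unknown rank category {cat!r} for {sid!r}; expected one of {RANK_CATEGORIES}"
            )
        out[sid] = table[cat]
    return out


def derive_starting_ratings(
    spec: PriorSpec | None, roster: Iterable[str]
) -> dict[str, float]:
    """Compute every roster member's starting Elo-rating from the priors.

    Precedence: explicit prior Elo-ratings, else ordinal ranks, else rank
    categories (converted via :func:`categorical_to_ordinal`), else everyone
    starts at ``S_e``.  For rank-based priors each ranked id gets

        E_i = S_e + (x_r - S_ri) * K * S_ri ** (-I_r)

    with ``x_r`` the median of the supplied ranks, after which all ranked
    ids are shifted by a common constant so their mean equals ``S_e``
    (centering preserves every pairwise difference, and is the identity in
    the symmetric complete-ranking case at ``I_r = 0``).  Unranked ids get
    ``S_e`` exactly.
    """
    roster = set(roster)
    if not roster:
        raise ValueError("roster is empty")
    if spec is None:
        spec = PriorSpec()
    unknown = spec.prior_ids() - roster
    if unknown:
        raise ValueError(
            f"prior mappings reference ids not in roster: {sorted(unknown)}"
        )

    s_e = float(spec.starting_value)
    ratings = {sid: s_e for sid in roster}

    if spec.prior_elo:
        ratings.update({sid: float(v) for sid, v in spec.prior_elo.items()})
        return ratings

    if spec.prior_ranks:
        ranks = {sid: float(r) for sid, r in spec.prior_ranks.items()}
    elif spec.prior_categories:
        ranks = categorical_to_ordinal(spec.prior_categories, len(roster))
    else:
        return ratings

    ids = sorted(ranks)
    s_ri = np.array([ranks[sid] for sid in ids], dtype=float)
    x_r = float(np.median(s_ri))
    raw = s_e + (x_r - s_ri) * spec.k * s_ri ** (-spec.rank_index)
    centered = raw + (s_e - raw.mean())
    ratings.update(dict(zip(ids, centered.tolist())))
    return ratings


_SCALAR_KEYS = {
    "starting_value": "starting_value",
    "startingvalue": "starting_value",
    "constant_k": "k",
    "k": "k",
    "prior_rank_index": "rank_index",
    "priorRankIndex": "rank_index",
}
_MAPPING_KEYS = {
    "prior_elo": "prior_elo",
    "priorElo": "prior_elo",
    "prior_ranks": "prior_ranks",
    "priorRanks": "prior_ranks",
    "prior_categories": "prior_categories",
    "priorRankCategory": "prior_categories",
}


class _StrictLoader(yaml.SafeLoader):
    """SafeLoader that rejects duplicate mapping keys instead of keeping the last."""


def _construct_mapping(loader, node, deep=False):
    mapping = {}
    for key_node, value_node in node.value:
        key = loader.construct_object(key_node, deep=deep)
        if key in mapping:
            raise ValueError(f"duplicate key {key!r} in prior config")
        mapping[key] = loader.construct_object(value_node, deep=deep)
    return mapping


_StrictLoader.add_constructor(
    yaml.resolver.BaseResolver.DEFAULT_MAPPING_TAG, _construct_mapping
)


def load_prior_config(path: str | Path) -> PriorSpec:
    """Read a prior-history config file (flat YAML) into a :class:`PriorSpec`.

    Recognized keys (R-style aliases in parentheses): ``starting_value``
    (``startingvalue``), ``k`` (``constant_k``), ``prior_rank_index``
    (``priorRankIndex``), and the three prior mappings ``prior_elo``
    (``priorElo``), ``prior_ranks`` (``priorRanks``), ``prior_categories``
    (``priorRankCategory``).  Ids are case-sensitive.  An empty file yields
    all defaults and no priors.  Unknown or duplicate keys raise a
    ``ValueError`` naming the offender.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.load(fh, Loader=_StrictLoader)
    if doc is None:
        return PriorSpec()
    if not isinstance(doc, dict):
        raise ValueError(f"prior config {path} must be a key-value document")

    kwargs: dict = {}
    for key, value in doc.items():
        if key in _SCALAR_KEYS:
            try:
                kwargs[_SCALAR_KEYS[key]] = float(value)
            except (TypeError, ValueError):
                raise ValueError(f"key {key!r}: expected a number, got {value!r}") from None
        elif key in _MAPPING_KEYS:
            if value is None:
                continue
            if not isinstance(value, dict):
                raise ValueError(f"key {key!r}: expected an id -> value mapping")
            field_name = _MAPPING_KEYS[key]
            if field_name == "prior_categories":
                kwargs[field_name] = {str(sid): str(v) for sid, v in value.items()}
            else:
                try:
                    kwargs[field_name] = {str(sid): float(v) for sid, v in value.items()}
                except (TypeError, ValueError):
                    raise ValueError(f"key {key!r}: non-numeric value in mapping") from None
        else:
            raise ValueError(f"unknown key {key!r} in prior config {path}")
    return PriorSpec(**kwargs)
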