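"""Shared fixtures: the published 9-interaction worked example and helpers."""

from __future__ import annotations

import math

import pytest
from hypothesis import settings

import eloseq as es

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")

# Nine dyadic interactions among five male chimpanzees (the standard
# worked-example datafile: ISO dates, per-row K, Outcome 1 = decided).
EXAMPLE_CSV = """\
Date,Time,Winner,Loser,K,Outcome
2003-08-10,15:34,ZF,TK,100,1
2003-10-13,08:56,DN,ZF,200,1
2003-10-16,08:44,ZF,TK,200,1
2003-10-24,09:11,ZF,MA,275,1
2003-10-28,11:09,ZF,NK,200,1
2003-10-28,11:11,DN,ZF,200,1
2003-10-28,11:12,ZF,TK,200,1
2003-10-28,12:05,NK,TK,200,1
2003-10-28,12:36,NK,TK,100,1
"""

EXAMPLE_IDS = {"ZF", "TK", "DN", "MA", "NK"}
EXAMPLE_K = [100, 200, 200, 275, 200, 200, 200, 200, 100]


def brute_force_sequence(rows, start=1000.0):
    """Independent straight-line oracle: sequential normal-model updates.

    ``rows`` are (winner, loser, k) triples in chronological order.  Uses
    math.erf directly, no package code.
    """
    ids = {x for w, l, _ in rows for x in (w, l)}
    r = {i: float(start) for i in ids}
    history = []
    for w, l, k in rows:
        z = (r[w] - r[l]) / (200.0 * math.sqrt(2.0))
        p = 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))
        r[w] += (1.0 - p) * k
        r[l] -= (1.0 - p) * k
        history.append(dict(r))
    return r, history


@pytest.fixture
def example_csv(tmp_path):
    path = tmp_path / "example_interactions.csv"
    path.write_text(EXAMPLE_CSV)
    return path


@pytest.fixture
def example_interactions(example_csv):
    return es.read_interactions(example_csv)


@pytest.fixture
def example_result(example_interactions):
    return es.run_sequence(example_interactions)


@pytest.fixture
def example_oracle():
    """Brute-force final ratings and per-event history for the worked example."""
    rows = [
        ("ZF", "TK", 100), ("DN", "ZF", 200), ("ZF", "TK", 200),
        ("ZF", "MA", 275), ("ZF", "NK", 200), ("DN", "ZF", 200),
        ("ZF", "TK", 200), ("NK", "TK", 200), ("NK", "TK", 100),
    ]
    return brute_force_sequence(rows)
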