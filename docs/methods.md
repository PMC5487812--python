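# Methods

## The rating model

eloseq models social dominance as a sequence of pairwise contests. Each
individual *i* carries a real-valued Elo-rating *Rᵢ* (unbounded; negative
values are legal). For a decided contest between winner *w* and loser *l*
with per-interaction factor *K*:

    p  = P(w wins | R_w − R_l)
    R_w ← R_w + (1 − p)·K
    R_l ← R_l − (1 − p)·K

Draws are supported symmetrically: each participant moves by
`K·(0.5 − p_self)`, the two changes being exact negatives. Every update is
therefore zero-sum, and the sum of ratings is invariant over a whole run
(the test suite verifies drift < 1e−6 over 10,000 events; in practice it is
at round-off, ~1e−11).

Two expectation models are provided because the literature uses both and
the choice is an assumption worth making explicit:

* **normal** (default): `p = Φ(d / (200·√2))` — the convention of the
  lineage this package follows; 200 is the traditional class interval, so
  a one-class advantage wins with p ≈ 0.76.
* **logistic**: `p = 1 / (1 + 10^(−d/400))` — the classical chess rule.

Both satisfy `p(0) = 0.5`, `p(d) + p(−d) = 1`, and strict monotonicity in
*d*; switching models changes numbers slightly but never the qualitative
behavior. Which of the two the original R implementation used is not
documented; offering both was the deliberate resolution.

## Starting ratings from prior history

Three prior forms, processed in precedence order (explicit Elo > ordinal
ranks > ordered categories), mirror decreasing knowledge. Rank-based priors
pass through

    E_i = S_e + (x_r − S_ri) · K · S_ri^(−I_r)

with `x_r` the median of the supplied ranks. Parameters, units and
defaults:

| parameter | meaning | default |
|---|---|---|
| `S_e` (starting_value) | baseline rating, Elo points | 1000 |
| `K` (k) | initialization step, Elo points per rank at `I_r=0` | 200 |
| `I_r` (rank_index) | reciprocal-power spreading index, dimensionless ≥ 0 | 0 |

`I_r = 0` spaces complete ranks exactly `K` apart. Increasing `I_r`
stretches the top-ranked individual away (despotic top) and compresses low
ranks (egalitarian bottom); 0.3 is a reasonable field value and is used in
the example configs. Ordered categories map to fractional ordinal ranks
`alpha → 1, high → N/4, medium → N/2, low → N − N/4` (N = roster size),
kept unrounded to avoid spurious ties.

**Centering.** The source description says only that ratings are "centered"
on the baseline; we define this as shifting all *ranked* ids by a common
constant so their mean equals `S_e`. This preserves every pairwise
difference the formula produced and reduces to the identity for complete
symmetric rankings at `I_r = 0`. Unranked ids receive `S_e` exactly and do
not enter the median or the centering — they represent individuals about
whom nothing is known.

Tied ranks are allowed and yield identical starting ratings. `x_r` is the
median of the supplied rank values as given (ties included).

## Sequence processing

The interaction file dialect is `Date,Time,Winner,Loser,K,Outcome` with ISO
dates, optional times, case-sensitive ids, blank K falling back to the
run-wide default, and Outcome 1/0 for decided/draw. Rows are stably sorted
by (date, time); a missing time sorts to the end of its day; equal
timestamps keep file order — processing is therefore deterministic, and
permuting rows of a file with unique timestamps cannot change the result.
Individuals appearing only in priors keep their starting rating and appear
in all outputs.

## Daily snapshots and burn-in

Ratings are piecewise constant between events, so a day's snapshot is each
id's rating after the last event at or before end of that day. Whether the
day's *own* events count is switchable (`include_same_day`, default on —
the conservative choice when comparing same-day observations such as
signals against daily ranks; both semantics are exposed because field
protocols differ). Ordinal ranks use competition ranking (1, 2, 2, 4): tied
ratings genuinely mean undecided relative positions, so both get the better
rank.

`detect_burn_in(window_days=30, tolerance=25)` returns the earliest date
from which, over one window, the top-rated individual's identity never
changes and its largest day-over-day rating change is ≤ tolerance. The
defaults — a month of stability, 1/8 of the default K — are pragmatic
conventions for a chimpanzee-like interaction rate, not estimates; they
should be tuned to the organism. The detector is monotone in tolerance. If
the whole sequence is shorter than one window the single spanning window is
evaluated. Alpha-identity ties are broken by id order, consistently with
the ranking convention.

## Signal validation

A directional subordination signal (the pant-grunt analog) from *s* to *r*
is *inconsistent* iff `rating(s) − rating(r) > class_interval` on the
signal's date (same snapshot semantics as above). The default
`class_interval = 0` counts every reversed-direction signal — even a
9-point reversal — because the validation question is categorical error,
not class structure; the traditional 200-point class interval is the
documented alternative for treating near-equals as undecided. Equal ratings
are never inconsistent. Dyads are counted as unordered pairs among
inconsistent signals; the mean ± SD summarizes the positive rating
differences of the offenders (SD is the sample SD, undefined for a single
inconsistency).

## The simulator

The synthetic module generates the study conditions all tests run under:

* latent strengths evenly spaced one unit apart (descending with id order),
  so `steepness` is directly the log-odds of an adjacent-rank upset;
  default steepness ln 4 ≈ 1.386 gives the adjacent win probability 0.8
  used in the recovery experiments;
* `n = 10` individuals, `2000` events over `300` days by default — a
  moderately sampled field season; events spread uniformly over days,
  within-day order = event order, one-second time steps from 06:00 so CSV
  round-trips preserve ordering;
* the winner of each uniformly sampled dyad is drawn from a logistic in the
  latent strength difference — deliberately *not* the expectation model
  being fitted, to avoid circularity; an optional `rank_bias` oversamples
  high-rankers as focal-follow protocols do;
* each event's K is drawn from the reference intensity mixture: categories
  (50, 100, 150, 175, 200, 225, 250, 300, 375) with weights proportional to
  observed counts (38, 53, 5, 22, 125, 97, 26, 35, 4 of 405) — mild threats
  common, targeted charging displays (K = 200) the mode, prolonged wounding
  attacks rare;
* signals are emitted subordinate → dominant at `signal_rate` per event,
  reversed with probability `signal_error_rate` to plant known errors.

What the simulator does **not** emulate: fission–fusion party structure and
observation gaps, escalation dynamics within interactions, rank change over
time (the latent order is static), individual variation in aggressiveness,
and observer error in winner/loser assignment. Passing tests therefore show
that the machinery recovers a *static linear* hierarchy from noisy wins and
losses under realistic event rates and K mixtures — not that any particular
field data set is well described by it.

## Numerical and design notes

* Expected probabilities use `math.erf`; no iteration, no tolerance knobs.
* The zero-sum property is exact up to float round-off because both
  participants receive the same `Δ` with opposite signs.
* Problem sizes in the test suite (10,000-event conservation runs, 20-seed
  recovery and burn-in studies) were chosen as the smallest sizes at which
  the studied effects are unambiguous; the whole suite runs in well under a
  minute.
* Exact-order recovery (every rank correct) is only expected under a steep
  hierarchy; at adjacent win probability 0.8 the final ordering of close
  neighbors legitimately fluctuates, which is why the rank-recovery
  criterion is a Spearman correlation at 0.8 steepness but the exact-order
  test uses 0.95, and the zero-inconsistency signal check uses 0.99 (a
  near-deterministic hierarchy, i.e. a genuinely converged model).
* Burn-in contrast at the default event density (≈7/day) often yields equal
  burn-in dates for prior and no-prior runs — with that much data both
  converge fast; at sparser, more field-realistic densities (1–3 events per
  day) priors move the detected date strictly earlier in most replicates
  and never later in any pilot.

## Known limitations

* `read_trajectory` reconstructs a run from its long-format CSV; ids that
  never interacted are not representable there, so the file-based
  `eloseq extract`/`eloseq validate` commands cover only interacting
  individuals — use the in-process API when prior-only individuals matter.
* K values are taken as given; estimating them (e.g. by maximum likelihood,
  or deriving `I_r` from hierarchy-steepness measures) is out of scope.
* Subordination signals are used for validation only, never as rating
  updates; whether and with what K such signals should update ratings is an
  open scientific question the package deliberately does not answer.
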