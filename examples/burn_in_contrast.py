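"""Demonstrate the burn-in problem and its fix on one simulated event stream.

The same 600-event sequence (10 individuals over 300 days — a sparse,
field-realistic two contests per day — adjacent-rank win probability 0.8,
intensity-mixture K values) is analyzed twice: once with every individual
starting at 1000, and once seeding starting ratings from the true latent
order as ordinal priors.  With priors the day-one ranks are already correct
and the alpha's trajectory stabilizes months earlier than in the default
run, whose early ratings all fall inside the burn-in period.
"""

import eloseq as es

cfg = es.SimConfig(n_events=600, days=300, seed=2)
interactions, _, latent_order = es.simulate(cfg)

no_prior = es.run_sequence(interactions)
spec = es.PriorSpec(prior_ranks={sid: i + 1 for i, sid in enumerate(latent_order)})
with_prior = es.run_sequence(interactions, spec=spec)

day0 = interactions[0].date
flat = es.snapshot(no_prior, day0, include_same_day=False)
seeded = es.snapshot(with_prior, day0, include_same_day=False)
print(f"latent order: {' > '.join(latent_order)}")
print(f"day-one ranks, no priors:   all tied "
      f"({sorted(set(flat.ratings.values()))[0]:.0f} points each)")
print(f"day-one ranks, with priors: "
      f"{[seeded.ordinal_ranks[sid] for sid in latent_order]}")

d_default = es.detect_burn_in(no_prior)
d_prior = es.detect_burn_in(with_prior)
print(f"\nburn-in end (30-day window, 25-point tolerance):")
print(f"  default start : {d_default}")
print(f"  with priors   : {d_prior}")
print("\nRatings before the burn-in end are unreliable and should be discarded;")
print("prior history moves that boundary earlier (or removes it).")
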