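"""Validate a modeled hierarchy against directional subordination signals.

A steep hierarchy is simulated with an error-free subordinate-to-dominant
signal channel plus a second run where 25% of signals are planted in the
reversed direction.  The consistency report counts signals whose signaller
out-rates its recipient on the signal's day — categorical errors unless the
two fall within the same rating class.
"""

import eloseq as es

base = dict(n_individuals=6, n_events=600, days=150, signal_rate=0.4,
            steepness=es.steepness_for_adjacent_p(0.99), seed=7)

for error_rate in (0.0, 0.25):
    cfg = es.SimConfig(signal_error_rate=error_rate, **base)
    interactions, signals, latent_order = es.simulate(cfg)
    spec = es.PriorSpec(prior_ranks={sid: i + 1 for i, sid in enumerate(latent_order)})
    result = es.run_sequence(interactions, spec=spec)

    burn_end = es.detect_burn_in(result)
    late = [s for s in signals if burn_end is None or s.date > burn_end]
    report = es.consistency_report(result, late)
    print(f"signal error rate {error_rate:4.0%}: "
          f"{len(late)} post-burn-in signals -> "
          f"inconsistencies (dyads)  {report.summary()}")

print("\nFormat mirrors the conventional 'N (dyads)  mean ± SD' layout: with an")
print("error-free channel the converged model shows no reversals; planted")
print("reversed signals are flagged, with the rating gap of each offender.")
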