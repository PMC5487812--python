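"""Process the worked-example interaction file and print the final hierarchy.

Nine dyadic interactions among five males, each with its own K value, run
with everyone starting at 1000 (no prior history) and the normal expectation
model.  The printed ratings are interval-scale competitive-ability scores;
the ranks are their descending order on the last observation day.
"""

from pathlib import Path

import eloseq as es

DATA = Path(__file__).parent / "data" / "example_interactions.csv"

interactions = es.read_interactions(DATA)
result = es.run_sequence(interactions)
final_day = es.snapshot(result, result.last_date)

print(f"{result.n_processed} interactions, {len(result.roster)} individuals\n")
print(f"{'id':>4} {'final rating':>14} {'rank':>6}")
for sid in sorted(result.roster, key=lambda s: final_day.ordinal_ranks[s]):
    print(f"{sid:>4} {final_day.ratings[sid]:>14.2f} {final_day.ordinal_ranks[sid]:>6}")

total = sum(result.final_state.ratings.values())
print(f"\nrating sum {total:.6f} (conserved: started at {5 * 1000})")
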