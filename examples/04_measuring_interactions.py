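"""Measuring pairwise interactions across community contexts.

Runs the reduced interaction study (nested single-dropout subcommunities of
an eight-isolate community, observed with sequencing and plating noise),
computes both interaction metrics for every comparable context pair, prunes
outliers, and summarizes the distribution of interaction strengths and the
coexistence screen.
"""

import numpy as np

from commix import (
    compute_all_interactions,
    prune_outliers,
    screen_context_dependence,
)
from commix.scenarios import nested_noisy_study

profiles = nested_noisy_study(seed=1)
print(f"{len(profiles)} observed community profiles "
      f"({len({p.design_id for p in profiles})} designs x replicates)")

records = compute_all_interactions(profiles)
print(f"{len(records)} interactions measured "
      f"(context pairs differing by one isolate)")

kept_pop = prune_outliers(records, measure="pop_log", z_max=1.0)
kept_pc = prune_outliers(records, measure="per_capita", z_max=1.0)
pop = np.array([r.pop_effect for r in kept_pop])
pc = np.array([r.per_capita for r in kept_pc])

print(f"\nafter +-1 SD pruning per measure:")
print(f"  population effect (ratio - 1): n={len(pop)}, "
      f"median {np.median(pop):+.3f}, {100 * np.mean(pop < 0):.0f}% negative")
print(f"  per-capita effect:             n={len(pc)}, "
      f"median {np.median(pc):+.3f}, {100 * np.mean(pc < 0):.0f}% negative")

example = max(kept_pop, key=lambda r: abs(r.pop_effect))
print(f"\nstrongest retained interaction: {example.interactor} on "
      f"{example.focal} in context {example.richness_context}")
print(f"  focal density {example.n_without:.0f} -> {example.n_with:.0f} CFU/uL, "
      f"pop effect {example.pop_effect:+.2f}, per-capita {example.per_capita:+.3f}")

# screen community-level (replicate-aggregated) profiles for context-
# dependent coexistence, as when choosing which communities to decompose
from collections import defaultdict

from commix import aggregate_replicates

by_design = defaultdict(list)
for p in profiles:
    by_design[p.design_id].append(p)
aggregates = [aggregate_replicates(reps) for reps in by_design.values()]
calls = screen_context_dependence(aggregates)
print(f"\ncoexistence screen over {len(aggregates)} communities: "
      f"{len(calls)} (focal, excluder, context) calls where a focal coexists "
      f"with an isolate in one community but is excluded in another "
      f"containing it")
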