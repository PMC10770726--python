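"""Combinatorial community design: pools, pool combinations, and nested
single-dropout decomposition.

Builds the full-scale design — 56 isolates over 21 genera, randomly split
into 7 pools of 8, combined into all 127 pool combinations — then decomposes
one community around a focal/excluder pair into nested subcommunities that
differ by a single isolate, the unit of interaction measurement.
"""

from commix import (
    enumerate_pool_combinations,
    make_pools,
    nested_decomposition,
    synthetic_catalog,
)

catalog = synthetic_catalog(n_isolates=56, n_genera=21, seed=1)
catalog = make_pools(catalog, n_pools=7, pool_size=8, seed=1)
designs = enumerate_pool_combinations(catalog)

by_n_pools = {}
for d in designs:
    by_n_pools.setdefault(len(d.members) // 8, []).append(d)
print(f"{len(designs)} communities from 7 pools")
for k in sorted(by_n_pools):
    print(f"  {len(by_n_pools[k]):3d} communities using {k} pool(s)")

superset = next(d for d in designs if d.richness == 16)
focal, excluder = sorted(superset.members)[:2]
chain = nested_decomposition(superset, focal, excluder, max_communities=9, seed=1)
print(f"\nnested decomposition of {superset.design_id} around ({focal}, {excluder}):")
for prev, d in zip([None] + chain[:-1], chain):
    step = ""
    if prev is not None:
        (changed,) = prev.members ^ d.members
        step = f"  ({'+' if changed in d.members else '-'}{changed})"
    print(f"  richness {d.richness:2d}: {d.design_id[:60]}{step}")

# Each consecutive pair differs by exactly one isolate, so the effect of that
# isolate on every shared member is measurable at every richness step.
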