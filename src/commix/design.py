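"""Combinatorial community design.

Implements the experimental design logic of the study system: isolates are
randomly partitioned into equal-sized pools, every nonempty combination of
pools defines a community, and communities showing context-dependent
coexistence are decomposed into nested subcommunities that differ by a single
isolate — the unit of comparison for interaction measurement.  All initial
states are equal-titer: each member receives the same share of a fixed total
inoculum.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .catalog import IsolateCatalog

__all__ = [
    "CommunityDesign",
    "PassageProtocol",
    "make_pools",
    "enumerate_pool_combinations",
    "nested_decomposition",
    "initial_state",
]

DEFAULT_TOTAL_TITER = 1e6  # cells inoculated per community


@dataclass(frozen=True)
class CommunityDesign:
    """Declared initial membership of one community.

    ``per_member_titer`` is implied: every member receives
    ``initial_total_titer / |members|`` cells (equal-proportion inoculation).
    """

    design_id: str
    members: frozenset[str]
    initial_total_titer: float = DEFAULT_TOTAL_TITER
    replicate: int = 1

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"design {self.design_id!r} has no members")
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")

    @property
    def richness(self) -> int:
        return len(self.members)

    @property
    def per_member_titer(self) -> float:
        return self.initial_total_titer / len(self.members)

    def with_replicate(self, replicate: int) -> "CommunityDesign":
        return CommunityDesign(
            self.design_id, self.members, self.initial_total_titer, replicate
        )


@dataclass(frozen=True)
class PassageProtocol:
    """Serial-passage schedule: dilute ``dilution_factor`` into fresh medium
    every ``cycle_hours`` for ``n_cycles`` growth cycles (default 1:100 / 24 h
    / 6 cycles)."""

    dilution_factor: float = 0.01
    cycle_hours: float = 24.0
    n_cycles: int = 6

    def __post_init__(self) -> None:
        if not (0 < self.dilution_factor < 1):
            raise ValueError("dilution_factor must be in (0, 1)")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")


def make_pools(
    catalog: IsolateCatalog, n_pools: int, pool_size: int, seed: int
) -> IsolateCatalog:
    """Randomly partition all isolates into ``n_pools`` disjoint pools of
    ``pool_size`` members each.

    Deterministic given ``seed``.  Returns a new catalog with pool ids 1..n.
    """
    n = len(catalog)
    if n_pools * pool_size != n:
        raise ValueError(
            f"cannot split {n} isolates into {n_pools} pools of {pool_size} "
            f"({n_pools} x {pool_size} = {n_pools * pool_size} != {n})"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    pool_ids = [0] * n
    for rank, idx in enumerate(order):
        pool_ids[idx] = rank // pool_size + 1
    return IsolateCatalog(
        isolate_ids=list(catalog.isolate_ids),
        genera=list(catalog.genera),
        pool_ids=pool_ids,
    )


def enumerate_pool_combinations(
    catalog: IsolateCatalog, total_titer: float = DEFAULT_TOTAL_TITER
) -> list[CommunityDesign]:
    """All 2^n - 1 nonempty pool combinations as community designs.

    Members of a design are the union of the member isolates of its pools;
    design ids name the pools joined by '+', e.g. ``P1+P3``.
    """
    pools = catalog.pools
    if not pools:
        raise ValueError("catalog has no pools assigned; run make_pools first")
    pool_ids = sorted(pools)
    designs = []
    for k in range(1, len(pool_ids) + 1):
        for combo in itertools.combinations(pool_ids, k):
            members = frozenset(
                iso for pid in combo for iso in pools[pid]
            )
            design_id = "+".join(f"P{pid}" for pid in combo)
            designs.append(
                CommunityDesign(design_id, members, initial_total_titer=total_titer)
            )
    return designs


def _design_id_for(members: frozenset[str]) -> str:
    return "+".join(sorted(members))


def nested_decomposition(
    superset: CommunityDesign,
    focal: str,
    excluder: str,
    max_communities: int | None = None,
    seed: int = 0,
) -> list[CommunityDesign]:
    """Decompose a community into nested subcommunities around a focal isolate
    and its putative excluder.

    Background isolates (everything except focal and excluder) are added one
    at a time in a seeded random order.  At each background level ``B`` three
    designs are emitted — ``B+{focal}``, ``B+{focal,excluder}``, ``B+{excluder}``
    — so the focal/excluder interaction is measurable at every richness step.
    The returned list is ordered as a chain in which consecutive designs differ
    by exactly one isolate (within a level: add excluder, drop focal; between
    levels: add the next background isolate), zig-zagging direction per level.

    ``max_communities`` truncates the chain after that many designs, mirroring
    the fact that real decompositions are non-exhaustive.
    """
    if focal not in superset.members:
        raise ValueError(f"focal {focal!r} not in superset members")
    if excluder not in superset.members:
        raise ValueError(f"excluder {excluder!r} not in superset members")
    if focal == excluder:
        raise ValueError("focal and excluder must differ")

    background = sorted(superset.members - {focal, excluder})
    rng = np.random.default_rng(seed)
    rng.shuffle(background)

    chain: list[frozenset[str]] = []
    level_sets: list[frozenset[str]] = [frozenset()]
    for k in range(len(background)):
        level_sets.append(frozenset(background[: k + 1]))
    for level, bg in enumerate(level_sets):
        triple = [
            bg | {focal},
            bg | {focal, excluder},
            bg | {excluder},
        ]
        if level % 2 == 1:  # zig-zag so the inter-level step is one addition
            triple.reverse()
        chain.extend(frozenset(s) for s in triple)
    if max_communities is not None:
        chain = chain[:max_communities]
    return [
        CommunityDesign(
            _design_id_for(members),
            members,
            initial_total_titer=superset.initial_total_titer,
        )
        for members in chain
    ]


def initial_state(design: CommunityDesign, catalog: IsolateCatalog) -> np.ndarray:
    """Equal-titer initial cell counts in catalog order; non-members get 0."""
    state = np.zeros(len(catalog))
    share = design.per_member_titer
    for iso in design.members:
        state[catalog.index_of(iso)] = share
    return state


def with_replicates(
    designs: list[CommunityDesign], n_replicates: int
) -> list[CommunityDesign]:
    """Expand each design into ``n_replicates`` replicate designs."""
    return [d.with_replicate(r) for d in designs for r in range(1, n_replicates + 1)]
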