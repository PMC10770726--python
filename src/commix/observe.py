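"""Observation models: shotgun sequencing counts and CFU plate counts.

Sequencing is modeled at the count level: reads are multinomial over the true
relative abundances; within each configured "ambiguity set" (groups of
isolates whose genomes are similar enough that reads cannot be uniquely
assigned) a fraction of each member's reads is moved to a shared "tossed"
pool, exactly the information loss the downstream reallocation step corrects.

Total community density is observed by plating a serial-dilution triplicate:
colony counts are Poisson around true density x dilution x plated volume,
with a lognormal plating-efficiency multiplier of configurable CV; the
density estimate is the mean back-calculated CFU/uL over all plates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SequencingObservation",
    "CfuObservation",
    "ExactObservation",
    "observe_sequencing",
    "observe_cfu",
    "observe_exact",
    "DEFAULT_DILUTIONS",
]

# Dilution series used for plate counting, in triplicate each.
DEFAULT_DILUTIONS = (3e-5, 1e-6, 3e-6)
DEFAULT_PLATED_VOLUME = 100.0  # uL spread per plate
DEFAULT_DEPTH = 50_000  # reads per sample


@dataclass
class SequencingObservation:
    """Per-isolate unambiguous read counts plus per-set tossed read pools."""

    isolate_ids: list[str]
    counts: np.ndarray  # unambiguous reads per isolate
    ambiguity_sets: list[frozenset[str]] = field(default_factory=list)
    tossed: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if np.any(self.counts < 0):
            raise ValueError("negative read counts")
        seen: set[str] = set()
        for s in self.ambiguity_sets:
            if seen & s:
                raise ValueError(f"ambiguity sets overlap: {sorted(seen & s)}")
            seen |= s
        if len(self.tossed) != len(self.ambiguity_sets):
            raise ValueError("one tossed count per ambiguity set required")

    @property
    def total_reads(self) -> int:
        return int(self.counts.sum()) + int(sum(self.tossed))


@dataclass
class CfuObservation:
    """Colony counts per (dilution, replicate plate) and the derived total
    density estimate in CFU/uL."""

    dilutions: tuple[float, ...]
    counts: np.ndarray  # (n_dilutions, n_plate_replicates) integer colonies
    plated_volume: float
    estimate: float = field(init=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if np.any(self.counts < 0):
            raise ValueError("negative colony counts")
        per_plate = self.counts / (
            np.asarray(self.dilutions)[:, None] * self.plated_volume
        )
        self.estimate = float(per_plate.mean())


@dataclass
class ExactObservation:
    """Noise-free observation of a final state: exact relative abundances and
    exact total density.  Used when observation noise is switched off."""

    isolate_ids: list[str]
    relative: np.ndarray
    total_density: float


def observe_sequencing(
    final_state: np.ndarray,
    isolate_ids: list[str],
    depth: int = DEFAULT_DEPTH,
    ambiguity_sets: list[frozenset[str]] | None = None,
    ambiguous_fraction: float = 0.0,
    seed: int = 0,
) -> SequencingObservation:
    """Draw ``depth`` reads multinomially from the true composition, then move
    ``ambiguous_fraction`` of each ambiguity-set member's reads (binomially)
    into the set's shared tossed pool."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    final_state = np.asarray(final_state, dtype=float)
    total = final_state.sum()
    if total <= 0:
        raise ValueError("cannot sequence an empty community")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(depth, final_state / total)

    ambiguity_sets = list(ambiguity_sets or [])
    index = {iso: i for i, iso in enumerate(isolate_ids)}
    tossed = []
    for s in ambiguity_sets:
        pool = 0
        for iso in s:
            i = index[iso]
            if ambiguous_fraction > 0 and counts[i] > 0:
                moved = rng.binomial(counts[i], ambiguous_fraction)
                counts[i] -= moved
                pool += int(moved)
        tossed.append(pool)
    return SequencingObservation(
        isolate_ids=list(isolate_ids),
        counts=counts,
        ambiguity_sets=ambiguity_sets,
        tossed=tossed,
    )


def observe_cfu(
    final_state: np.ndarray,
    plating_cv: float = 0.1,
    seed: int = 0,
    dilutions: tuple[float, ...] = DEFAULT_DILUTIONS,
    n_plate_replicates: int = 3,
    plated_volume: float = DEFAULT_PLATED_VOLUME,
) -> CfuObservation:
    """Observe total community density by dilution plating.

    Expected colonies per plate are ``true_total * dilution * plated_volume``.
    With ``plating_cv > 0`` counts are Poisson with a lognormal efficiency
    multiplier (mean 1, CV ``plating_cv``); with ``plating_cv == 0`` counts are
    the rounded expectations — a fully deterministic, noise-off observation.
    """
    true_total = float(np.asarray(final_state, dtype=float).sum())
    rng = np.random.default_rng(seed)
    lam = true_total * np.asarray(dilutions)[:, None] * plated_volume
    lam = np.broadcast_to(lam, (len(dilutions), n_plate_replicates))
    if plating_cv == 0:
        counts = np.rint(lam).astype(np.int64)
    else:
        sigma2 = np.log1p(plating_cv**2)
        eff = np.exp(
            rng.normal(-sigma2 / 2, np.sqrt(sigma2), size=lam.shape)
        )
        counts = rng.poisson(lam * eff)
    return CfuObservation(
        dilutions=tuple(dilutions), counts=counts, plated_volume=plated_volume
    )


def observe_exact(
    final_state: np.ndarray, isolate_ids: list[str]
) -> ExactObservation:
    """Noise-off observation: exact relative abundances and total density."""
    final_state = np.asarray(final_state, dtype=float)
    total = final_state.sum()
    rel = final_state / total if total > 0 else np.zeros_like(final_state)
    return ExactObservation(
        isolate_ids=list(isolate_ids), relative=rel, total_density=float(total)
    )
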