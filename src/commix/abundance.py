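"""From raw observations to per-isolate absolute densities.

Three steps mirror the study's accounting: (1) tossed (ambiguously mapped)
reads are reallocated within each ambiguity set in proportion to the members'
unambiguous counts; (2) isolates with less than 1% of total mapped reads are
treated as absent and the remaining relative abundances renormalized;
(3) relative abundances are scaled by the plate-count estimate of total
community density to give absolute densities in CFU/uL.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .observe import CfuObservation, ExactObservation, SequencingObservation

__all__ = [
    "ObservedProfile",
    "reallocate_ambiguous",
    "detect_members",
    "to_absolute",
    "aggregate_replicates",
    "profile_from_exact",
]

logger = logging.getLogger(__name__)

DETECTION_THRESHOLD = 0.01


@dataclass
class ObservedProfile:
    """Final-passage composition of one community (one replicate, or an
    aggregate over replicates).

    ``relative_abundance`` sums to 1 over detected members;
    ``absolute_density[iso] = relative_abundance[iso] * total_density``.
    ``designed_members`` (when known) is the inoculated membership, used by the
    coexistence screen to distinguish exclusion from never-inoculated.
    """

    design_id: str
    replicate: int
    relative_abundance: dict[str, float]
    total_density: float
    designed_members: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if self.relative_abundance:
            s = sum(self.relative_abundance.values())
            if abs(s - 1.0) > 1e-9:
                raise ValueError(
                    f"relative abundances sum to {s!r}, not 1 "
                    f"(design {self.design_id}, rep {self.replicate})"
                )
        if self.total_density < 0:
            raise ValueError("total_density must be >= 0")
        if self.designed_members is not None:
            extra = set(self.relative_abundance) - set(self.designed_members)
            if extra:
                raise ValueError(
                    f"detected members not in design: {sorted(extra)}"
                )

    @property
    def detected_members(self) -> frozenset[str]:
        return frozenset(self.relative_abundance)

    @property
    def richness(self) -> int:
        return len(self.relative_abundance)

    @property
    def absolute_density(self) -> dict[str, float]:
        return {
            iso: rel * self.total_density
            for iso, rel in self.relative_abundance.items()
        }

    def density_of(self, isolate_id: str) -> float:
        return self.relative_abundance.get(isolate_id, 0.0) * self.total_density


def _largest_remainder(quotas: np.ndarray, total: int) -> np.ndarray:
    """Round nonnegative quotas (summing to ``total``) to integers that sum to
    exactly ``total``."""
    floors = np.floor(quotas).astype(np.int64)
    short = total - int(floors.sum())
    if short > 0:
        order = np.argsort(-(quotas - floors), kind="stable")
        floors[order[:short]] += 1
    return floors


def reallocate_ambiguous(
    obs: SequencingObservation, fractional: bool = False
) -> dict[str, float]:
    """Redistribute each ambiguity set's tossed reads over its members in
    proportion to their unambiguous counts.

    Isolates outside any set are untouched; total reads are conserved exactly
    (largest-remainder rounding in the default integer mode).  If a set has no
    unambiguous reads at all its tossed pool is split equally.
    """
    counts = {iso: float(c) for iso, c in zip(obs.isolate_ids, obs.counts)}
    index = {iso: i for i, iso in enumerate(obs.isolate_ids)}
    for members, tossed in zip(obs.ambiguity_sets, obs.tossed):
        if tossed == 0:
            continue
        ordered = sorted(members, key=index.__getitem__)
        unamb = np.array([counts[m] for m in ordered])
        if unamb.sum() > 0:
            quotas = tossed * unamb / unamb.sum()
        else:
            logger.warning(
                "ambiguity set %s has no unambiguous reads; splitting %d "
                "tossed reads equally",
                sorted(members),
                tossed,
            )
            quotas = np.full(len(ordered), tossed / len(ordered))
        shares = quotas if fractional else _largest_remainder(quotas, tossed)
        for m, extra in zip(ordered, shares):
            counts[m] += float(extra)
    return counts


def detect_members(
    counts: dict[str, float], threshold: float = DETECTION_THRESHOLD
) -> dict[str, float]:
    """Apply the relative-abundance detection threshold and renormalize.

    Isolates with strictly less than ``threshold`` of total counts are treated
    as absent (an isolate at exactly the threshold is kept).  Returns relative
    abundances over detected members, summing to 1.
    """
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("no reads: total count is zero")
    kept = {iso: c for iso, c in counts.items() if c / total >= threshold}
    if not kept:
        raise ValueError(
            f"all isolates below the {threshold:.0%} detection threshold; "
            "sample is uninterpretable"
        )
    kept_total = sum(kept.values())
    return {iso: c / kept_total for iso, c in kept.items()}


def to_absolute(
    relative: dict[str, float],
    cfu: CfuObservation | float,
    design_id: str = "",
    replicate: int = 1,
    designed_members: frozenset[str] | None = None,
) -> ObservedProfile:
    """Attach a total-density estimate to relative abundances.

    ``cfu`` may be a :class:`CfuObservation` or a bare CFU/uL number.
    """
    total = cfu.estimate if isinstance(cfu, CfuObservation) else float(cfu)
    if total < 0:
        raise ValueError("total density estimate must be >= 0")
    return ObservedProfile(
        design_id=design_id,
        replicate=replicate,
        relative_abundance=dict(relative),
        total_density=total,
        designed_members=designed_members,
    )


def profile_from_exact(
    exact: ExactObservation,
    threshold: float = DETECTION_THRESHOLD,
    design_id: str = "",
    replicate: int = 1,
    designed_members: frozenset[str] | None = None,
) -> ObservedProfile:
    """Build a profile from a noise-free observation (detection threshold
    still applies; everything else is exact)."""
    counts = {
        iso: float(v)
        for iso, v in zip(exact.isolate_ids, exact.relative)
        if v > 0
    }
    rel = detect_members(counts, threshold=threshold)
    # The exact observation knows the truth, so the total is discounted by the
    # mass of sub-threshold members and detected densities are recovered
    # exactly.  (With a real plate-count total that mass is not separable and
    # to_absolute keeps the full estimate.)
    detected_fraction = sum(counts[i] for i in rel) / sum(counts.values())
    return ObservedProfile(
        design_id=design_id,
        replicate=replicate,
        relative_abundance=rel,
        total_density=exact.total_density * detected_fraction,
        designed_members=designed_members,
    )


def aggregate_replicates(profiles: list[ObservedProfile]) -> ObservedProfile:
    """Collapse replicate profiles of one design into a single profile.

    A member is detected in the aggregate if detected in a strict majority of
    replicates; its density is the mean absolute density over all replicates
    (zeros counted where undetected).  Relative abundances are recomputed from
    the mean absolute densities.
    """
    if not profiles:
        raise ValueError("need at least one replicate profile")
    design_ids = {p.design_id for p in profiles}
    if len(design_ids) > 1:
        raise ValueError(f"profiles from multiple designs: {sorted(design_ids)}")
    n = len(profiles)
    members = set().union(*(p.detected_members for p in profiles))
    detected = {
        iso
        for iso in members
        if sum(iso in p.detected_members for p in profiles) > n / 2
    }
    if not detected:
        raise ValueError("no member detected in a majority of replicates")
    mean_abs = {
        iso: math.fsum(p.density_of(iso) for p in profiles) / n for iso in detected
    }
    total = math.fsum(mean_abs.values())
    rel = (
        {iso: v / total for iso, v in mean_abs.items()}
        if total > 0
        else {iso: 1.0 / len(detected) for iso in detected}
    )
    designed = profiles[0].designed_members
    return ObservedProfile(
        design_id=profiles[0].design_id,
        replicate=0,  # 0 marks an aggregate
        relative_abundance=rel,
        total_density=total,
        designed_members=designed,
    )
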