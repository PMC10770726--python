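"""Pairwise interaction measurement across community contexts.

An interaction is measured by comparing a focal isolate's absolute density
between two communities whose (observed) compositions differ by exactly one
isolate — the interactor.  Two metrics are computed per record:

* population-level effect: the ratio of focal density with vs. without the
  interactor, presented as ratio - 1 (and as ln(ratio) for distributional
  work, since the log symmetrizes ratios);
* per-capita effect: (n_with - n_without) / interactor density, the effect
  per interactor cell.

The two are algebraically linked: pop_effect = per_capita * interactor_density
/ n_without.  Records are pruned per metric to within ±1 SD of the metric's
mean, removing spurious values driven by isolates hovering near the detection
threshold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .abundance import ObservedProfile

__all__ = [
    "InteractionRecord",
    "CoexistenceCall",
    "find_context_pairs",
    "compute_interaction",
    "compute_all_interactions",
    "screen_context_dependence",
    "prune_outliers",
    "records_to_frame",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class InteractionRecord:
    """One measured interaction of an interactor on a focal isolate.

    ``richness_context`` is written on observed (detected) richness, e.g.
    "2=>3".  ``exclusion`` flags records where the focal was undetected in the
    with-context (pop_ratio 0, pop_log undefined).
    """

    focal: str
    interactor: str
    background: frozenset[str]
    context_without: str
    context_with: str
    replicate: int
    richness_context: str
    n_without: float
    n_with: float
    interactor_density: float
    total_without: float
    total_with: float

    @property
    def pop_ratio(self) -> float:
        return self.n_with / self.n_without

    @property
    def pop_effect(self) -> float:
        return self.pop_ratio - 1.0

    @property
    def pop_log(self) -> float:
        return math.log(self.pop_ratio) if self.pop_ratio > 0 else math.nan

    @property
    def per_capita(self) -> float:
        return (self.n_with - self.n_without) / self.interactor_density

    @property
    def focal_change(self) -> float:
        return self.n_with - self.n_without

    @property
    def total_change(self) -> float:
        return self.total_with - self.total_without

    @property
    def exclusion(self) -> bool:
        return self.n_with == 0

    @property
    def richness_without(self) -> int:
        return int(self.richness_context.split("=>")[0])


@dataclass(frozen=True)
class CoexistenceCall:
    """Context-dependent coexistence: focal coexists with the excluder in one
    community but is excluded from another community containing the excluder."""

    focal: str
    excluder: str
    context_coexist: str
    context_excluded: str


def find_context_pairs(
    profiles: list[ObservedProfile],
    use_designed_membership: bool = False,
) -> list[tuple[ObservedProfile, ObservedProfile, str]]:
    """All ordered profile pairs whose member sets differ by exactly one
    isolate (the interactor, present in the larger context).

    Pairing is within matching replicate ids, on observed (detected)
    membership by default; ``use_designed_membership`` switches to the
    inoculated membership.
    """

    def members(p: ObservedProfile) -> frozenset[str]:
        if use_designed_membership:
            if p.designed_members is None:
                raise ValueError(f"profile {p.design_id} lacks designed members")
            return p.designed_members
        return p.detected_members

    pairs = []
    by_rep: dict[int, list[ObservedProfile]] = {}
    for p in profiles:
        by_rep.setdefault(p.replicate, []).append(p)
    for group in by_rep.values():
        for without in group:
            m_wo = members(without)
            for with_ in group:
                if with_ is without:
                    continue
                m_w = members(with_)
                diff = m_w - m_wo
                if len(diff) == 1 and m_wo < m_w:
                    pairs.append((without, with_, next(iter(diff))))
    return pairs


def compute_interaction(
    pair: tuple[ObservedProfile, ObservedProfile, str],
) -> list[InteractionRecord]:
    """All interaction records for one context pair — one per focal isolate
    detected in the without-context.

    Records with undefined ratios (focal undetected without the interactor, or
    interactor density zero) are skipped with a logged reason.  A focal that
    disappears in the with-context yields an exclusion record (n_with = 0).
    """
    without, with_, interactor = pair
    interactor_density = with_.density_of(interactor)
    records: list[InteractionRecord] = []
    richness_context = f"{without.richness}=>{with_.richness}"
    if interactor_density <= 0:
        logger.info(
            "skipping pair %s -> %s: interactor %s density is zero",
            without.design_id,
            with_.design_id,
            interactor,
        )
        return records
    for focal in sorted(without.detected_members):
        n_without = without.density_of(focal)
        if n_without <= 0:
            logger.info(
                "skipping focal %s in %s: density without interactor is zero",
                focal,
                without.design_id,
            )
            continue
        records.append(
            InteractionRecord(
                focal=focal,
                interactor=interactor,
                background=without.detected_members - {focal},
                context_without=without.design_id,
                context_with=with_.design_id,
                replicate=without.replicate,
                richness_context=richness_context,
                n_without=n_without,
                n_with=with_.density_of(focal),
                interactor_density=interactor_density,
                total_without=without.total_density,
                total_with=with_.total_density,
            )
        )
    return records


def compute_all_interactions(
    profiles: list[ObservedProfile],
    use_designed_membership: bool = False,
) -> list[InteractionRecord]:
    """Find all single-member context pairs and compute their records."""
    records: list[InteractionRecord] = []
    for pair in find_context_pairs(profiles, use_designed_membership):
        records.extend(compute_interaction(pair))
    return records


def screen_context_dependence(
    profiles: list[ObservedProfile],
) -> list[CoexistenceCall]:
    """Screen profiles for context-dependent coexistence.

    Emits one call per (focal, excluder, coexist-context, excluded-context)
    where the focal is detected alongside the excluder in one community but —
    though inoculated — undetected in another community in which the excluder
    is detected.  Profiles without designed membership fall back to treating
    absence as exclusion.
    """
    calls: list[CoexistenceCall] = []
    for coexist in profiles:
        det = coexist.detected_members
        for focal in sorted(det):
            partners = det - {focal}
            for excluded_ctx in profiles:
                if excluded_ctx is coexist:
                    continue
                if focal in excluded_ctx.detected_members:
                    continue
                if (
                    excluded_ctx.designed_members is not None
                    and focal not in excluded_ctx.designed_members
                ):
                    continue  # never inoculated; not an exclusion
                for excluder in sorted(
                    partners & excluded_ctx.detected_members
                ):
                    calls.append(
                        CoexistenceCall(
                            focal=focal,
                            excluder=excluder,
                            context_coexist=coexist.design_id,
                            context_excluded=excluded_ctx.design_id,
                        )
                    )
    return calls


def prune_outliers(
    records: list[InteractionRecord],
    measure: str = "pop_log",
    z_max: float = 1.0,
) -> list[InteractionRecord]:
    """Keep records whose ``measure`` lies within ``z_max`` sample SDs of the
    mean over all records.

    Records with an undefined value for the measure (e.g. pop_log of an
    exclusion) are dropped from that measure's analysis set.  If the SD is 0
    no outlier is definable and all defined records are kept.
    """
    valid = [
        (rec, getattr(rec, measure))
        for rec in records
        if not math.isnan(getattr(rec, measure))
    ]
    if len(valid) < 2:
        return [rec for rec, _ in valid]
    values = np.array([v for _, v in valid])
    sd = values.std(ddof=1)
    if sd == 0:
        return [rec for rec, _ in valid]
    mean = values.mean()
    kept = [rec for (rec, v) in valid if abs(v - mean) <= z_max * sd]
    logger.info(
        "pruning on %s: kept %d of %d records (|z| <= %g)",
        measure,
        len(kept),
        len(valid),
        z_max,
    )
    return kept


def records_to_frame(records: list[InteractionRecord]) -> pd.DataFrame:
    """Tidy long-format table of interaction records."""
    rows = []
    for rec in records:
        rows.append(
            {
                "focal": rec.focal,
                "interactor": rec.interactor,
                "background": ",".join(sorted(rec.background)),
                "context_without": rec.context_without,
                "context_with": rec.context_with,
                "replicate": rec.replicate,
                "richness_context": rec.richness_context,
                "n_without": rec.n_without,
                "n_with": rec.n_with,
                "interactor_density": rec.interactor_density,
                "pop_ratio": rec.pop_ratio,
                "pop_effect": rec.pop_effect,
                "pop_log": rec.pop_log,
                "per_capita": rec.per_capita,
                "focal_change": rec.focal_change,
                "total_without": rec.total_without,
                "total_with": rec.total_with,
                "total_change": rec.total_change,
                "exclusion": rec.exclusion,
            }
        )
    return pd.DataFrame(rows)
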