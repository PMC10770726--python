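"""Canned simulation scenarios: the study conditions as code.

Each function builds a seeded ground-truth world, runs the simulator and the
measurement pipeline on it, and returns the quantity of interest.  These are
the conditions under which the package's recovery properties are evaluated:

* ``competition_parameters`` — a purely competitive community (all
  off-diagonal effects negative, moderate strength), the regime in which
  total density saturates with richness and interactions attenuate;
* ``noise_free_profiles`` — a nested single-dropout decomposition observed
  without measurement noise;
* ``attenuation_median_shift`` — the median change in |population effect|
  between richness contexts differing by one background member;
* ``sign_recovery_trial`` — whether a strong two-member interaction's
  measured per-capita sign matches the true coefficient sign.
"""

from __future__ import annotations

import numpy as np

from .abundance import detect_members, profile_from_exact, reallocate_ambiguous, to_absolute
from .catalog import IsolateCatalog, synthetic_catalog
from .context_stats import pair_across_richness, shift_summary
from .design import CommunityDesign, PassageProtocol, nested_decomposition
from .glv import (
    GLVParameters,
    GLVPriorConfig,
    child_seed,
    sample_glv_parameters,
    serial_passage,
)
from .interactions import compute_all_interactions, prune_outliers
from .observe import observe_cfu, observe_exact, observe_sequencing

__all__ = [
    "competition_parameters",
    "noise_free_profiles",
    "nested_noisy_study",
    "attenuation_median_shift",
    "sign_recovery_trial",
]


def competition_parameters(
    catalog: IsolateCatalog,
    seed: int,
    scale: float = 0.4,
    capacity_sd: float = 0.2,
) -> GLVParameters:
    """All-negative (purely competitive) GLV draw: interspecific competition
    at 0.2-1 x ``scale`` of self-limitation, carrying capacities lognormal
    around 1e5 CFU/uL."""
    rng = np.random.default_rng(seed)
    n = len(catalog)
    r = rng.uniform(0.4, 0.6, n)
    K = 1e5 * np.exp(rng.normal(0, capacity_sd, n))
    A = np.zeros((n, n))
    np.fill_diagonal(A, -r / K)
    for i in range(n):
        for j in range(n):
            if i != j:
                A[i, j] = -rng.uniform(0.2, 1.0) * scale * (r[i] / K[i])
    return GLVParameters(list(catalog.isolate_ids), r, A)


def noise_free_profiles(
    catalog: IsolateCatalog,
    params: GLVParameters,
    focal: str,
    excluder: str,
    protocol: PassageProtocol | None = None,
    seed: int = 0,
):
    """Simulate a nested decomposition of the full community and observe every
    final state without measurement noise."""
    protocol = protocol or PassageProtocol()
    superset = CommunityDesign("full", frozenset(catalog.isolate_ids))
    profiles = []
    for d in nested_decomposition(superset, focal, excluder, seed=seed):
        traj = serial_passage(d, params, protocol, catalog)
        if traj.final_state.sum() > 0:
            profiles.append(
                profile_from_exact(
                    observe_exact(traj.final_state, list(catalog.isolate_ids)),
                    design_id=d.design_id,
                    designed_members=d.members,
                )
            )
    return profiles


def nested_noisy_study(
    seed: int,
    n_isolates: int = 8,
    n_genera: int = 4,
    n_replicates: int = 3,
    n_focal_pairs: int = 3,
    depth: int = 50_000,
    plating_cv: float = 0.1,
    ambiguous_fraction: float = 0.2,
    threshold: float = 0.01,
):
    """The interaction study proper, at reduced scale with observation noise.

    A community of ``n_isolates`` is decomposed into nested single-dropout
    subcommunities around ``n_focal_pairs`` focal/excluder pairs (mirroring
    the multiple decomposed community pairs of the full-scale study); every
    subcommunity is passaged, then each replicate is observed through the
    sequencing model (multinomial reads, same-genus ambiguity) and the CFU
    plating model, and reconstructed into an absolute-abundance profile.
    Ground-truth parameters come from the genus-structured prior at its
    defaults.
    """
    catalog = synthetic_catalog(n_isolates, n_genera, seed=child_seed(seed, "cat"))
    params = sample_glv_parameters(
        catalog, GLVPriorConfig(), seed=child_seed(seed, "glv")
    )
    protocol = PassageProtocol()
    superset = CommunityDesign("full", frozenset(catalog.isolate_ids))
    by_genus: dict[str, list[str]] = {}
    for iso, genus in zip(catalog.isolate_ids, catalog.genera):
        by_genus.setdefault(genus, []).append(iso)
    amb_sets = [frozenset(v) for v in by_genus.values() if len(v) > 1]

    designs: dict[str, CommunityDesign] = {}
    for k in range(n_focal_pairs):
        focal = catalog.isolate_ids[(2 * k) % n_isolates]
        excluder = catalog.isolate_ids[(2 * k + 1) % n_isolates]
        for d in nested_decomposition(
            superset, focal, excluder, seed=child_seed(seed, "chain", k)
        ):
            designs.setdefault(d.design_id, d)

    profiles = []
    for design in designs.values():
        traj = serial_passage(design, params, protocol, catalog)
        final = traj.final_state
        if final.sum() <= 0:
            continue
        present_sets = [
            frozenset(i for i in s if final[catalog.index_of(i)] > 0)
            for s in amb_sets
        ]
        present_sets = [s for s in present_sets if len(s) >= 2]
        for rep in range(1, n_replicates + 1):
            seq = observe_sequencing(
                final,
                list(catalog.isolate_ids),
                depth=depth,
                ambiguity_sets=present_sets,
                ambiguous_fraction=ambiguous_fraction,
                seed=child_seed(seed, design.design_id, rep, "seq"),
            )
            counts = reallocate_ambiguous(seq)
            counts = {k: v for k, v in counts.items() if v > 0}
            cfu = observe_cfu(
                final,
                plating_cv=plating_cv,
                seed=child_seed(seed, design.design_id, rep, "cfu"),
            )
            try:
                rel = detect_members(counts, threshold=threshold)
            except ValueError:
                continue
            profiles.append(
                to_absolute(
                    rel,
                    cfu,
                    design_id=design.design_id,
                    replicate=rep,
                    designed_members=design.members,
                )
            )
    return profiles


def attenuation_median_shift(
    seed: int, n_isolates: int = 6, scale: float = 0.4
) -> float:
    """Median paired shift in |population effect| between richness contexts
    r=>r+1 and r+1=>r+2 under saturating-total-density competition.

    Negative values mean interactions attenuate as richness grows.
    """
    cat = synthetic_catalog(n_isolates, n_isolates, seed=seed)
    params = competition_parameters(cat, seed=seed, scale=scale)
    profiles = noise_free_profiles(
        cat, params, cat.isolate_ids[0], cat.isolate_ids[1], seed=seed
    )
    records = prune_outliers(compute_all_interactions(profiles), "pop_log")
    pairs = pair_across_richness(records, delta=1)
    sf = shift_summary(pairs, measure="pop_effect", group_by_initial_sign=False)
    return float(sf.iloc[0].median_abs_shift)


def sign_recovery_trial(
    seed: int, min_strength: float = 0.3, max_strength: float = 0.7
):
    """One two-member draw with a strong focal-directed coefficient.

    Returns (true_sign, measured_sign) of the interactor's effect on the
    focal isolate, or None if the interaction was unmeasurable (interactor
    excluded).  The back-effect on the interactor is kept weak so the
    interactor persists.
    """
    cat = IsolateCatalog(["F", "I"], ["g1", "g2"])
    rng = np.random.default_rng(seed)
    r = rng.uniform(0.4, 0.6, 2)
    K = 1e5 * np.exp(rng.normal(0, 0.2, 2))
    A = np.diag(-r / K)
    sign = -1.0 if rng.random() < 0.5 else 1.0
    A[0, 1] = sign * rng.uniform(min_strength, max_strength) * r[0] / K[0]
    A[1, 0] = -rng.uniform(0.0, 0.2) * r[1] / K[1]
    params = GLVParameters(["F", "I"], r, A)
    protocol = PassageProtocol()
    profiles = []
    for members in ({"F"}, {"F", "I"}):
        d = CommunityDesign("+".join(sorted(members)), frozenset(members))
        traj = serial_passage(d, params, protocol, cat)
        profiles.append(
            profile_from_exact(
                observe_exact(traj.final_state, ["F", "I"]),
                design_id=d.design_id,
            )
        )
    recs = [
        rec
        for rec in compute_all_interactions(profiles)
        if rec.focal == "F" and rec.interactor == "I"
    ]
    if not recs:
        return None
    return float(np.sign(A[0, 1])), float(np.sign(recs[0].per_capita))
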