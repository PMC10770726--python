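"""Context pairing, interaction metrics, coexistence screen, and pruning."""

import math

import numpy as np
import pytest

from commix.abundance import to_absolute
from commix.interactions import (
    InteractionRecord,
    compute_all_interactions,
    compute_interaction,
    find_context_pairs,
    prune_outliers,
    screen_context_dependence,
)


def profile(design_id, abundances: dict, total: float, replicate=1, designed=None):
    s = sum(abundances.values())
    rel = {k: v / s for k, v in abundances.items()}
    return to_absolute(
        rel,
        total,
        design_id=design_id,
        replicate=replicate,
        designed_members=frozenset(designed) if designed else None,
    )


def record(n_without, n_with, interactor_density, **kw):
    defaults = dict(
        focal="F",
        interactor="I",
        background=frozenset(),
        context_without="d1",
        context_with="d2",
        replicate=1,
        richness_context="1=>2",
        total_without=n_without,
        total_with=n_with + interactor_density,
    )
    defaults.update(kw)
    return InteractionRecord(
        n_without=n_without,
        n_with=n_with,
        interactor_density=interactor_density,
        **defaults,
    )


class TestFindContextPairs:
    def test_single_member_difference_is_paired(self):
        p1 = profile("d1", {"A": 1.0}, 100)
        p2 = profile("d2", {"A": 0.5, "B": 0.5}, 200)
        pairs = find_context_pairs([p1, p2])
        assert len(pairs) == 1
        without, with_, interactor = pairs[0]
        assert (without.design_id, with_.design_id, interactor) == ("d1", "d2", "B")

    def test_background_isolates_allowed(self):
        p1 = profile("d1", {"A": 0.5, "C": 0.5}, 100)
        p2 = profile("d2", {"A": 0.4, "B": 0.3, "C": 0.3}, 200)
        pairs = find_context_pairs([p1, p2])
        assert [(p[2]) for p in pairs] == ["B"]

    def test_disjoint_profiles_are_not_paired(self):
        p1 = profile("d1", {"A": 1.0}, 100)
        p2 = profile("d2", {"B": 0.5, "C": 0.5}, 100)
        assert find_context_pairs([p1, p2]) == []

    def test_two_member_difference_excluded(self):
        p1 = profile("d1", {"A": 1.0}, 100)
        p2 = profile("d2", {"A": 0.4, "B": 0.3, "C": 0.3}, 100)
        assert find_context_pairs([p1, p2]) == []

    def test_pairing_respects_replicates(self):
        p1 = profile("d1", {"A": 1.0}, 100, replicate=1)
        p2 = profile("d2", {"A": 0.5, "B": 0.5}, 100, replicate=2)
        assert find_context_pairs([p1, p2]) == []


class TestComputeInteraction:
    def test_worked_arithmetic(self):
        p1 = profile("d1", {"F": 1.0}, 100)
        p2 = profile("d2", {"F": 50, "I": 200}, 250)
        (rec,) = compute_interaction((p1, p2, "I"))
        assert rec.pop_ratio == pytest.approx(0.5)
        assert rec.pop_effect == pytest.approx(-0.5)
        assert rec.pop_log == pytest.approx(math.log(0.5))
        assert rec.per_capita == pytest.approx(-0.25)
        assert rec.richness_context == "1=>2"

    def test_no_change_is_zero_effect(self):
        rec = record(100.0, 100.0, 50.0)
        assert rec.pop_effect == 0 and rec.per_capita == 0

    def test_exclusion_record_flagged(self):
        p1 = profile("d1", {"F": 0.5, "X": 0.5}, 200)
        p2 = profile("d2", {"X": 0.5, "I": 0.5}, 200)
        # F undetected with the interactor: measurable for focal X only,
        # while F yields an exclusion record via designed pairing upstream.
        recs = compute_interaction((p1, p2, "I"))
        by_focal = {r.focal: r for r in recs}
        assert by_focal["F"].exclusion
        assert by_focal["F"].pop_ratio == 0
        assert math.isnan(by_focal["F"].pop_log)
        assert not by_focal["X"].exclusion

    def test_algebraic_identity_on_randomized_records(self):
        # pop_effect and per_capita computed through independent expressions
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n_wo, n_w, dens = rng.uniform(1, 1e6, 3)
            rec = record(n_wo, n_w, dens)
            lhs = rec.pop_effect
            rhs = rec.per_capita * rec.interactor_density / rec.n_without
            assert lhs == pytest.approx(rhs, rel=1e-9)

    def test_signs_of_both_measures_agree(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            n_wo, n_w, dens = rng.uniform(1, 1e5, 3)
            rec = record(n_wo, n_w, dens)
            assert np.sign(rec.pop_effect) == np.sign(rec.per_capita)

    def test_zero_interactor_density_skipped(self):
        p1 = profile("d1", {"F": 1.0}, 100)
        p2 = to_absolute(
            {"F": 0.5, "I": 0.5}, 0.0, design_id="d2"
        )  # total 0 -> interactor density 0
        assert compute_interaction((p1, p2, "I")) == []


class TestCoexistenceScreen:
    def test_context_dependent_exclusion_found(self):
        d1 = profile("d1", {"F": 0.5, "E": 0.5}, 100, designed={"F", "E"})
        d2 = profile("d2", {"E": 0.7, "X": 0.3}, 100, designed={"F", "E", "X"})
        calls = screen_context_dependence([d1, d2])
        assert [(c.focal, c.excluder, c.context_coexist, c.context_excluded) for c in calls] == [
            ("F", "E", "d1", "d2")
        ]

    def test_never_inoculated_is_not_exclusion(self):
        d1 = profile("d1", {"F": 0.5, "E": 0.5}, 100, designed={"F", "E"})
        d2 = profile("d2", {"E": 0.7, "X": 0.3}, 100, designed={"E", "X"})
        assert screen_context_dependence([d1, d2]) == []

    def test_focal_present_everywhere_yields_no_calls(self):
        d1 = profile("d1", {"F": 0.5, "E": 0.5}, 100, designed={"F", "E"})
        d2 = profile("d2", {"F": 0.3, "E": 0.4, "X": 0.3}, 100, designed={"F", "E", "X"})
        assert screen_context_dependence([d1, d2]) == []


class TestPruning:
    def test_worked_outlier_example(self):
        # values [0,0,0,0,10]: mean 2, sample SD sqrt(20) ~ 4.472 -> 10 pruned
        recs = [record(100.0, 100.0 * (1 + v), 50.0) for v in [0, 0, 0, 0, 10]]
        kept = prune_outliers(recs, measure="pop_effect", z_max=1.0)
        assert len(kept) == 4
        assert all(r.pop_effect == 0 for r in kept)

    def test_equal_values_all_kept(self):
        recs = [record(100.0, 150.0, 50.0) for _ in range(5)]
        assert len(prune_outliers(recs, "pop_effect")) == 5

    def test_infinite_z_keeps_everything(self):
        rng = np.random.default_rng(2)
        recs = [
            record(*rng.uniform(1, 1e4, 3)) for _ in range(50)
        ]
        assert len(prune_outliers(recs, "per_capita", z_max=math.inf)) == 50

    def test_undefined_log_values_excluded_from_log_pruning(self):
        recs = [record(100.0, 0.0, 50.0)] + [
            record(100.0, 150.0, 50.0) for _ in range(4)
        ]
        kept = prune_outliers(recs, "pop_log")
        assert len(kept) == 4
        assert all(not r.exclusion for r in kept)


class TestNullRecovery:
    def test_zero_interactions_give_zero_measured_effects(
        self, catalog6, protocol
    ):
        """Off-diagonal coefficients all zero + noise-off observation ->
        every measured effect is zero (to floating tolerance)."""
        from commix.abundance import profile_from_exact
        from commix.design import CommunityDesign, nested_decomposition
        from commix.glv import GLVPriorConfig, sample_glv_parameters, serial_passage
        from commix.observe import observe_exact

        cfg = GLVPriorConfig(interaction_scale=0.0, same_genus_shift=0.0)
        params = sample_glv_parameters(catalog6, cfg, seed=7)
        superset = CommunityDesign("full", frozenset(catalog6.isolate_ids))
        profiles = []
        for d in nested_decomposition(superset, "isoA", "isoB", seed=7):
            traj = serial_passage(d, params, protocol, catalog6)
            profiles.append(
                profile_from_exact(
                    observe_exact(traj.final_state, list(catalog6.isolate_ids)),
                    design_id=d.design_id,
                )
            )
        records = compute_all_interactions(profiles)
        assert records, "no interactions measured"
        for rec in records:
            assert abs(rec.pop_effect) < 1e-6
            assert abs(rec.per_capita) < 1e-6


class TestSignRecovery:
    def test_percapita_sign_matches_true_coefficient(self, protocol):
        """Two-member communities with strong coefficients: the sign of the
        measured per-capita effect recovers the sign of the true a_ij in at
        least 90% of seeded draws."""
        from commix.catalog import IsolateCatalog
        from commix.design import CommunityDesign
        from commix.glv import GLVParameters, serial_passage
        from commix.abundance import profile_from_exact
        from commix.observe import observe_exact

        cat = IsolateCatalog(["F", "I"], ["g1", "g2"])
        hits, measured = 0, 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            r = rng.uniform(0.4, 0.6, 2)
            K = 1e5 * np.exp(rng.normal(0, 0.2, 2))
            A = np.diag(-r / K)
            sign = -1.0 if rng.random() < 0.5 else 1.0
            A[0, 1] = sign * rng.uniform(0.3, 0.7) * r[0] / K[0]  # strong
            A[1, 0] = -rng.uniform(0.0, 0.2) * r[1] / K[1]  # weak back-effect
            params = GLVParameters(["F", "I"], r, A)
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
                r_
                for r_ in compute_all_interactions(profiles)
                if r_.focal == "F" and r_.interactor == "I"
            ]
            if not recs:
                continue
            measured += 1
            if np.sign(recs[0].per_capita) == np.sign(A[0, 1]):
                hits += 1
        assert measured >= 45
        assert hits / measured >= 0.9
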