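"""Paired richness-context shifts, group comparisons, richness-density
relationships, and the explanatory-power regressions."""

import itertools

import numpy as np
import pytest
from scipy import stats

from commix.abundance import to_absolute
from commix.context_stats import (
    PairedContextRecord,
    fit_cross_context_models,
    fit_focal_change_models,
    group_comparison,
    pair_across_richness,
    richness_density_stats,
    shift_summary,
)
from commix.interactions import InteractionRecord


def record(
    n_without,
    n_with,
    interactor_density,
    background=frozenset(),
    focal="F",
    interactor="I",
    total_without=None,
    total_with=None,
    richness=None,
):
    r_wo = richness if richness is not None else len(background) + 1
    return InteractionRecord(
        focal=focal,
        interactor=interactor,
        background=frozenset(background),
        context_without="c" + "".join(sorted(background)) or "c0",
        context_with="cw" + "".join(sorted(background)),
        replicate=1,
        richness_context=f"{r_wo}=>{r_wo + 1}",
        n_without=n_without,
        n_with=n_with,
        interactor_density=interactor_density,
        total_without=total_without if total_without is not None else n_without,
        total_with=total_with
        if total_with is not None
        else n_with + interactor_density,
    )


def paired(low_effect, high_effect, background_high=("X",)):
    """Build a paired record with chosen pop_effect values (n_without 100)."""
    low = record(100.0, 100.0 * (1 + low_effect), 50.0, background=frozenset())
    high = record(
        100.0,
        100.0 * (1 + high_effect),
        50.0,
        background=frozenset(background_high),
    )
    return PairedContextRecord(focal="F", interactor="I", low=low, high=high)


class TestPairAcrossRichness:
    def test_nested_backgrounds_differing_by_one_pair(self):
        low = record(100, 50, 20, background=frozenset())
        high = record(80, 60, 10, background=frozenset({"X"}))
        pairs = pair_across_richness([low, high], delta=1)
        assert len(pairs) == 1
        assert pairs[0].low is low and pairs[0].high is high

    def test_non_nested_backgrounds_not_paired(self):
        a = record(100, 50, 20, background=frozenset({"X"}))
        b = record(80, 60, 10, background=frozenset({"Y"}))
        assert pair_across_richness([a, b], delta=1) == []

    def test_delta_two_pairs_across_two_steps(self):
        low = record(100, 50, 20, background=frozenset())
        high = record(80, 60, 10, background=frozenset({"X", "Y"}))
        assert pair_across_richness([low, high], delta=1) == []
        assert len(pair_across_richness([low, high], delta=2)) == 1

    def test_one_low_record_can_pair_with_multiple_highs(self):
        low = record(100, 50, 20, background=frozenset())
        h1 = record(80, 60, 10, background=frozenset({"X"}))
        h2 = record(70, 65, 15, background=frozenset({"Y"}))
        assert len(pair_across_richness([low, h1, h2], delta=1)) == 2


class TestShiftSummary:
    def test_no_shift_gives_median_zero_p_one(self):
        pairs = [paired(0.3, 0.3) for _ in range(8)]
        sf = shift_summary(pairs, measure="pop_effect")
        overall = sf[sf.group == "all"].iloc[0]
        assert overall.median_shift == 0
        assert overall.p_shift == 1.0

    def test_consistent_attenuation_detected_at_n6(self):
        # all |high| < |low|: exact signed-rank two-sided p = 2/2^6 = 0.03125
        lows = [-0.8, -0.7, -0.6, 0.9, 0.7, -0.5]
        pairs = [paired(lo, lo * 0.5) for lo in lows]
        sf = shift_summary(pairs, measure="pop_effect")
        overall = sf[sf.group == "all"].iloc[0]
        assert overall.median_abs_shift < 0
        assert overall.p_abs_shift == pytest.approx(2 / 2**6)
        assert overall.p_abs_shift < 0.05

    def test_swapping_low_and_high_negates_median_shift(self):
        rng = np.random.default_rng(3)
        effects = rng.uniform(-0.9, 1.0, (12, 2))
        fwd = [paired(lo, hi) for lo, hi in effects]
        rev = [paired(hi, lo) for lo, hi in effects]
        f = shift_summary(fwd, group_by_initial_sign=False).iloc[0]
        r = shift_summary(rev, group_by_initial_sign=False).iloc[0]
        assert f.median_shift == pytest.approx(-r.median_shift)

    def test_sign_strata_reported(self):
        pairs = [paired(-0.5, -0.3)] * 4 + [paired(0.5, 0.3)] * 4
        sf = shift_summary(pairs, measure="pop_effect")
        assert set(sf.group) == {"all", "initially_negative", "initially_positive"}


class TestGroupComparison:
    def test_identical_groups_p_one(self):
        recs = [record(100, 50, 20), record(100, 200, 20)]  # -0.5 and +1.0 ...
        recs = [
            record(100, 50, 20),
            record(100, 150, 20),
        ]  # |effects| 0.5 and 0.5
        out = group_comparison(recs, "sign", measure="pop_effect")
        assert out["p_value"] == 1.0

    def test_stronger_negatives_detected(self):
        rng = np.random.default_rng(4)
        recs = []
        for _ in range(100):
            recs.append(record(100.0, 100.0 * (1 - rng.uniform(0.4, 0.9)), 20.0))
            recs.append(record(100.0, 100.0 * (1 + rng.uniform(0.0, 0.3)), 20.0))
        out = group_comparison(recs, "sign", measure="pop_effect")
        assert out["median_negative"] > out["median_positive"]
        assert out["p_value"] < 0.05

    def test_same_genus_more_negative(self, catalog6):
        # isoA/isoB congeneric; isoA/isoC cross-genus
        rng = np.random.default_rng(5)
        recs = []
        for _ in range(100):
            recs.append(
                record(
                    100.0,
                    100.0 * (1 + rng.normal(-0.5, 0.2)),
                    20.0,
                    focal="isoA",
                    interactor="isoB",
                )
            )
            recs.append(
                record(
                    100.0,
                    100.0 * (1 + rng.normal(-0.3, 0.2)),
                    20.0,
                    focal="isoA",
                    interactor="isoC",
                )
            )
        out = group_comparison(recs, "same_genus", measure="pop_effect", catalog=catalog6)
        assert out["median_same_genus"] < out["median_cross_genus"]
        assert out["p_value"] < 0.05

    def test_empty_group_is_an_error(self):
        recs = [record(100, 50, 20)] * 3  # all negative
        with pytest.raises(ValueError, match="positive"):
            group_comparison(recs, "sign", measure="pop_effect")


def make_profiles(density_of_richness, richnesses=(1, 2, 3, 4, 5), reps=3):
    profiles = []
    for rich in richnesses:
        for rep in range(1, reps + 1):
            members = {f"m{k}": 1.0 for k in range(rich)}
            s = sum(members.values())
            profiles.append(
                to_absolute(
                    {k: v / s for k, v in members.items()},
                    density_of_richness(rich, rep),
                    design_id=f"d{rich}",
                    replicate=rep,
                )
            )
    return profiles


class TestRichnessDensity:
    def test_constant_density_gives_zero_correlation(self):
        profiles = make_profiles(lambda rich, rep: 1000.0)
        out = richness_density_stats(profiles)
        assert out["pearson_richness_total"] == 0.0

    def test_linear_density_gives_unit_correlation(self):
        profiles = make_profiles(lambda rich, rep: 500.0 * rich)
        out = richness_density_stats(profiles)
        assert out["pearson_richness_total"] == pytest.approx(1.0)

    def test_saturating_density_negative_individual_correlation(self):
        # total saturates -> per-member density falls with richness
        profiles = make_profiles(
            lambda rich, rep: 1000.0 * rich / (1 + 0.5 * (rich - 1))
        )
        out = richness_density_stats(profiles)
        assert out["pearson_richness_total"] > 0
        assert out["pearson_richness_individual"] < 0

    def test_context_total_change_correlation_excludes_sparse_contexts(self):
        recs = []
        for rich in (1, 2, 3):
            for _ in range(5):
                recs.append(
                    record(
                        100.0,
                        80.0,
                        20.0,
                        richness=rich,
                        total_without=1000.0,
                        total_with=1000.0 + 300.0 / rich,
                    )
                )
        # one sparse context (< 3 observations) must be ignored
        recs.append(
            record(100.0, 80.0, 20.0, richness=7, total_without=0.0, total_with=1e6)
        )
        profiles = make_profiles(lambda rich, rep: 100.0 * rich)
        out = richness_density_stats(profiles, records=recs)
        assert out["n_context_total_change"] == 15
        assert out["pearson_context_total_change"] < 0

    def test_too_few_richness_levels_is_an_error(self):
        profiles = make_profiles(lambda rich, rep: 100.0, richnesses=(1, 2))
        with pytest.raises(ValueError, match="richness"):
            richness_density_stats(profiles)


def linear_records(n, slope=0.5, noise_sd=0.0, seed=0, contexts=(1, 2, 3)):
    rng = np.random.default_rng(seed)
    recs = []
    for k in range(n):
        tc = rng.uniform(-1000, 1000)
        fc = slope * tc + rng.normal(0, noise_sd) if noise_sd else slope * tc
        rich = contexts[k % len(contexts)]
        recs.append(
            record(
                1000.0,
                1000.0 + fc,
                200.0,
                richness=rich,
                total_without=5000.0,
                total_with=5000.0 + tc,
            )
        )
    return recs


class TestFocalChangeModels:
    def test_noiseless_linear_signal_gives_unit_adj_r2(self):
        results = fit_focal_change_models(linear_records(60))
        first = results[0]
        assert first.label == "focal_change ~ total_change"
        assert first.adj_r2 == pytest.approx(1.0, abs=1e-9)

    def test_pure_noise_gives_near_zero_adj_r2(self):
        rng = np.random.default_rng(6)
        recs = []
        for k in range(400):
            recs.append(
                record(
                    1000.0,
                    1000.0 + rng.normal(0, 100),
                    200.0,
                    richness=(k % 3) + 1,
                    total_without=5000.0,
                    total_with=5000.0 + rng.uniform(-1000, 1000),
                )
            )
        results = fit_focal_change_models(recs)
        assert abs(results[0].adj_r2) < 0.05

    def test_categorical_model_weaker_than_continuous_on_pure_signal(self):
        results = fit_focal_change_models(linear_records(90, seed=2))
        by_label = {r.label: r for r in results}
        assert (
            by_label["focal_change ~ n_context"].adj_r2
            < by_label["focal_change ~ total_change"].adj_r2
        )


class TestCrossContextModels:
    def _pairs(self, n, a=0.0, b=1.0, noise_sd=0.0, seed=0, shuffle=False):
        rng = np.random.default_rng(seed)
        pairs = []
        lows = rng.uniform(-500, 500, n)
        totals = rng.uniform(-800, 800, n)
        if shuffle:
            pred_lows = rng.permutation(lows)
        else:
            pred_lows = lows
        for k in range(n):
            high_fc = a * totals[k] + b * lows[k] + (
                rng.normal(0, noise_sd) if noise_sd else 0.0
            )
            low = record(
                1000.0, 1000.0 + pred_lows[k], 200.0, background=frozenset()
            )
            high = record(
                1000.0,
                1000.0 + high_fc,
                200.0,
                background=frozenset({"X"}),
                total_without=5000.0,
                total_with=5000.0 + totals[k],
            )
            pairs.append(
                PairedContextRecord(focal="F", interactor="I", low=low, high=high)
            )
        return pairs

    def test_high_equals_low_gives_unit_adj_r2(self):
        pairs = self._pairs(40, a=0.0, b=1.0)
        by_label = {r.label: r for r in fit_cross_context_models(pairs)}
        assert by_label["focal_change ~ interaction_effect"].adj_r2 == pytest.approx(
            1.0, abs=1e-9
        )

    def test_joint_model_beats_singles_when_both_signals_present(self):
        for seed in range(20):
            pairs = self._pairs(100, a=0.6, b=0.6, noise_sd=100.0, seed=seed)
            by_label = {r.label: r for r in fit_cross_context_models(pairs)}
            joint = by_label["focal_change ~ total_change + interaction_effect"]
            assert joint.adj_r2 > by_label["focal_change ~ total_change"].adj_r2
            assert (
                joint.adj_r2 > by_label["focal_change ~ interaction_effect"].adj_r2
            )

    def test_shuffled_low_context_values_have_no_explanatory_power(self):
        pairs = self._pairs(300, a=0.0, b=1.0, noise_sd=50.0, seed=1, shuffle=True)
        by_label = {r.label: r for r in fit_cross_context_models(pairs)}
        assert abs(by_label["focal_change ~ interaction_effect"].adj_r2) < 0.05

    def test_joint_adj_r2_nearly_dominates_singles_on_random_data(self):
        # nested OLS near-monotonicity after adjustment (the adjustment
        # penalty for one extra predictor is ~(1-R^2)/(n-3), well under the
        # 0.02 slack at this n)
        for seed in range(10):
            pairs = self._pairs(200, a=0.3, b=0.2, noise_sd=400.0, seed=seed)
            by_label = {r.label: r for r in fit_cross_context_models(pairs)}
            joint = by_label["focal_change ~ total_change + interaction_effect"]
            singles = [
                by_label["focal_change ~ total_change"].adj_r2,
                by_label["focal_change ~ interaction_effect"].adj_r2,
            ]
            assert joint.adj_r2 >= max(singles) - 0.02
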