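"""Cross-context statistics.

How does the same interaction change when measured in a richer community?
Records sharing a (focal, interactor) pair whose background sets are nested
and differ by a configurable number of isolates are paired, and the shift in
interaction strength between the low- and high-richness context is analyzed
with paired Wilcoxon signed-rank tests.  Group comparisons (negative vs.
positive interactions, same- vs. cross-genus pairs) use Wilcoxon rank-sum
tests.  Richness-density relationships are summarized with Pearson
correlations and Holm-corrected pairwise t-tests, and the explanatory power
of community properties for interaction effects is quantified with ordinary
least-squares models (adjusted R²).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .abundance import ObservedProfile
from .catalog import IsolateCatalog
from .interactions import InteractionRecord

__all__ = [
    "PairedContextRecord",
    "ModelResult",
    "pair_across_richness",
    "shift_summary",
    "group_comparison",
    "richness_density_stats",
    "fit_focal_change_models",
    "fit_cross_context_models",
]

logger = logging.getLogger(__name__)

SMALL_SAMPLE_N = 6


@dataclass(frozen=True)
class PairedContextRecord:
    """One interaction observed in two richness contexts whose backgrounds are
    nested and differ by a fixed number of isolates (default one)."""

    focal: str
    interactor: str
    low: InteractionRecord
    high: InteractionRecord

    def __post_init__(self) -> None:
        if (self.low.focal, self.low.interactor) != (
            self.high.focal,
            self.high.interactor,
        ):
            raise ValueError("paired records must share focal and interactor")
        if not self.low.background < self.high.background:
            raise ValueError("low background must be a strict subset of high")

    @property
    def delta(self) -> int:
        return len(self.high.background) - len(self.low.background)

    def shift(self, measure: str) -> float:
        return getattr(self.high, measure) - getattr(self.low, measure)

    @property
    def shift_pop(self) -> float:
        return self.shift("pop_effect")

    @property
    def shift_pc(self) -> float:
        return self.shift("per_capita")


@dataclass
class ModelResult:
    """Summary of one least-squares fit: label, n, model df, adjusted R²,
    model p-value, and the coefficient table."""

    label: str
    n: int
    df_model: int
    adj_r2: float
    p_value: float
    coefficients: pd.DataFrame

    def as_row(self) -> dict:
        return {
            "model": self.label,
            "n": self.n,
            "df": self.df_model,
            "adj_r2": self.adj_r2,
            "p_value": self.p_value,
        }


def pair_across_richness(
    records: list[InteractionRecord], delta: int = 1
) -> list[PairedContextRecord]:
    """Pair records of the same (focal, interactor) whose backgrounds are
    nested and differ by exactly ``delta`` isolates.

    One low-context record may pair with several higher-richness records.
    Pairing is within replicates.
    """
    by_key: dict[tuple[str, str, int], list[InteractionRecord]] = {}
    for rec in records:
        by_key.setdefault((rec.focal, rec.interactor, rec.replicate), []).append(rec)
    pairs: list[PairedContextRecord] = []
    for group in by_key.values():
        for low, high in itertools.permutations(group, 2):
            if (
                low.background < high.background
                and len(high.background - low.background) == delta
            ):
                pairs.append(
                    PairedContextRecord(
                        focal=low.focal, interactor=low.interactor, low=low, high=high
                    )
                )
    return pairs


def _paired_wilcoxon(low: np.ndarray, high: np.ndarray) -> float:
    """Two-sided paired signed-rank p-value; exact null for n <= 25."""
    diffs = high - low
    if np.allclose(diffs, 0):
        return 1.0
    method = "exact" if len(diffs) <= 25 and not np.any(diffs == 0) else "approx"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(
            stats.wilcoxon(low, high, alternative="two-sided", method=method).pvalue
        )


def _shift_block(lows: np.ndarray, highs: np.ndarray) -> dict:
    return {
        "n": len(lows),
        "median_low": float(np.median(lows)),
        "median_high": float(np.median(highs)),
        "median_shift": float(np.median(highs - lows)),
        "p_shift": _paired_wilcoxon(lows, highs),
        "median_abs_shift": float(np.median(np.abs(highs) - np.abs(lows))),
        "p_abs_shift": _paired_wilcoxon(np.abs(lows), np.abs(highs)),
    }


def shift_summary(
    pairs: list[PairedContextRecord],
    measure: str = "pop_effect",
    group_by_initial_sign: bool = True,
) -> pd.DataFrame:
    """Paired-shift summary for one interaction measure.

    Rows: overall, and (optionally) strata by the sign of the low-context
    value.  Columns: medians of low/high/shift/|shift|, two-sided signed-rank
    p-values on paired values and on absolute values.
    """
    if not pairs:
        raise ValueError("no paired context records")
    lows = np.array([getattr(p.low, measure) for p in pairs])
    highs = np.array([getattr(p.high, measure) for p in pairs])
    ok = ~(np.isnan(lows) | np.isnan(highs))
    lows, highs = lows[ok], highs[ok]
    if len(lows) < SMALL_SAMPLE_N:
        logger.warning(
            "only %d paired shifts for %s; p-values unreliable", len(lows), measure
        )
    rows = [{"group": "all", **_shift_block(lows, highs)}]
    if group_by_initial_sign:
        for name, mask in (
            ("initially_negative", lows < 0),
            ("initially_positive", lows > 0),
        ):
            if mask.any():
                rows.append({"group": name, **_shift_block(lows[mask], highs[mask])})
    return pd.DataFrame(rows)


def group_comparison(
    records: list[InteractionRecord],
    grouping: str,
    measure: str = "pop_effect",
    catalog: IsolateCatalog | None = None,
) -> dict:
    """Two-group comparison of interaction values.

    ``grouping='sign'`` compares |value| between negative- and positive-valued
    records (are negative interactions stronger?); ``grouping='same_genus'``
    compares raw values between same-genus and cross-genus (focal, interactor)
    pairs and needs a catalog for genus labels.  Two-sided Wilcoxon rank-sum
    (Mann-Whitney) test.
    """
    if not records:
        raise ValueError("no interaction records to compare")
    values = np.array([getattr(rec, measure) for rec in records])
    keep = ~np.isnan(values)
    records = [r for r, k in zip(records, keep) if k]
    values = values[keep]
    if grouping == "sign":
        a, b = np.abs(values[values < 0]), np.abs(values[values > 0])
        names = ("negative", "positive")
    elif grouping == "same_genus":
        if catalog is None:
            raise ValueError("genus grouping requires an isolate catalog")
        same = np.array(
            [
                catalog.genus_of(r.focal) == catalog.genus_of(r.interactor)
                for r in records
            ]
        )
        a, b = values[same], values[~same]
        names = ("same_genus", "cross_genus")
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    for name, grp in zip(names, (a, b)):
        if len(grp) == 0:
            raise ValueError(f"group {name!r} is empty")
    if np.array_equal(np.sort(a), np.sort(b)):
        p = 1.0
    else:
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    return {
        "grouping": grouping,
        "measure": measure,
        f"n_{names[0]}": len(a),
        f"n_{names[1]}": len(b),
        f"median_{names[0]}": float(np.median(a)),
        f"median_{names[1]}": float(np.median(b)),
        "p_value": p,
    }


def richness_density_stats(
    profiles: list[ObservedProfile],
    records: list[InteractionRecord] | None = None,
    min_context_observations: int = 3,
) -> dict:
    """Richness-density relationships across final community profiles.

    Returns Pearson correlations of final richness with total community
    density and with individual member density, Holm-corrected pairwise
    t-tests of individual density between richness groups, and (when
    interaction records are supplied) the correlation between richness
    context and the absolute change in total density per interaction,
    dropping richness contexts with fewer observations than
    ``min_context_observations``.
    """
    richness = np.array([p.richness for p in profiles], dtype=float)
    totals = np.array([p.total_density for p in profiles])
    if len(np.unique(richness)) < 3:
        raise ValueError("need at least 3 distinct richness values")

    def _pearson(x, y):
        if np.std(x) == 0 or np.std(y) == 0:
            return 0.0, 1.0
        r, p = stats.pearsonr(x, y)
        return float(r), float(p)

    r_total, p_total = _pearson(richness, totals)

    ind_rich, ind_dens = [], []
    for p in profiles:
        for iso, dens in p.absolute_density.items():
            ind_rich.append(p.richness)
            ind_dens.append(dens)
    ind_rich = np.array(ind_rich, dtype=float)
    ind_dens = np.array(ind_dens)
    r_ind, p_ind = _pearson(ind_rich, ind_dens)

    groups = {int(k): ind_dens[ind_rich == k] for k in np.unique(ind_rich)}
    combos = [
        (a, b)
        for a, b in itertools.combinations(sorted(groups), 2)
        if len(groups[a]) > 1 and len(groups[b]) > 1
    ]
    pairwise = pd.DataFrame(columns=["richness_a", "richness_b", "p_raw", "p_holm"])
    if combos:
        raw = [
            float(stats.ttest_ind(groups[a], groups[b]).pvalue) for a, b in combos
        ]
        holm = multipletests(raw, method="holm")[1]
        pairwise = pd.DataFrame(
            {
                "richness_a": [a for a, _ in combos],
                "richness_b": [b for _, b in combos],
                "p_raw": raw,
                "p_holm": holm,
            }
        )

    out = {
        "pearson_richness_total": r_total,
        "p_richness_total": p_total,
        "pearson_richness_individual": r_ind,
        "p_richness_individual": p_ind,
        "pairwise_individual_density": pairwise,
    }

    if records is not None:
        ctx = np.array([rec.richness_without for rec in records], dtype=float)
        tchange = np.abs(np.array([rec.total_change for rec in records]))
        counts = pd.Series(ctx).value_counts()
        keep_ctx = counts[counts >= min_context_observations].index
        mask = np.isin(ctx, keep_ctx)
        if len(np.unique(ctx[mask])) >= 2:
            r_tc, p_tc = _pearson(ctx[mask], tchange[mask])
        else:
            r_tc, p_tc = np.nan, np.nan
        out["pearson_context_total_change"] = r_tc
        out["p_context_total_change"] = p_tc
        out["n_context_total_change"] = int(mask.sum())
    return out


def _fit(label: str, formula: str, df: pd.DataFrame) -> ModelResult:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = smf.ols(formula, data=df).fit()
    coef = pd.DataFrame(
        {
            "coef": res.params,
            "stderr": res.bse,
            "p_value": res.pvalues,
        }
    )
    return ModelResult(
        label=label,
        n=int(res.nobs),
        df_model=int(res.df_model),
        adj_r2=float(res.rsquared_adj),
        p_value=float(res.f_pvalue),
        coefficients=coef,
    )


def _drop_sparse_levels(
    df: pd.DataFrame, column: str, min_records: int
) -> pd.DataFrame:
    counts = df[column].value_counts()
    sparse = counts[counts < min_records].index.tolist()
    if sparse:
        logger.warning(
            "dropping %s levels with < %d records: %s", column, min_records, sparse
        )
        df = df[~df[column].isin(sparse)]
    return df


def fit_focal_change_models(
    records: list[InteractionRecord], min_level_records: int = 3
) -> list[ModelResult]:
    """Model the interaction effect (focal density change) from community
    properties, within single richness contexts.

    Three fits: focal change on total density change; on richness context (as
    a factor); and on their interaction.  Richness-context levels with fewer
    than ``min_level_records`` records are dropped from the categorical fits.
    """
    df = pd.DataFrame(
        {
            "focal_change": [r.focal_change for r in records],
            "total_change": [r.total_change for r in records],
            "n_context": [r.richness_context for r in records],
        }
    )
    results = [_fit("focal_change ~ total_change", "focal_change ~ total_change", df)]
    dfc = _drop_sparse_levels(df, "n_context", min_level_records)
    if dfc["n_context"].nunique() >= 2:
        results.append(
            _fit("focal_change ~ n_context", "focal_change ~ C(n_context)", dfc)
        )
        results.append(
            _fit(
                "focal_change ~ total_change * n_context",
                "focal_change ~ total_change * C(n_context)",
                dfc,
            )
        )
    else:
        logger.warning("too few richness-context levels for categorical fits")
    # Per-context stratified fits of focal ~ total change.
    for level, sub in dfc.groupby("n_context"):
        if len(sub) >= 3:
            results.append(
                _fit(
                    f"focal_change ~ total_change | {level}",
                    "focal_change ~ total_change",
                    sub,
                )
            )
    return results


def fit_cross_context_models(
    pairs: list[PairedContextRecord], min_level_records: int = 3
) -> list[ModelResult]:
    """Model the high-context interaction effect from (a) the high-context
    total density change, (b) the pair's richness contexts (factor), (c) the
    low-context interaction effect, and (d) total change + low-context effect
    jointly (no interaction term).

    Orientation is bottom-up: the predictor interaction effect always comes
    from the lower richness context, the predicted effect and total change
    from the higher one.
    """
    df = pd.DataFrame(
        {
            "focal_change": [p.high.focal_change for p in pairs],
            "total_change": [p.high.total_change for p in pairs],
            "contexts": [
                f"{p.low.richness_context}&{p.high.richness_context}" for p in pairs
            ],
            "interaction_effect": [p.low.focal_change for p in pairs],
        }
    )
    results = [
        _fit("focal_change ~ total_change", "focal_change ~ total_change", df)
    ]
    dfc = _drop_sparse_levels(df, "contexts", min_level_records)
    if dfc["contexts"].nunique() >= 2:
        results.append(
            _fit("focal_change ~ n_contexts", "focal_change ~ C(contexts)", dfc)
        )
    else:
        logger.warning("too few context-pair levels for the categorical fit")
    results.append(
        _fit(
            "focal_change ~ interaction_effect",
            "focal_change ~ interaction_effect",
            df,
        )
    )
    results.append(
        _fit(
            "focal_change ~ total_change + interaction_effect",
            "focal_change ~ total_change + interaction_effect",
            df,
        )
    )
    return results
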