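"""End-to-end pipeline orchestration.

Stages communicate only through TSV tables in the output directory
(design -> simulate -> abundance -> interactions -> stats), each carrying a
provenance header (config hash, master seed, package version).  Re-running
with the same config and seed is bit-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .abundance import (
    aggregate_replicates,
    detect_members,
    profile_from_exact,
    reallocate_ambiguous,
    to_absolute,
)
from .catalog import IsolateCatalog, read_catalog, synthetic_catalog, write_catalog
from .config import PipelineConfig
from .context_stats import (
    fit_cross_context_models,
    fit_focal_change_models,
    group_comparison,
    pair_across_richness,
    richness_density_stats,
    shift_summary,
)
from .design import CommunityDesign, enumerate_pool_combinations, make_pools
from .glv import child_seed, sample_glv_parameters, serial_passage
from .interactions import (
    compute_all_interactions,
    prune_outliers,
    records_to_frame,
    screen_context_dependence,
)
from .io import frame_to_profiles, profiles_to_frame, read_table, write_table
from .observe import observe_cfu, observe_exact, observe_sequencing

__all__ = ["run_pipeline", "PipelineError"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved on disk."""


def _provenance(config: PipelineConfig) -> dict:
    return {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
    }


def _designs_frame(designs: list[CommunityDesign]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "design_id": [d.design_id for d in designs],
            "replicate": [d.replicate for d in designs],
            "members": [",".join(sorted(d.members)) for d in designs],
            "total_titer": [d.initial_total_titer for d in designs],
        }
    )


def _read_designs(outdir: Path) -> list[CommunityDesign]:
    df = read_table(outdir / "designs.tsv")
    return [
        CommunityDesign(
            design_id=row["design_id"],
            members=frozenset(row["members"].split(",")),
            initial_total_titer=float(row["total_titer"]),
            replicate=int(row["replicate"]),
        )
        for _, row in df.iterrows()
    ]


def stage_design(config: PipelineConfig, outdir: Path) -> None:
    """Build the pooled catalog and all pool-combination designs."""
    dc = config.design
    catalog = synthetic_catalog(
        dc.n_pools * dc.pool_size, dc.n_genera, seed=child_seed(config.seed, "catalog")
    )
    catalog = make_pools(
        catalog, dc.n_pools, dc.pool_size, seed=child_seed(config.seed, "pools")
    )
    write_catalog(catalog, outdir / "catalog.tsv")
    base = enumerate_pool_combinations(catalog, total_titer=dc.total_titer)
    designs = [
        d.with_replicate(r) for d in base for r in range(1, dc.n_replicates + 1)
    ]
    write_table(_designs_frame(designs), outdir / "designs.tsv", _provenance(config))
    logger.info("design: %d communities x %d replicates", len(base), dc.n_replicates)


def _same_genus_ambiguity_sets(catalog: IsolateCatalog) -> list[frozenset[str]]:
    """Congeneric isolates share similar genomes, hence ambiguous reads."""
    by_genus: dict[str, list[str]] = {}
    for iso, genus in zip(catalog.isolate_ids, catalog.genera):
        by_genus.setdefault(genus, []).append(iso)
    return [frozenset(v) for v in by_genus.values() if len(v) > 1]


def stage_simulate(config: PipelineConfig, outdir: Path) -> None:
    """Sample ground-truth GLV parameters, run serial passage for every
    design, and observe each replicate (sequencing counts + CFU plating)."""
    catalog = read_catalog(outdir / "catalog.tsv")
    designs = _read_designs(outdir)
    params = sample_glv_parameters(
        catalog, config.glv, seed=child_seed(config.seed, "glv")
    )
    pframe = pd.DataFrame(params.A, columns=catalog.isolate_ids)
    pframe.insert(0, "isolate_id", catalog.isolate_ids)
    pframe.insert(1, "r", params.r)
    write_table(pframe, outdir / "glv_parameters.tsv", _provenance(config))

    # Dynamics are deterministic: simulate each unique design once.
    truth_rows = []
    finals: dict[str, np.ndarray] = {}
    for design in designs:
        if design.design_id not in finals:
            traj = serial_passage(
                design,
                params,
                config.protocol,
                catalog,
                culture_volume=config.culture_volume,
                extinction_floor=config.extinction_floor,
            )
            finals[design.design_id] = traj.final_state
            for iso, dens in zip(catalog.isolate_ids, traj.final_state):
                if dens > 0:
                    truth_rows.append(
                        {
                            "design_id": design.design_id,
                            "isolate_id": iso,
                            "density": dens,
                        }
                    )
    write_table(pd.DataFrame(truth_rows), outdir / "truth.tsv", _provenance(config))

    obs = config.observation
    amb_sets = _same_genus_ambiguity_sets(catalog) if obs.ambiguous_fraction > 0 else []
    count_rows, tossed_rows, cfu_rows = [], [], []
    amb_rows = [
        {"set_id": f"amb{k + 1:02d}", "isolate_id": iso}
        for k, s in enumerate(amb_sets)
        for iso in sorted(s)
    ]
    set_ids = {s: f"amb{k + 1:02d}" for k, s in enumerate(amb_sets)}
    for design in designs:
        final = finals[design.design_id]
        key = (design.design_id, design.replicate)
        if obs.noise:
            seq = observe_sequencing(
                final,
                list(catalog.isolate_ids),
                depth=obs.depth,
                ambiguity_sets=[s for s in amb_sets if any(
                    final[catalog.index_of(i)] > 0 for i in s
                )],
                ambiguous_fraction=obs.ambiguous_fraction,
                seed=child_seed(config.seed, *key, "seq"),
            )
            # Keep zero-count rows for members of sets holding tossed reads so
            # the reallocation stage sees the full set membership.
            in_tossed_set = set().union(
                *(s for s, t in zip(seq.ambiguity_sets, seq.tossed) if t > 0),
                set(),
            ) & design.members
            for iso, c in zip(seq.isolate_ids, seq.counts):
                if c > 0 or iso in in_tossed_set:
                    count_rows.append(
                        {
                            "design_id": design.design_id,
                            "replicate": design.replicate,
                            "isolate_id": iso,
                            "reads": int(c),
                        }
                    )
            for s, t in zip(seq.ambiguity_sets, seq.tossed):
                if t > 0:
                    tossed_rows.append(
                        {
                            "design_id": design.design_id,
                            "replicate": design.replicate,
                            "set_id": set_ids[s],
                            "tossed": t,
                        }
                    )
            cfu = observe_cfu(
                final,
                plating_cv=obs.plating_cv,
                seed=child_seed(config.seed, *key, "cfu"),
            )
            total = cfu.estimate
        else:
            exact = observe_exact(final, list(catalog.isolate_ids))
            for iso, rel in zip(exact.isolate_ids, exact.relative):
                if rel > 0:
                    count_rows.append(
                        {
                            "design_id": design.design_id,
                            "replicate": design.replicate,
                            "isolate_id": iso,
                            "reads": rel,
                        }
                    )
            total = exact.total_density
        cfu_rows.append(
            {
                "design_id": design.design_id,
                "replicate": design.replicate,
                "total_cfu": total,
            }
        )
    prov = _provenance(config)
    write_table(pd.DataFrame(count_rows), outdir / "counts.tsv", prov)
    write_table(pd.DataFrame(amb_rows), outdir / "ambiguity.tsv", prov)
    write_table(pd.DataFrame(tossed_rows), outdir / "tossed.tsv", prov)
    write_table(pd.DataFrame(cfu_rows), outdir / "cfu.tsv", prov)
    logger.info("simulate: %d communities observed", len(designs))


def stage_abundance(config: PipelineConfig, outdir: Path) -> None:
    """Reallocate ambiguous reads, apply the detection threshold, and convert
    to absolute densities; optionally aggregate replicates."""
    from .observe import SequencingObservation

    counts = read_table(outdir / "counts.tsv")
    cfu = read_table(outdir / "cfu.tsv")
    tossed = read_table(outdir / "tossed.tsv")
    amb = read_table(outdir / "ambiguity.tsv")
    designs = {(d.design_id, d.replicate): d for d in _read_designs(outdir)}

    sets: dict[str, frozenset[str]] = {}
    if len(amb):
        for sid, sub in amb.groupby("set_id"):
            sets[sid] = frozenset(sub["isolate_id"])
    cfu_map = {
        (r["design_id"], int(r["replicate"])): float(r["total_cfu"])
        for _, r in cfu.iterrows()
    }
    tossed_map: dict[tuple, dict[str, int]] = {}
    if len(tossed):
        for _, r in tossed.iterrows():
            tossed_map.setdefault((r["design_id"], int(r["replicate"])), {})[
                r["set_id"]
            ] = int(r["tossed"])

    threshold = config.analysis.detection_threshold
    profiles = []
    skipped = 0
    for (design_id, replicate), sub in counts.groupby(["design_id", "replicate"]):
        key = (design_id, int(replicate))
        raw = dict(zip(sub["isolate_id"], sub["reads"].astype(float)))
        sample_tossed = tossed_map.get(key, {})
        if sample_tossed:
            iso = list(raw)
            obs = SequencingObservation(
                isolate_ids=iso,
                counts=np.rint([raw[i] for i in iso]).astype(np.int64),
                ambiguity_sets=[sets[sid] & set(iso) for sid in sample_tossed],
                tossed=list(sample_tossed.values()),
            )
            raw = reallocate_ambiguous(obs)
        try:
            rel = detect_members(raw, threshold=threshold)
        except ValueError as exc:
            logger.warning("abundance: skipping %s: %s", key, exc)
            skipped += 1
            continue
        total = cfu_map[key]
        if not config.observation.noise:
            # Noise-off totals are exact, so sub-threshold mass is separable
            # and detected densities can be recovered exactly.
            total *= sum(raw[i] for i in rel) / sum(raw.values())
        profiles.append(
            to_absolute(
                rel,
                total,
                design_id=design_id,
                replicate=int(replicate),
                designed_members=designs[key].members if key in designs else None,
            )
        )
    if config.analysis.aggregation == "aggregate":
        by_design: dict[str, list] = {}
        for p in profiles:
            by_design.setdefault(p.design_id, []).append(p)
        profiles = [aggregate_replicates(reps) for reps in by_design.values()]
    write_table(
        profiles_to_frame(profiles), outdir / "profiles.tsv", _provenance(config)
    )
    logger.info("abundance: %d profiles (%d samples skipped)", len(profiles), skipped)


def stage_interactions(config: PipelineConfig, outdir: Path) -> None:
    """Measure all single-interactor interactions, screen context-dependent
    coexistence, and flag per-measure pruning."""
    profiles = frame_to_profiles(read_table(outdir / "profiles.tsv"))
    records = compute_all_interactions(profiles)
    ana = config.analysis
    kept_pop = set(
        id(r) for r in prune_outliers(records, ana.prune_population_on, ana.z_max)
    )
    kept_pc = set(id(r) for r in prune_outliers(records, "per_capita", ana.z_max))
    frame = records_to_frame(records)
    if len(frame):
        frame["kept_population"] = [id(r) in kept_pop for r in records]
        frame["kept_per_capita"] = [id(r) in kept_pc for r in records]
    write_table(frame, outdir / "interactions.tsv", _provenance(config))

    calls = screen_context_dependence(profiles)
    write_table(
        pd.DataFrame(
            [
                {
                    "focal": c.focal,
                    "excluder": c.excluder,
                    "context_coexist": c.context_coexist,
                    "context_excluded": c.context_excluded,
                }
                for c in calls
            ]
        ),
        outdir / "coexistence_calls.tsv",
        _provenance(config),
    )
    logger.info(
        "interactions: %d records (%d kept population, %d kept per-capita), "
        "%d coexistence calls",
        len(records),
        len(kept_pop),
        len(kept_pc),
        len(calls),
    )


def _records_from_frame(outdir: Path, pruned_on: str | None = None):
    from .interactions import InteractionRecord

    df = read_table(outdir / "interactions.tsv")
    if df.empty:
        return []
    if pruned_on is not None and len(df):
        df = df[df[pruned_on]]
    records = []
    for _, row in df.iterrows():
        records.append(
            InteractionRecord(
                focal=row["focal"],
                interactor=row["interactor"],
                background=frozenset(
                    str(row["background"]).split(",")
                )
                if isinstance(row["background"], str) and row["background"]
                else frozenset(),
                context_without=row["context_without"],
                context_with=row["context_with"],
                replicate=int(row["replicate"]),
                richness_context=row["richness_context"],
                n_without=float(row["n_without"]),
                n_with=float(row["n_with"]),
                interactor_density=float(row["interactor_density"]),
                total_without=float(row["total_without"]),
                total_with=float(row["total_with"]),
            )
        )
    return records


def stage_stats(config: PipelineConfig, outdir: Path) -> None:
    """Cross-context statistics: paired shifts, group comparisons,
    richness-density relationships, and the model tables."""
    prov = _provenance(config)
    ana = config.analysis
    catalog = read_catalog(outdir / "catalog.tsv")
    profiles = frame_to_profiles(read_table(outdir / "profiles.tsv"))
    all_records = _records_from_frame(outdir)
    pop_records = _records_from_frame(outdir, "kept_population")
    pc_records = _records_from_frame(outdir, "kept_per_capita")

    shift_frames = []
    for measure, recs in (("pop_effect", pop_records), ("per_capita", pc_records)):
        pairs = pair_across_richness(recs, delta=ana.delta)
        if pairs:
            sf = shift_summary(pairs, measure=measure)
            sf.insert(0, "measure", measure)
            shift_frames.append(sf)
    shifts = (
        pd.concat(shift_frames, ignore_index=True) if shift_frames else pd.DataFrame()
    )
    write_table(shifts, outdir / "shift_summary.tsv", prov)

    group_rows = []
    for measure, recs in (("pop_effect", pop_records), ("per_capita", pc_records)):
        for grouping in ("sign", "same_genus"):
            try:
                group_rows.append(
                    group_comparison(recs, grouping, measure=measure, catalog=catalog)
                )
            except ValueError as exc:
                logger.warning("group comparison %s/%s: %s", grouping, measure, exc)
    write_table(pd.DataFrame(group_rows), outdir / "group_comparisons.tsv", prov)

    try:
        rd = richness_density_stats(profiles, records=all_records)
        pairwise = rd.pop("pairwise_individual_density")
        write_table(pd.DataFrame([rd]), outdir / "richness_density.tsv", prov)
        write_table(pairwise, outdir / "richness_pairwise_ttests.tsv", prov)
    except ValueError as exc:
        logger.warning("richness-density stats unavailable: %s", exc)

    model_rows = []
    if pop_records:
        for res in fit_focal_change_models(pop_records):
            model_rows.append({"table": "focal_change", **res.as_row()})
        pairs = pair_across_richness(pop_records, delta=ana.delta)
        if pairs:
            for res in fit_cross_context_models(pairs):
                model_rows.append({"table": "cross_context", **res.as_row()})
    write_table(pd.DataFrame(model_rows), outdir / "model_summaries.tsv", prov)
    logger.info("stats: %d model fits", len(model_rows))


STAGES = [
    ("design", stage_design),
    ("simulate", stage_simulate),
    ("abundance", stage_abundance),
    ("interactions", stage_interactions),
    ("stats", stage_stats),
]


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Run all stages in order; abort on the first failure, naming the stage
    and preserving partial outputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    for name, stage in STAGES:
        logger.info("--- stage %s ---", name)
        try:
            stage(config, outdir)
        except Exception as exc:
            raise PipelineError(
                f"stage {name!r} failed: {exc}; partial outputs in {outdir}"
            ) from exc
    return outdir
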