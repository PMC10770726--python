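"""Plain-TSV table I/O with provenance headers, and external-data import.

Every table the pipeline writes is tab-separated text preceded by commented
provenance lines (``# key: value``) recording the config hash, master seed and
package version.  Stages communicate only through these declared schemas, so
real relative-abundance and CFU tables can replace the simulator's output.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .abundance import ObservedProfile

__all__ = [
    "write_table",
    "read_table",
    "read_provenance",
    "profiles_to_frame",
    "frame_to_profiles",
    "import_external",
    "SchemaError",
]


class SchemaError(ValueError):
    """A table does not match its declared schema."""


def write_table(df: pd.DataFrame, path, provenance: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = _io.StringIO()
    for key, value in (provenance or {}).items():
        buf.write(f"# {key}: {value}\n")
    df.to_csv(buf, sep="\t", index=False)
    path.write_text(buf.getvalue())


def read_table(path) -> pd.DataFrame:
    try:
        # round_trip parsing so write -> read -> write is byte-identical
        return pd.read_csv(
            path, sep="\t", comment="#", float_precision="round_trip"
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame()


def read_provenance(path) -> dict:
    out = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition(":")
            out[key.strip()] = value.strip()
    return out


def profiles_to_frame(profiles: list[ObservedProfile]) -> pd.DataFrame:
    """Long-format profile table: one row per detected member."""
    rows = []
    for p in profiles:
        designed = (
            ",".join(sorted(p.designed_members))
            if p.designed_members is not None
            else ""
        )
        for iso in sorted(p.relative_abundance):
            rows.append(
                {
                    "design_id": p.design_id,
                    "replicate": p.replicate,
                    "isolate_id": iso,
                    "relative_abundance": p.relative_abundance[iso],
                    "total_density": p.total_density,
                    "absolute_density": p.relative_abundance[iso] * p.total_density,
                    "designed_members": designed,
                }
            )
    return pd.DataFrame(rows)


def frame_to_profiles(df: pd.DataFrame) -> list[ObservedProfile]:
    if df.empty:
        return []
    profiles = []
    for (design_id, replicate), sub in df.groupby(
        ["design_id", "replicate"], sort=True
    ):
        designed = None
        if "designed_members" in sub and isinstance(
            sub["designed_members"].iloc[0], str
        ):
            raw = sub["designed_members"].iloc[0]
            if raw:
                designed = frozenset(raw.split(","))
        rel = dict(zip(sub["isolate_id"], sub["relative_abundance"]))
        s = sum(rel.values())
        if abs(s - 1.0) > 1e-6:
            raise SchemaError(
                f"design {design_id} rep {replicate}: relative abundances sum "
                f"to {s:.6g}, not 1"
            )
        rel = {k: v / s for k, v in rel.items()}
        profiles.append(
            ObservedProfile(
                design_id=str(design_id),
                replicate=int(replicate),
                relative_abundance=rel,
                total_density=float(sub["total_density"].iloc[0]),
                designed_members=designed,
            )
        )
    return profiles


def _require_columns(df: pd.DataFrame, cols: list[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing columns {missing}")


def import_external(
    counts_path,
    cfu_path,
    ambiguity_path=None,
    tossed_path=None,
    threshold: float = 0.01,
) -> list[ObservedProfile]:
    """Build observed profiles from externally supplied tables.

    ``counts_path``: TSV with design_id, replicate, isolate_id, reads
    (unambiguous read counts, or already-corrected counts).
    ``cfu_path``: TSV with design_id, replicate, total_cfu (CFU/uL estimate).
    ``ambiguity_path`` (optional): TSV with set_id, isolate_id defining
    disjoint ambiguity sets; ``tossed_path`` then gives design_id, replicate,
    set_id, tossed read counts to reallocate.

    Schema violations are reported with 1-based data row numbers.
    """
    from .abundance import detect_members, reallocate_ambiguous, to_absolute
    from .observe import SequencingObservation

    counts = read_table(counts_path)
    _require_columns(counts, ["design_id", "replicate", "isolate_id", "reads"], "counts")
    for i, row in counts.iterrows():
        if pd.isna(row["reads"]) or row["reads"] < 0:
            raise SchemaError(f"counts row {i + 1}: invalid read count {row['reads']!r}")

    cfu = read_table(cfu_path)
    _require_columns(cfu, ["design_id", "replicate", "total_cfu"], "cfu")
    for i, row in cfu.iterrows():
        if pd.isna(row["total_cfu"]) or row["total_cfu"] < 0:
            raise SchemaError(f"cfu row {i + 1}: invalid total_cfu {row['total_cfu']!r}")
    cfu_map = {
        (str(r["design_id"]), int(r["replicate"])): float(r["total_cfu"])
        for _, r in cfu.iterrows()
    }

    sets: list[frozenset[str]] = []
    set_order: list = []
    if ambiguity_path is not None:
        amb = read_table(ambiguity_path)
        _require_columns(amb, ["set_id", "isolate_id"], "ambiguity")
        grouped = amb.groupby("set_id")["isolate_id"].apply(list)
        set_order = list(grouped.index)
        sets = [frozenset(map(str, v)) for v in grouped.values]

    tossed_map: dict[tuple[str, int], dict] = {}
    if tossed_path is not None:
        tos = read_table(tossed_path)
        _require_columns(tos, ["design_id", "replicate", "set_id", "tossed"], "tossed")
        for i, row in tos.iterrows():
            if pd.isna(row["tossed"]) or row["tossed"] < 0:
                raise SchemaError(f"tossed row {i + 1}: invalid tossed {row['tossed']!r}")
            key = (str(row["design_id"]), int(row["replicate"]))
            tossed_map.setdefault(key, {})[row["set_id"]] = int(row["tossed"])

    profiles = []
    for (design_id, replicate), sub in counts.groupby(["design_id", "replicate"]):
        key = (str(design_id), int(replicate))
        if key not in cfu_map:
            raise SchemaError(
                f"no CFU estimate for design {design_id} replicate {replicate}"
            )
        iso = [str(x) for x in sub["isolate_id"]]
        sample_tossed = tossed_map.get(key, {})
        set_by_id = dict(zip(set_order, sets))
        obs = SequencingObservation(
            isolate_ids=iso,
            counts=np.asarray(sub["reads"], dtype=np.int64)
            if np.issubdtype(sub["reads"].dtype, np.integer)
            else np.rint(sub["reads"]).astype(np.int64),
            # sets are intersected with the sample's observed isolates
            ambiguity_sets=[set_by_id[sid] & set(iso) for sid in sample_tossed],
            tossed=list(sample_tossed.values()),
        )
        corrected = reallocate_ambiguous(obs)
        rel = detect_members(corrected, threshold=threshold)
        profiles.append(
            to_absolute(
                rel,
                cfu_map[key],
                design_id=str(design_id),
                replicate=int(replicate),
            )
        )
    return profiles
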