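"""Isolate catalog: who the community members are and how they are pooled.

The catalog is the single source of truth for isolate identity, genus label,
and pool assignment.  All density vectors downstream are indexed in catalog
order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["IsolateCatalog", "synthetic_catalog", "read_catalog", "write_catalog"]

UNPOOLED = -1


@dataclass
class IsolateCatalog:
    """Ordered collection of isolates with genus labels and pool assignments.

    Parameters
    ----------
    isolate_ids : list of str
        Unique short identifiers, one per isolate.
    genera : list of str
        Genus label per isolate (parallel to ``isolate_ids``).
    pool_ids : list of int, optional
        Pool assignment per isolate, 1-based; ``-1`` means unassigned.
    """

    isolate_ids: list[str]
    genera: list[str]
    pool_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.isolate_ids)) != len(self.isolate_ids):
            raise ValueError("isolate_ids must be unique")
        if len(self.genera) != len(self.isolate_ids):
            raise ValueError(
                f"{len(self.genera)} genus labels for {len(self.isolate_ids)} isolates"
            )
        if not self.pool_ids:
            self.pool_ids = [UNPOOLED] * len(self.isolate_ids)
        if len(self.pool_ids) != len(self.isolate_ids):
            raise ValueError("pool_ids length must match isolate_ids")
        self._index = {iso: i for i, iso in enumerate(self.isolate_ids)}

    def __len__(self) -> int:
        return len(self.isolate_ids)

    def index_of(self, isolate_id: str) -> int:
        return self._index[isolate_id]

    def genus_of(self, isolate_id: str) -> str:
        return self.genera[self._index[isolate_id]]

    @property
    def pools(self) -> dict[int, list[str]]:
        """Mapping pool_id -> member isolate ids (assigned pools only)."""
        out: dict[int, list[str]] = {}
        for iso, pid in zip(self.isolate_ids, self.pool_ids):
            if pid != UNPOOLED:
                out.setdefault(pid, []).append(iso)
        return out

    def validate_pools(self, pool_size: int | None = None) -> None:
        """Check pools are disjoint (guaranteed by construction) and equal-sized."""
        pools = self.pools
        if not pools:
            raise ValueError("no pools assigned")
        sizes = {pid: len(members) for pid, members in pools.items()}
        if pool_size is not None:
            bad = {pid: n for pid, n in sizes.items() if n != pool_size}
            if bad:
                raise ValueError(f"pools with size != {pool_size}: {bad}")
        elif len(set(sizes.values())) > 1:
            raise ValueError(f"unequal pool sizes: {sizes}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "isolate_id": self.isolate_ids,
                "genus": self.genera,
                "pool_id": self.pool_ids,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "IsolateCatalog":
        return cls(
            isolate_ids=[str(x) for x in df["isolate_id"]],
            genera=[str(x) for x in df["genus"]],
            pool_ids=[int(x) for x in df["pool_id"]] if "pool_id" in df else [],
        )


def synthetic_catalog(
    n_isolates: int, n_genera: int, seed: int = 0, prefix: str = "iso"
) -> IsolateCatalog:
    """Generate a synthetic isolate catalog with genus labels.

    Every genus gets at least one isolate; remaining isolates are assigned
    to genera at random (so some genera hold several congeneric isolates,
    as in real leaf-microbiome collections).
    """
    import numpy as np

    if n_genera > n_isolates:
        raise ValueError("cannot have more genera than isolates")
    rng = np.random.default_rng(seed)
    genus_names = [f"genus{g + 1:02d}" for g in range(n_genera)]
    assignment = list(range(n_genera)) + list(
        rng.integers(0, n_genera, n_isolates - n_genera)
    )
    rng.shuffle(assignment)
    return IsolateCatalog(
        isolate_ids=[f"{prefix}{i + 1:02d}" for i in range(n_isolates)],
        genera=[genus_names[g] for g in assignment],
    )


def read_catalog(path) -> IsolateCatalog:
    """Read an isolate catalog from TSV (columns isolate_id, genus, pool_id)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return IsolateCatalog.from_frame(df)


def write_catalog(catalog: IsolateCatalog, path) -> None:
    catalog.to_frame().to_csv(path, sep="\t", index=False)
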