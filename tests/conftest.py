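import numpy as np
import pytest

from commix.catalog import IsolateCatalog, synthetic_catalog
from commix.design import CommunityDesign, PassageProtocol, make_pools


@pytest.fixture
def catalog6() -> IsolateCatalog:
    """Six isolates, three genera (two congeneric pairs + two singletons)."""
    return IsolateCatalog(
        isolate_ids=["isoA", "isoB", "isoC", "isoD", "isoE", "isoF"],
        genera=["g1", "g1", "g2", "g2", "g3", "g3"],
    )


@pytest.fixture
def catalog56() -> IsolateCatalog:
    """The full-scale design: 56 isolates over 21 genera, pooled 7 x 8."""
    cat = synthetic_catalog(56, 21, seed=11)
    return make_pools(cat, n_pools=7, pool_size=8, seed=11)


@pytest.fixture
def protocol() -> PassageProtocol:
    return PassageProtocol(dilution_factor=0.01, cycle_hours=24.0, n_cycles=6)


def competition_params(catalog, seed=0, scale=0.4, capacity_sd=0.2):
    """All-negative (purely competitive) GLV parameter draw for tests."""
    from commix.scenarios import competition_parameters

    return competition_parameters(catalog, seed=seed, scale=scale, capacity_sd=capacity_sd)
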