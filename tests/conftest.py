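import numpy as np
import pytest

from pollinet import InteractionNetwork, SpeciesInfo


def make_network(
    counts,
    plant_ids=None,
    pollinator_ids=None,
    site="S1",
    treatment="restored",
    period="2012-09",
    vertebrates=(),
):
    counts = np.asarray(counts)
    n_p, n_a = counts.shape
    plant_ids = plant_ids or tuple(f"p{i + 1}" for i in range(n_p))
    pollinator_ids = pollinator_ids or tuple(f"a{k + 1}" for k in range(n_a))
    meta = {p: SpeciesInfo(guild="plant", taxon_group="Angiospermae") for p in plant_ids}
    for a in pollinator_ids:
        vert = a in vertebrates
        meta[a] = SpeciesInfo(
            guild="pollinator",
            taxon_group="Gekkonidae" if vert else "Hymenoptera",
            is_vertebrate=vert,
        )
    return InteractionNetwork(
        plant_ids=tuple(plant_ids),
        pollinator_ids=tuple(pollinator_ids),
        counts=counts,
        site_id=site,
        treatment=treatment,
        period=period,
        species_meta=meta,
    )


@pytest.fixture
def small_net():
    """4 plants x 4 pollinators, connected, moderately nested."""
    return make_network(
        [
            [5, 3, 2, 1],
            [4, 2, 1, 0],
            [3, 1, 0, 0],
            [2, 0, 0, 0],
        ]
    )


@pytest.fixture
def two_blocks_net():
    """Two disjoint K2,2 blocks with unit weights."""
    return make_network(
        [
            [1, 1, 0, 0],
            [1, 1, 0, 0],
            [0, 0, 1, 1],
            [0, 0, 1, 1],
        ]
    )
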