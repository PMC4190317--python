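import numpy as np
import pytest

from phylobeta.io import CommunityMatrix, SiteRecord
from phylobeta.phylogeny import assemble_community_tree, parse_newick
from phylobeta.synth import ScenarioConfig, simulate_bundle

BALANCED_4 = "((A:1,B:1):1,(C:1,D:1):1);"


@pytest.fixture
def four_taxon_tree():
    return parse_newick(BALANCED_4)


@pytest.fixture
def small_matrix():
    # 3 sites x 4 species, all patterns of sharing represented
    return CommunityMatrix(
        sites=["s1", "s2", "s3"],
        species=["A", "B", "C", "D"],
        occupancy=np.array([[1, 1, 0, 0], [0, 1, 1, 0], [1, 0, 1, 1]]),
    )


def make_site(site_id, lon, lat, **over):
    climate = {
        "ANNT": 20.0, "MAXT": 28.0, "MINT": 12.0, "DIFT": 16.0,
        "PPT": 1500.0, "PPTS": 40.0, "PPTW": 600.0, "PPTD": 120.0, "DIFP": 480.0,
        "MAEL": 800.0, "MIEL": 100.0, "DIEL": 700.0,
    }
    climate.update(over)
    return SiteRecord(site_id=site_id, longitude=lon, latitude=lat, climate=climate)


@pytest.fixture(scope="session")
def bundle():
    """One study-scale synthetic bundle shared by read-only tests."""
    return simulate_bundle(ScenarioConfig(seed=11))


@pytest.fixture(scope="session")
def assembled_tree(bundle):
    return assemble_community_tree(bundle.master_tree, bundle.matrix.species,
                                   bundle.graft_rules)
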