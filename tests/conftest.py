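import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from karstpatch import geometry, phylo

settings.register_profile(
    "ci", deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

#: 4-taxon toy tree used throughout: d(A,B)=2, d(C,D)=4, cross pairs 5
TOY_NEWICK = "((A:1,B:1):1,(C:2,D:2):1);"


@pytest.fixture(scope="session")
def toy_tree() -> phylo.PhyloTree:
    return phylo.parse_newick(TOY_NEWICK)


@pytest.fixture(scope="session")
def toy_dist(toy_tree) -> phylo.DistanceMatrix:
    return toy_tree.cophenetic()


@pytest.fixture
def grid_factory():
    def make(depths, cell_side=0.39) -> geometry.SoilGrid:
        return geometry.SoilGrid(depths=np.asarray(depths, dtype=float), cell_side=cell_side)

    return make
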