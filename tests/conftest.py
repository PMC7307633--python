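import numpy as np
import pytest

from pcxdend.swc import SOMA, APICAL, BASAL, NeuronMorphology, SwcNode
from pcxdend.synth.morpho import default_layer_geometry


TOY_SWC = """\
# soma root, apical chain bifurcating into two tips
1 1 0 0 0 5 -1
2 4 0 25 0 1 1
3 4 0 50 0 1 2
4 4 0 75 0 1 3
5 4 0 100 0 1 4
6 4 25 50 0 1 3
7 4 50 50 0 1 6
"""


@pytest.fixture
def toy_swc_path(tmp_path):
    p = tmp_path / "toy.swc"
    p.write_text(TOY_SWC)
    return p


@pytest.fixture
def band_geometry():
    """Parallel straight boundaries: L1a/L1b at y=-80, L1b/L2a at y=0,
    L2/L3 at y=120 (layer-2 width 120 µm), depth increasing with +y."""
    return default_layer_geometry()


def random_tree(rng, n_branch_nodes=60, p_apical=0.7):
    """A random valid soma-rooted tree for partition/oracle tests."""
    nodes = [SwcNode(1, SOMA, 0.0, 0.0, 0.0, 5.0, -1)]
    for _ in range(n_branch_nodes):
        parent = nodes[int(rng.integers(len(nodes)))]
        if parent.type_code == SOMA:
            tcode = APICAL if rng.random() < p_apical else BASAL
        else:
            tcode = parent.type_code          # compartments stay connected
        xyz = parent.xyz + rng.normal(0, 12, size=3)
        nodes.append(SwcNode(len(nodes) + 1, tcode, *xyz, 0.5, parent.id))
    return NeuronMorphology(nodes)
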