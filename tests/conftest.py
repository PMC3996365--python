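import numpy as np
import pytest
from scipy import ndimage

from hepaq3d.cellshape import CellShapeParams, analyze_cells, approximate_cells
from hepaq3d.core import LabelVolume
from hepaq3d.graph import SpatialGraph
from hepaq3d.networks import segment_bile, segment_sinusoids
from hepaq3d.nuclei import classify_nuclei, score_brdu, segment_nuclei
from hepaq3d.presets import (
    default_bile_params,
    default_nuclei_params,
    default_sinusoid_params,
)
from hepaq3d.synthetic import NoiseSpec, PhantomSpec, generate

import networkx as nx


@pytest.fixture(scope="session")
def default_phantom():
    """The default seeded phantom: the reference end-to-end test condition."""
    return generate(PhantomSpec(seed=0))


@pytest.fixture(scope="session")
def clean_phantom():
    """Same geometry as the default phantom, but no noise and no blur."""
    return generate(PhantomSpec(seed=0, noise=NoiseSpec(0.0, 0.0), blur=None))


@pytest.fixture(scope="session")
def analyzed(default_phantom):
    """Default phantom pushed through the default segmentation pipelines."""
    ph = default_phantom
    sin = segment_sinusoids(
        ph.channels["DPPIV"], ph.channels["DMs"], default_sinusoid_params()
    )
    bile = segment_bile(ph.channels["DPPIV"], sin, default_bile_params())
    npar = default_nuclei_params()
    labels = segment_nuclei(ph.channels["DAPI"], npar)
    hep, non_hep, records = classify_nuclei(labels, npar)
    records = score_brdu(records, labels, ph.channels["BrdU"], 100)
    return {
        "phantom": ph,
        "sinusoid": sin,
        "bile": bile,
        "nuclei_labels": labels,
        "hep_mask": hep,
        "non_hep_mask": non_hep,
        "records": records,
        "nuclei_params": npar,
    }


def make_graph(positions, edges, radii=None, network_type="sinusoid"):
    """Build a SpatialGraph from {id: (x, y, z)} positions and edge pairs."""
    g = nx.Graph()
    for v, pos in positions.items():
        g.add_node(
            v,
            pos=np.asarray(pos, dtype=np.float64),
            radius=0.0 if radii is None else float(radii.get(v, 0.0)),
        )
    g.add_edges_from(edges)
    return SpatialGraph(g, network_type, (1.0, 1.0, 1.0))


def h_graph(arm=2.0, bar=4.0):
    """H-shaped graph: two degree-3 nodes joined by one edge, four leaves."""
    pos = {
        0: (0.0, 0.0, 0.0),
        1: (bar, 0.0, 0.0),
        2: (-arm, arm, 0.0),
        3: (-arm, -arm, 0.0),
        4: (bar + arm, arm, 0.0),
        5: (bar + arm, -arm, 0.0),
    }
    edges = [(0, 1), (0, 2), (0, 3), (1, 4), (1, 5)]
    return make_graph(pos, edges)


def count_cavities(mask_data):
    """Number of 6-connected background components not touching the border."""
    bg, n = ndimage.label(~mask_data, structure=ndimage.generate_binary_structure(3, 1))
    touching = set()
    for sl in (
        bg[0], bg[-1], bg[:, 0], bg[:, -1], bg[:, :, 0], bg[:, :, -1]
    ):
        touching.update(np.unique(sl))
    return sum(1 for i in range(1, n + 1) if i not in touching)


def dice(a, b):
    return 2.0 * (a & b).sum() / (a.sum() + b.sum())
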