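import numpy as np
import pytest

from vasctree.graph import (
    build_geometric_graph,
    detect_topology_abnormalities,
    track_trees,
)
from vasctree.skeleton import OpticDisc, detect_landmarks, skeletonize
from vasctree.synthetic import TreeSpec, generate_tree


@pytest.fixture(scope="session")
def tree_spec():
    return TreeSpec()


@pytest.fixture(scope="session")
def od(tree_spec):
    return OpticDisc(center=tree_spec.root, radius=20.0)


@pytest.fixture(scope="session")
def clean_tree(tree_spec):
    """A clean depth-3 binary tree fixture: (mask, fov, truth)."""
    return generate_tree(tree_spec)


def analyze_mask(mask, fov, od):
    """Shared mini-pipeline: skeleton -> landmarks -> graph -> trees -> topo."""
    skel = skeletonize(mask)
    lm = detect_landmarks(skel, od=od, fov=fov)
    g = build_geometric_graph(skel, lm)
    trees, orphans = track_trees(g)
    report = detect_topology_abnormalities(g, trees, orphans)
    return skel, lm, g, trees, report


@pytest.fixture(scope="session")
def clean_analysis(clean_tree, od):
    mask, fov, truth = clean_tree
    return analyze_mask(mask, fov, od)


def straight_tube(width: int, length: int = 60, shape=(80, 80)) -> np.ndarray:
    """Horizontal constant-width tube centred in the raster."""
    mask = np.zeros(shape, dtype=bool)
    row = shape[0] // 2
    half = width // 2
    c0 = (shape[1] - length) // 2
    if width % 2:
        mask[row - half : row + half + 1, c0 : c0 + length] = True
    else:
        mask[row - half : row + half, c0 : c0 + length] = True
    return mask


def symmetric_y(shape=(64, 64)) -> np.ndarray:
    """1-px-wide Y: a vertical stem splitting into two diagonal arms."""
    skel = np.zeros(shape, dtype=bool)
    cr, cc = 32, 32
    for i in range(20):
        skel[cr + i, cc] = True  # stem downward
    for i in range(1, 20):
        skel[cr - i, cc - i] = True
        skel[cr - i, cc + i] = True
    return skel
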