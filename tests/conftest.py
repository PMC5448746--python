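import numpy as np
import pytest

from ricecanopy import datamodel, reconstruct, synthetic


@pytest.fixture(scope="session")
def small_arch():
    """Seeded 8-hill canopy, small enough for fast profile tests."""
    tpl = synthetic.PlantTemplate(seed=11, tillers_per_hill=3, leaves_per_tiller=4)
    return synthetic.generate_architecture(tpl, synthetic.default_context())


@pytest.fixture(scope="session")
def one_tiller():
    tpl = synthetic.PlantTemplate(seed=4, tillers_per_hill=1, leaves_per_tiller=4)
    arch = synthetic.generate_architecture(tpl, synthetic.default_context(rows=1, cols=1))
    return arch.hills[0].tillers[0]


def flat_rectangle_leaf(length=10.0, halfwidth=1.0, z=0.0, azimuth=0.0, n=51, base_xy=(0.0, 0.0)):
    """Hand-built horizontal rectangular leaf at height ``z`` along +x."""
    m = datamodel.MidribCurve2D(
        points=np.array([[0.0, 0.0], [length, 0.0]]),
        fit=np.array([0.0, 1.0, 0.0, 0.0, 0.0, 0.0]),
        length=length,
    )
    samples = np.column_stack([np.linspace(0, length, n), np.full(n, halfwidth)])
    samples[-1, 1] = 0.0  # nominal sharp tip so validation accepts the record
    shape = datamodel.LeafShapeProfile(
        samples=samples, poly=np.array([0, 0, 0, 0, 0, 0, halfwidth], dtype=float)
    )
    sl = max(z, 1.0) + 5.0
    bx, by = base_xy
    stem = datamodel.StemRecord(
        length=sl,
        radius_profile=[[0.0, 0.3], [sl, 0.3]],
        axis_bottom=np.array([bx, by, 0.0]),
        axis_top=np.array([bx, by, sl]),
    )
    leaf = datamodel.LeafRecord(
        azimuth=azimuth, node_image=np.array([0.0, z]), midrib2d=m, shape=shape
    )
    leaf.node3d = reconstruct.leaf_node_3d(leaf.node_image, azimuth, stem)
    leaf.midrib3d = reconstruct.midrib_3d(m, azimuth, leaf.node3d, stem, n)
    leaf.edges3d = reconstruct.leaf_edges_3d(leaf.midrib3d, leaf.shape)
    return leaf, stem


def single_leaf_architecture(leaf, stem, ctx=None):
    ctx = ctx or synthetic.default_context(rows=1, cols=1)
    hill = datamodel.Hill(datamodel.HillPosition(1, 1), (0.0, 0.0), [datamodel.Tiller(stem, [leaf])])
    return datamodel.DigitalArchitecture(context=ctx, hills=[hill])
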