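import numpy as np
import pytest

from neglectmap.disconnect import StreamlineSet
from neglectmap.synthetic import (
    default_tract_grouping,
    make_lesions,
    make_parcellation,
    make_streamlines,
    make_template,
)
from neglectmap.volumes import LesionMask


@pytest.fixture(scope="session")
def template24():
    return make_template((24, 24, 24))


@pytest.fixture(scope="session")
def parcellation24(template24):
    return make_parcellation(template24, n_cortical_per_hemi=6, n_subcortical=3, seed=0)


@pytest.fixture(scope="session")
def grouping24(parcellation24):
    return default_tract_grouping(parcellation24, n_tracts=4, edges_per_tract=2, seed=0)


@pytest.fixture(scope="session")
def streamlines24(parcellation24, grouping24):
    return make_streamlines(parcellation24, grouping24, n_per_edge=8, seed=1)


@pytest.fixture(scope="session")
def cohort24(template24):
    return make_lesions(template24, 30, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def straight_streamline(template, start_vox, end_vox, n=None):
    """Dense straight polyline between two voxel centres (helper)."""
    p0 = template.voxel_to_world(np.asarray(start_vox))
    p1 = template.voxel_to_world(np.asarray(end_vox))
    if n is None:
        n = max(2, int(np.ceil(np.linalg.norm(p1 - p0) / (0.5 * min(template.spacing_mm)))))
    t = np.linspace(0, 1, n + 1)[:, None]
    return p0 + t * (p1 - p0)


def mask_from_voxels(template, voxels):
    data = np.zeros(template.shape, dtype=bool)
    for v in voxels:
        data[tuple(v)] = True
    return LesionMask(template=template, data=data)


def mask_with_count(template, n_voxels, offset=0):
    """Mask whose first ``n_voxels`` flat entries (after offset) are lesioned."""
    data = np.zeros(template.n_voxels, dtype=bool)
    data[offset:offset + n_voxels] = True
    return LesionMask(template=template, data=data.reshape(template.shape))
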