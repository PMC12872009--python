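import numpy as np
import pytest

from cordpop.geometry import (Footprint, GeometryConfig, LabeledMesh,
                              build_cross_section, voxelize)
from cordpop.morphology import PopulationSpec, make_subject


@pytest.fixture(scope="session")
def mean_subject():
    """The population-mean subject (cord 9.8 x 6.3 mm, canal 11.6 x 8.1)."""
    return make_subject("S0", scow=9.8, scod=6.3, scw=11.6, scd=8.1)


@pytest.fixture(scope="session")
def default_spec():
    return PopulationSpec(n_subjects=40, rng_seed=1)


@pytest.fixture(scope="session")
def mean_section(mean_subject):
    return build_cross_section(mean_subject, GeometryConfig())


@pytest.fixture(scope="session")
def mean_mesh(mean_section):
    return voxelize(mean_section)


def toy_strain_field(labels, strains, evols=None, xs=None, ys=None,
                     ipsi_sign=1.0, voxel_size=1.0, cord_rx=5.0,
                     cord_ry=3.0):
    """Hand-built strain field for enumeration oracles."""
    from cordpop.surrogate import StrainField

    labels = np.asarray(labels, dtype=np.int8)
    n = labels.size
    strains = np.asarray(strains, dtype=float)
    evols = np.ones(n) if evols is None else np.asarray(evols, dtype=float)
    xs = np.zeros(n) if xs is None else np.asarray(xs, dtype=float)
    ys = np.zeros(n) if ys is None else np.asarray(ys, dtype=float)
    mesh = LabeledMesh(x=xs, y=ys, evol=evols, label=labels,
                       voxel_size=voxel_size, slab_thickness=1.0,
                       ipsi_sign=ipsi_sign, cord_rx=cord_rx, cord_ry=cord_ry)
    fp = Footprint(center=0.5, radius=2.5, lo=-2.0, hi=2.5 + 0.5,
                   overhang_ipsi=False, overhang_contra=False,
                   overhang_fraction=0.0)
    return StrainField(mesh=mesh, min_lep=strains, footprint=fp)
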