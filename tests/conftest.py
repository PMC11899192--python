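import dataclasses

import numpy as np
import pytest

from fibmorph import PhantomSpec, default_cohort_spec, make_annulus_phantom


@pytest.fixture(scope="session")
def average_annulus():
    """Phantom with the cohort-average geometry (D_out 10.9, wall 2.7 mm)."""
    spec = PhantomSpec(outer_diameter=10.9, wall_thickness=2.7)
    image, bone, marrow, truth = make_annulus_phantom(spec, rng=0)
    return spec, image, bone, marrow, truth


@pytest.fixture(scope="session")
def triangular_annulus():
    """Deformed phantom with the k=3 (triangular periosteum) harmonic."""
    spec = PhantomSpec(
        outer_diameter=10.9,
        wall_thickness=2.7,
        deformation_harmonics=((3, 0.1, 0.4),),
    )
    image, bone, marrow, truth = make_annulus_phantom(spec, rng=0)
    return spec, image, bone, marrow, truth


@pytest.fixture()
def small_cohort_spec():
    """Default cohort shrunk to 4 subjects per group (fast image mode)."""
    spec = default_cohort_spec(seed=11)
    groups = {n: dataclasses.replace(g, n=4) for n, g in spec.groups.items()}
    return dataclasses.replace(spec, groups=groups)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
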