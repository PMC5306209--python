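import numpy as np
import pytest

from atriashape import make_sphere_template
from atriashape.synthetic import CohortConfig, _deform_template, _subject_map


@pytest.fixture(scope="session")
def template():
    return make_sphere_template(20.0)


@pytest.fixture(scope="session")
def ellipsoid_mesh(template):
    """Axis-aligned ellipsoid (35, 20, 30) mm from the template."""
    mesh = template.copy()
    S = np.diag([35 / 20, 20 / 20, 30 / 20])
    for attr in ("positions", "deriv_u", "deriv_v", "deriv_uv"):
        setattr(mesh, attr, getattr(mesh, attr) @ S.T)
    return mesh


@pytest.fixture(scope="session")
def egg_mesh(template):
    """Asymmetric 'egg': ellipsoid with superior AP widths scaled up."""
    latent = dict(radius_lr=28.0, radius_ap=20.0, radius_fh=30.0,
                  prominence=0.0, prominence_width=0.55, gamma=1.2)
    return _deform_template(template, _subject_map(latent))


@pytest.fixture(scope="session")
def small_cohort():
    """Shared 40-subject synthetic cohort (no clouds), moderate signal."""
    from atriashape.synthetic import generate_cohort

    return generate_cohort(CohortConfig(n_subjects=40, seed=7), with_clouds=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
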