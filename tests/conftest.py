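import numpy as np
import pytest

import protherm as pt
from protherm.hde import GeometryModel

try:  # configure hypothesis only when installed
    from hypothesis import HealthCheck, settings

    settings.register_profile(
        "protherm",
        derandomize=True,
        deadline=None,
        suppress_health_check=[HealthCheck.too_slow],
    )
    settings.load_profile("protherm")
except ImportError:  # pragma: no cover
    pass


#: Mb-like spherical ground truth (filling-basis radius), used across tests.
MB_SPHERE = dict(
    model=GeometryModel.SPHERE,
    kappa_true=0.10,
    g_true=255.0,
    radius_nm=1.529,
    cp_kj_mol_k=27.0,
)

#: GFP-like cylinder ground truth shared by the direction analyses.
GFP_CYLINDER = dict(
    radius_nm=1.2,
    height_nm=4.0,
    cp_kj_mol_k=47.0,
)


@pytest.fixture(scope="session")
def mb_sphere_shape():
    return pt.ShapeEstimate(model="sphere", R_s=MB_SPHERE["radius_nm"])


@pytest.fixture(scope="session")
def gfp_cylinder_shape():
    return pt.ShapeEstimate(
        model="cylinder",
        R_c=GFP_CYLINDER["radius_nm"],
        H_c=GFP_CYLINDER["height_nm"],
    )


@pytest.fixture(scope="session")
def mb_clean_trace():
    """Noise-free Mb-like relaxation trace (400 -> 300 K over 100 ps)."""
    spec = pt.SyntheticSpec(noise_sd_K=0.0, n_replicates=1, **MB_SPHERE)
    return pt.generate_traces(spec, method="series", n_terms=200)[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
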