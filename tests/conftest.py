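import numpy as np
import pytest

from lakebloom import BandSpec, GridTransform, S2A_WAVELENGTHS, Scene, SimConfig, generate_region


@pytest.fixture(scope="session")
def s2a_bands():
    roles = ("green", "red", "nir", "swir")
    return [BandSpec(role, i, S2A_WAVELENGTHS[role]) for i, role in enumerate(roles)]


def make_scene(values_by_role: dict[str, float | np.ndarray], shape=(4, 4),
               pixel_size=20.0, date_tag="2021-06") -> Scene:
    """Scene with constant (or given) reflectance per role, S2A band order."""
    roles = ("green", "red", "nir", "swir")
    refl = np.empty((len(roles), *shape))
    for i, role in enumerate(roles):
        refl[i] = values_by_role.get(role, 0.0)
    transform = GridTransform.from_origin(0.0, shape[0] * pixel_size, pixel_size)
    nodata = ~np.all(np.isfinite(refl), axis=0)
    return Scene(date_tag, refl, transform, nodata)


@pytest.fixture(scope="session")
def noiseless_region():
    """Six-lake noiseless synthetic region: pipeline results must equal truth exactly."""
    cfg = SimConfig(seed=11, n_lakes=6, grid_shape=(256, 256), n_months=8, noise_sd=0.0)
    return generate_region(cfg)


@pytest.fixture(scope="session")
def noisy_region():
    cfg = SimConfig(seed=12, n_lakes=6, grid_shape=(256, 256), n_months=8, noise_sd=0.01)
    return generate_region(cfg)
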