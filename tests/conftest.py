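import numpy as np
import pytest

import spillrecon as sr


@pytest.fixture(scope="session")
def small_grid():
    return sr.ImageGrid((32, 32), (3.0, 3.0))


@pytest.fixture(scope="session")
def small_geom():
    return sr.ProjectionGeometry(n_views=28, n_tang=40, bin_size=3.0)


@pytest.fixture(scope="session")
def psf42():
    return sr.PSFModel(4.2, 4.2)


@pytest.fixture(scope="session")
def small_model(small_geom, small_grid, psf42):
    return sr.SystemModel(small_geom, small_grid, rays_per_bin=2, psf=psf42)


@pytest.fixture(scope="session")
def bladder_box_problem(small_grid, small_model):
    """Noise-free bladder-only data with an exact background term."""
    rng = np.random.default_rng(1)
    M = 0.5 + 0.5 * rng.random(small_model.sinogram_shape)
    A = 0.1 * np.ones(small_model.sinogram_shape)
    ph = np.zeros(small_grid.shape)
    ph[10:20, 10:20] = 50.0
    mask = ph > 0
    P_exact = M * small_model.forward(ph)
    y = P_exact + A
    ss = sr.SinogramSet(y=y, M=M, A=A, geometry=small_model.geometry)
    return {"sinos": ss, "mask": mask, "P_exact": P_exact, "suv": 50.0}


@pytest.fixture(scope="session")
def tiny_pelvic():
    """Small pelvic phantom + model + one noise-free acquisition."""
    grid = sr.ImageGrid((48, 48), (4.0, 4.0))
    geom = sr.ProjectionGeometry(n_views=24, n_tang=56, bin_size=4.0)
    psf = sr.PSFModel(4.2, 4.2)
    model = sr.SystemModel(geom, grid, rays_per_bin=2, psf=psf)
    phantom = sr.make_pelvic_phantom(
        grid,
        bladder_suv=40.0,
        bladder_volume_ml=150.0,
        lesion_distances_mm=(18.0, 26.0, 12.0),
        background_lesion_distance_mm=45.0,
    )
    noise = sr.NoiseModel(total_counts=3e5, n_realisations=2, seed=11)
    sinos = sr.simulate_acquisition(phantom, model, noise)
    return {"grid": grid, "model": model, "phantom": phantom, "sinos": sinos,
            "noise": noise}
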