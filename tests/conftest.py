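"""Shared fixtures: synthetic scenes measured once per session.

Scene sizes follow the study design (100 meshes for the population
recoveries; 24 large meshes suffice for the density recovery; 60 for the
feret mode); seeds are fixed so every run sees the same realizations.
"""

import numpy as np
import pytest

from tjmesh.io import LocalizationTable
from tjmesh.morphometry import measure_all
from tjmesh.simulate import (
    CLD5_DIAMETER_MIXTURE,
    GaussianMixture1D,
    MeshTruth,
    SceneParams,
    make_scene,
    sample_localizations,
)


def annulus_table(
    center=(1000.0, 1000.0),
    radius=200.0,
    width=10.0,
    n=2000,
    seed=42,
    sigma_loc=1e-3,
) -> LocalizationTable:
    """Noise-free mesh fixture: points exactly on a thin annulus."""
    rng = np.random.default_rng(seed)
    phi = rng.uniform(0, 2 * np.pi, n)
    rr = radius + rng.uniform(-width / 2, width / 2, n)
    x = center[0] + rr * np.cos(phi)
    y = center[1] + rr * np.sin(phi)
    return LocalizationTable.from_arrays(x, y, sigma_loc=np.full(n, sigma_loc))


@pytest.fixture(scope="session")
def cld3_run():
    """Claudin-3 population scene measured end-to-end."""
    scene = make_scene(SceneParams(n_meshes=100, seed=101))
    df = measure_all(scene.table, scene.seeds())
    return scene, df


@pytest.fixture(scope="session")
def cld5_run():
    """Claudin-5 population scene measured end-to-end."""
    scene = make_scene(
        SceneParams(n_meshes=100, diameter_mixture=CLD5_DIAMETER_MIXTURE, seed=102)
    )
    df = measure_all(scene.table, scene.seeds())
    return scene, df


@pytest.fixture(scope="session")
def feret_run():
    """Randomly oriented elliptical meshes for the Feret-mode recovery."""
    scene = make_scene(SceneParams(n_meshes=60, orientation_mode="random", seed=103))
    df = measure_all(scene.table, scene.seeds())
    return scene, df


@pytest.fixture(scope="session")
def density_run():
    """Large single-size meshes for the density recovery."""
    mixture = GaussianMixture1D(means=(550.0, 550.0), fwhms=(1e-6, 1e-6))
    scene = make_scene(
        SceneParams(
            n_meshes=24,
            diameter_mixture=mixture,
            axis_ratio_mode=0.85,
            axis_ratio_sd=0.03,
            axis_ratio_range=(0.8, 0.92),
            seed=104,
        )
    )
    df = measure_all(scene.table, scene.seeds())
    return scene, df


@pytest.fixture(scope="session")
def ladder_run():
    """A 20-mesh diameter ladder (circles, 150–700 nm) for monotonicity."""
    params = SceneParams(seed=105)
    rng = np.random.default_rng(params.seed)
    diams = np.linspace(150.0, 700.0, 20)
    meshes, cursor = [], 0.0
    for d in diams:
        r = d / 2.0
        cx = cursor + r
        cursor += 2 * r + params.mesh_spacing
        meshes.append(
            MeshTruth(center=(cx, 500.0), a=r, b=r, theta=0.0, diameter=d,
                      axis_ratio=1.0, orientation_ratio=1.0)
        )
    bounds = (0.0, cursor + 400.0, 0.0, 1000.0)
    strands = [[m.boundary(720)] for m in meshes]
    table, _ = sample_localizations(meshes, strands, bounds, params, rng)
    return meshes, table
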