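"""Shared fixtures: synthetic benchmarks and their assimilation results.

The expensive end-to-end assimilations are session-scoped so that unit tests
and acceptance tests share one computation per benchmark case.
"""

from __future__ import annotations

import numpy as np
import pytest

from stokesflow.assimilation import AssimilationConfig, multiscale_assimilate
from stokesflow.geometry import disk_mesh, mask_to_mesh, rectangle_mesh
from stokesflow.synthetic import SyntheticSpec, analytic_flow, make_benchmark


@pytest.fixture(scope="session")
def default_spec():
    return SyntheticSpec(seed=1)


@pytest.fixture(scope="session")
def default_cfg(default_spec):
    return AssimilationConfig(pixel_size=default_spec.pixel_size,
                              dt=default_spec.dt)


@pytest.fixture(scope="session")
def translation_benchmark(default_spec):
    return make_benchmark("translation", default_spec)


@pytest.fixture(scope="session")
def translation_result(translation_benchmark, default_cfg):
    seq, masks, flow = translation_benchmark
    sol = multiscale_assimilate(seq.frames[0], seq.frames[1], masks[0],
                                default_cfg)
    return sol, flow


@pytest.fixture(scope="session")
def poiseuille_benchmark(default_spec):
    return make_benchmark("poiseuille", default_spec)


@pytest.fixture(scope="session")
def poiseuille_result(poiseuille_benchmark, default_cfg):
    seq, masks, flow = poiseuille_benchmark
    sol = multiscale_assimilate(seq.frames[0], seq.frames[1], masks[0],
                                default_cfg)
    return sol, flow


@pytest.fixture(scope="session")
def source_benchmark(default_spec):
    return make_benchmark("source", default_spec)


@pytest.fixture(scope="session")
def source_result(source_benchmark, default_cfg):
    seq, masks, flow = source_benchmark
    sol = multiscale_assimilate(seq.frames[0], seq.frames[1], masks[0],
                                default_cfg)
    return sol, flow


@pytest.fixture(scope="session")
def small_disk_mesh():
    """~500-node disk mesh for adjoint and solver unit tests."""
    return disk_mesh(5.0, 0.55)


@pytest.fixture(scope="session")
def unit_square_meshes():
    return {n: rectangle_mesh(1.0, 1.0, n, n) for n in (8, 16, 32)}


@pytest.fixture(scope="session")
def speckle_pair_small():
    """Small noiseless speckle pair with its disk mask (fast unit tests)."""
    spec = SyntheticSpec(shape=(64, 64), seed=3, noise_sigma=0.0,
                         photons_at_peak=0.0)
    seq, masks, flow = make_benchmark(
        "translation", spec, U=(0.1, 0.05), center=(5.12, 5.12), radius=3.5)
    return spec, seq, masks, flow


def l2_relative_error(sol, flow):
    """Relative L2 velocity error of a solution against the analytic truth."""
    pts = sol.u.space.coords
    truth = np.atleast_2d(flow.u(pts)).T
    num = np.sqrt((np.linalg.norm(sol.u.dofs - truth, axis=0) ** 2).mean())
    den = max(np.linalg.norm(truth, axis=0).mean(), 1e-300)
    return num / den
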