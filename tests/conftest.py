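"""Shared fixtures: all synthetic data is generated at test time.

The unit-test fixtures use a smaller box / particle count than the default
study conditions so the suite stays fast; the acceptance tests build their
own data at the validated conditions.
"""

import numpy as np
import pytest

from bwdcf import (BilayerGeometry, SpectrumModel, WavevectorGrid,
                   compute_profiles, fit_gaussian, generate_frames)
from bwdcf.deconstruct import accumulate_B, build_A, solve_C_and_gamma


@pytest.fixture(scope="session")
def small_system():
    """Reduced system for unit tests: same physics, fewer particles/modes."""
    spec = SpectrumModel()          # default membrane-like spectrum
    geom = BilayerGeometry(L=15.0, n_per_leaflet=300)
    return spec, geom


@pytest.fixture(scope="session")
def small_frames(small_system):
    spec, geom = small_system
    return list(generate_frames(spec, geom, 300, qmax=3.0, seed=42))


@pytest.fixture(scope="session")
def small_fit(small_frames):
    return fit_gaussian(compute_profiles(small_frames, bin_width=0.05))


@pytest.fixture(scope="session")
def small_spectrum(small_system, small_frames, small_fit):
    """Deconstructed gamma^CU(q) of the small system (shared by fit tests)."""
    spec, geom = small_system
    grid = WavevectorGrid.build(geom.L, 1.6)
    A = build_A(small_fit, 14)
    B = accumulate_B(small_frames, small_fit, grid, 14)
    with np.errstate(all="ignore"):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return solve_C_and_gamma(A, B)
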