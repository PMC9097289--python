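"""Inverse deconstruction: overlap matrices, projections, gamma^CU recovery."""

import numpy as np
import pytest

import bwdcf.deconstruct as dec
from bwdcf.bwseries import assemble_G_BW, height_moments
from bwdcf.dcf import WavevectorGrid, accumulate_dcf, phase_matrix
from bwdcf.deconstruct import (BMatrix, accumulate_B, build_A,
                               project_B_from_dcf, solve_C_and_gamma)
from bwdcf.profiles import GaussianLeafletFit, gaussian_derivative, scaled_basis
from bwdcf.synthgen import (BilayerGeometry, Configuration, SpectrumModel,
                            generate_frames, place_particles,
                            sample_surface_pair)


@pytest.fixture(scope="module")
def fit():
    return GaussianLeafletFit(rho0=1.6, d=4.0, alpha=0.25)


def test_A_parity_zeros_and_quadrature_oracle(fit):
    """Odd n+m entries vanish; even entries match scipy adaptive quadrature
    of the raw derivative products (independent oracle)."""
    from scipy.integrate import quad
    A = build_A(fit, 6)
    D = A.scale
    orders = np.arange(1, 7)
    for i, n in enumerate(orders):
        for j, m in enumerate(orders):
            if (n + m) % 2:
                assert A.A[i, j] == 0.0
                continue
            val, _ = quad(lambda z: gaussian_derivative(fit, n, z)
                          * gaussian_derivative(fit, m, z), -2, 6, limit=200)
            assert A.A[i, j] == pytest.approx(val * D[i] * D[j], rel=1e-9)


def test_A_closed_forms(fit):
    """A_00 = rho0^2/(2 sqrt(pi alpha)); A_11 = rho0^2/(4 sqrt(pi) alpha^{3/2})."""
    from scipy.integrate import quad
    a, r = fit.alpha, fit.rho0
    val00, _ = quad(lambda z: fit.g(z) ** 2, -2, 6, limit=200)
    assert val00 == pytest.approx(r ** 2 / (2 * np.sqrt(np.pi * a)), rel=1e-10)
    A = build_A(fit, 2)
    raw11 = A.A[0, 0] / A.scale[0] ** 2
    assert raw11 == pytest.approx(r ** 2 / (4 * np.sqrt(np.pi) * a ** 1.5), rel=1e-10)


def test_A_inverse_blocks_and_bounds(fit):
    A = build_A(fit, 8)
    np.testing.assert_allclose(A.Ainv @ A.A, np.eye(8), atol=1e-9)
    with pytest.raises(ValueError):
        build_A(fit, 0)
    with pytest.raises(ValueError):
        build_A(fit, 25)


def test_extended_precision_fallback_matches_float64(fit, monkeypatch):
    A64 = build_A(fit, 10)
    monkeypatch.setattr(dec, "_COND_LIMIT", 1.0)  # force the mpmath path
    Amp = build_A(fit, 10)
    np.testing.assert_allclose(Amp.Ainv, A64.Ainv, rtol=1e-8)


def test_accumulate_B_matches_hand_loop(fit):
    """Four-particle single frame: the factorized sums equal the explicit
    double loop over lipid pairs."""
    L = 10.0
    cfg = Configuration(
        leaflet=np.array([1, 1, -1, -1]),
        xy=np.array([[0.0, 0.0], [2.0, 3.0], [1.0, 1.0], [4.0, 2.0]]),
        z=np.array([2.1, 1.8, -1.9, -2.2]), L=L)
    grid = WavevectorGrid.build(L, 1.0)
    n_bw = 4
    B = accumulate_B([cfg], fit, grid, n_bw)
    wp = scaled_basis(fit, n_bw, cfg.z[:2], 1)[1:]
    wm = scaled_basis(fit, n_bw, cfg.z[2:], -1)[1:]
    for k, mi in enumerate(B.half_index):
        qv = grid.qvecs[mi]
        hand = np.zeros((n_bw, n_bw), dtype=complex)
        for i in range(2):
            for j in range(2):
                ph = np.exp(-1j * (qv @ cfg.xy[i])) * np.exp(1j * (qv @ cfg.xy[2 + j]))
                hand += np.outer(wp[:, i], wm[:, j]) * ph
        np.testing.assert_allclose(B.B_mode[k], hand / (L * L), atol=1e-13)


def test_uncorrelated_leaflets_give_vanishing_B(fit):
    """Leaflet surfaces drawn independently -> B averages to zero."""
    spec = SpectrumModel()
    geom = BilayerGeometry(L=12.0, n_per_leaflet=100)
    rng = np.random.default_rng(8)
    grid = WavevectorGrid.build(geom.L, 1.2)
    frames = []
    for _ in range(200):
        pa = sample_surface_pair(spec, geom, grid, rng)
        pb = sample_surface_pair(spec, geom, grid, rng)
        mixed = type(pa)(grid=grid, amp_plus=pa.amp_plus, amp_minus=pb.amp_minus)
        frames.append(place_particles(mixed, geom, rng))
    gfit = GaussianLeafletFit(rho0=100 / geom.area, d=geom.d, alpha=0.35)
    B = accumulate_B(frames, gfit, grid, 3)
    # each element is a zero-mean average; the element spread across modes
    # estimates the residual-noise scale, and the mode average must shrink
    # by sqrt(n_modes) on top of it
    spread = B.B_mode.real.std()
    n_half = B.half_index.size
    mean_over_modes = np.abs(B.B_mode.real.mean(axis=0))
    assert mean_over_modes.max() < 4 * spread / np.sqrt(n_half)


def _analytic_B(spec, fit, grid, n_bw, z):
    """Assemble B by projecting exact G_BW matrices (binned route, no noise)."""
    half = np.flatnonzero(grid.half)
    mom = height_moments(spec.gamma_cu, grid, n_bw)
    phi_p = scaled_basis(fit, n_bw, z, 1)[1:]
    phi_m = scaled_basis(fit, n_bw, z, -1)[1:]
    dz = z[1] - z[0]
    Bm = np.zeros((half.size, n_bw, n_bw), dtype=complex)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k, mi in enumerate(half):
            G = assemble_G_BW(fit, mom, "interlayer_CU", z, qvec_index=mi)
            Bm[k] = dz * dz * np.einsum("na,ab,mb->nm", phi_p, G["pm"], phi_m)
    return BMatrix(grid=grid, n_BW=n_bw, B_mode=Bm, half_index=half, n_frames=1)


def test_round_trip_recovers_input_spectrum_exactly(fit):
    """Forward-model oracle: G_BW from a known gamma^CU, projected and
    inverted, returns the input spectrum (the method's central property)."""
    spec = SpectrumModel()
    grid = WavevectorGrid.build(16.0, 1.4)
    z = np.arange(-4.6, 4.6, 0.05) + 0.025
    B = _analytic_B(spec, fit, grid, 8, z)
    A = build_A(fit, 8, z_grid=z)
    cu = solve_C_and_gamma(A, B)
    np.testing.assert_allclose(cu.gamma_cu, spec.gamma_cu(cu.q), rtol=1e-8)
    # C is diagonal when the model holds; the tiny trailing diagonal entries
    # keep the normalized leakage metric from being exactly zero
    assert np.all(cu.offdiag_frac < 1e-4)


def test_single_term_wertheim_inversion_is_exact(fit):
    """n_BW = 1 on a Wertheim-only synthetic G: scalar inversion, exact."""
    grid = WavevectorGrid.build(16.0, 1.0)
    half = np.flatnonzero(grid.half)
    gamma = 3.0 + 20.0 * grid.shell_q ** 2
    z = np.arange(-4.6, 4.6, 0.04) + 0.02
    phi_p = scaled_basis(fit, 1, z, 1)[1:]
    phi_m = scaled_basis(fit, 1, z, -1)[1:]
    dz = z[1] - z[0]
    Bm = np.zeros((half.size, 1, 1), dtype=complex)
    for k, mi in enumerate(half):
        q = grid.qmod[mi]
        S1 = 1.0 / (q * q * 3.0 + q ** 4 * 20.0)
        G = (S1 / fit.alpha) * np.outer(phi_p[0], phi_m[0])
        Bm[k] = dz * dz * phi_p @ G @ phi_m.T
    B = BMatrix(grid=grid, n_BW=1, B_mode=Bm, half_index=half, n_frames=1)
    A = build_A(fit, 1, z_grid=z)
    cu = solve_C_and_gamma(A, B)
    np.testing.assert_allclose(cu.gamma_cu, 3.0 + 20.0 * cu.q ** 2, rtol=1e-10)


def test_basis_scaling_invariance(fit):
    """The recovered spectrum is identical under the diagonal rescaling:
    an unscaled (raw-derivative) reimplementation gives the same gamma."""
    spec = SpectrumModel()
    grid = WavevectorGrid.build(16.0, 1.2)
    z = np.arange(-4.6, 4.6, 0.05) + 0.025
    n_bw = 8
    B = _analytic_B(spec, fit, grid, n_bw, z)
    A = build_A(fit, n_bw, z_grid=z)
    cu = solve_C_and_gamma(A, B)
    # raw-basis route
    raw = np.stack([gaussian_derivative(fit, n, z, 1) for n in range(1, n_bw + 1)])
    raw_m = np.stack([gaussian_derivative(fit, n, z, -1) for n in range(1, n_bw + 1)])
    dz = z[1] - z[0]
    A_raw = dz * raw @ raw.T
    orders = np.arange(1, n_bw + 1)
    A_raw[(orders[:, None] + orders[None, :]) % 2 == 1] = 0.0
    D = A.scale
    gammas = []
    for k, mi in enumerate(B.half_index):
        B_raw = B.B_mode[k].real / np.outer(D, D)
        C_raw = np.linalg.solve(A_raw, np.linalg.solve(A_raw, B_raw).T).T
        q = grid.qmod[mi]
        gammas.append(1.0 / (q * q * C_raw[0, 0]))
    gammas = np.asarray(gammas)
    got = {round(q, 9): g for q, g in zip(cu.q, cu.gamma_cu)}
    per_mode = {}
    for k, mi in enumerate(B.half_index):
        per_mode.setdefault(round(grid.qmod[mi], 9), []).append(gammas[k])
    for q, vals in per_mode.items():
        np.testing.assert_allclose(np.mean(vals), got[q], rtol=1e-10)


def test_binned_and_factorized_routes_agree(fit):
    """Particle frames: projecting the binned G equals the direct factorized
    sums within z-binning error."""
    spec = SpectrumModel()
    geom = BilayerGeometry(L=12.0, n_per_leaflet=150)
    frames = list(generate_frames(spec, geom, 40, qmax=2.0, seed=21))
    gfit = GaussianLeafletFit(rho0=150 / geom.area, d=4.0, alpha=0.25)
    grid = WavevectorGrid.build(geom.L, 1.0)
    n_bw = 6
    direct = accumulate_B(frames, gfit, grid, n_bw)
    dcfm = accumulate_dcf(frames, grid, bin_width=0.05, z_window=(-4.8, 4.8))
    binned = project_B_from_dcf(dcfm, gfit, n_bw)
    # binning displaces each particle by O(dz) inside its bin; with N
    # particles the residual on B scales as dz/sqrt(N) -- ~1% here
    scale = np.abs(direct.B_mode).max()
    np.testing.assert_allclose(binned.B_mode, direct.B_mode, atol=1.5e-2 * scale)
    d11 = np.abs(binned.B_mode[:, 0, 0] - direct.B_mode[:, 0, 0])
    assert (d11 / np.abs(direct.B_mode[:, 0, 0])).max() < 0.015


def test_truncation_stability_on_analytic_projection(fit):
    """gamma^CU from n_BW = 12 and n_BW = 20 agree to <1% on noiseless data."""
    spec = SpectrumModel()
    grid = WavevectorGrid.build(20.0, 1.2)
    z = np.arange(-4.8, 4.8, 0.05) + 0.025
    out = {}
    for n_bw in (12, 20):
        B = _analytic_B(spec, fit, grid, n_bw, z)
        A = build_A(fit, n_bw, z_grid=z)
        out[n_bw] = solve_C_and_gamma(A, B)
    np.testing.assert_allclose(out[20].gamma_cu, out[12].gamma_cu, rtol=0.01)


def test_nonpositive_c11_shell_dropped_with_warning(fit):
    grid = WavevectorGrid.build(16.0, 0.5)
    half = np.flatnonzero(grid.half)
    Bm = -np.ones((half.size, 2, 2), dtype=complex) * 1e-3
    B = BMatrix(grid=grid, n_BW=2, B_mode=Bm, half_index=half, n_frames=1)
    A = build_A(fit, 2)
    with pytest.warns(UserWarning, match="dropped"):
        cu = solve_C_and_gamma(A, B)
    assert cu.q.size == 0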