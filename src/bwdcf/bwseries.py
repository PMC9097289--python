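"""Forward Bedeaux-Weeks (BW) theory for the density correlation function.

Given a fluctuation spectrum gamma(q) on the discrete box grid and a
Gaussian profile fit, this module predicts the capillary-wave part of the
DCF as the series

    G_BW(z1, z2, q) = sum_{n=1..n_BW} [S_n(q) / n!] rho^{(n)}(z1) rho^{(n)}(z2)

(total, single-surface form) and its interlayer coupled-undulatory variant

    G_BW^{+-}(z1, z2, q) = sum_n [S_n^{CU}(q) / n!] g_+^{(n)}(z1) g_-^{(n)}(z2),

where S_n(q) is (A_o times) the Fourier-series coefficient of the n-th power
of the height-height correlation h(x) = sum_q [1/(beta A_o q^2 gamma(q))]
e^{iq.x}, normalized so S_1(q) = 1/(beta q^2 gamma(q)) exactly.  The powers
of h are formed on a periodic real-space grid conjugate to the box
wavevectors (discrete, box-periodic convention: the strong system-size
dependence of the n >= 2 moments is part of the physics and is not replaced
by continuum integrals).

This forward model is the exact oracle against which the inverse
deconstruction is validated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.fft import next_fast_len

from .dcf import StructureFactor, WavevectorGrid
from .profiles import GaussianLeafletFit, scaled_basis

__all__ = [
    "HeightCorrelationMoments",
    "height_moments",
    "assemble_G_BW",
    "predict_S_BW",
    "predict_S_BW_closed_form",
]


@dataclass
class HeightCorrelationMoments:
    """Per-wavevector BW moments S_n(q), n = 1..n_BW.

    ``S_mode`` has shape (n_BW, M) over the grid's wavevectors; vectors in one
    modulus shell can carry slightly different n >= 2 moments when they are
    not related by a lattice symmetry (a finite-size feature).  ``S_shell``
    averages over shells.
    """

    grid: WavevectorGrid
    n_BW: int
    S_mode: np.ndarray
    beta: float = 1.0

    @property
    def S_shell(self) -> np.ndarray:
        return self.grid.shell_average(self.S_mode)


def _gamma_on_modes(gamma_of_q, grid: WavevectorGrid) -> np.ndarray:
    if callable(gamma_of_q):
        g = np.asarray(gamma_of_q(grid.qmod), dtype=float)
    else:
        g = np.asarray(gamma_of_q, dtype=float)
        if g.shape == grid.shell_q.shape:
            out = np.empty(len(grid))
            for k, idx in enumerate(grid.shells):
                out[idx] = g[k]
            g = out
        elif g.shape != grid.qmod.shape:
            raise ValueError("gamma values must match grid modes or shells")
    if not np.all(np.isfinite(g)) or np.any(g <= 0):
        raise ValueError("gamma(q) must be finite and positive on the grid")
    return g


def height_moments(gamma_of_q, grid: WavevectorGrid, n_BW: int,
                   beta: float = 1.0, fft_size: int | None = None) -> HeightCorrelationMoments:
    """Fourier moments of powers of the height-height correlation.

    ``gamma_of_q`` may be a callable, a per-mode array, or a per-shell array.
    The real-space grid is sized so that the spectral support of h^n (at most
    n times the largest active index per axis) cannot alias back onto the
    analysis window; an explicitly passed ``fft_size`` is validated against
    that bound.
    """
    if n_BW < 1:
        raise ValueError("n_BW must be >= 1")
    g = _gamma_on_modes(gamma_of_q, grid)
    s = 1.0 / (beta * grid.area * grid.qmod ** 2 * g)   # per-mode <|xi_q|^2>
    nidx = int(np.abs(grid.nvecs).max())
    needed = (n_BW + 1) * nidx + 1
    if fft_size is None:
        M = next_fast_len(needed)
    else:
        M = fft_size
        if M < needed:
            raise ValueError(
                f"fft_size={M} too coarse for n_BW={n_BW}: powers of h alias "
                f"onto the analysis window (need >= {needed})")
    F = np.zeros((M, M))
    F[grid.nvecs[:, 0] % M, grid.nvecs[:, 1] % M] = s
    h = np.fft.ifft2(F).real * (M * M)
    S = np.empty((n_BW, len(grid)))
    hp = np.ones_like(h)
    ix, iy = grid.nvecs[:, 0] % M, grid.nvecs[:, 1] % M
    for n in range(1, n_BW + 1):
        hp = hp * h
        coef = np.fft.fft2(hp).real / (M * M)
        S[n - 1] = grid.area * coef[ix, iy]
    S[0] = grid.area * s  # anchor the normalization exactly
    return HeightCorrelationMoments(grid=grid, n_BW=n_BW, S_mode=S, beta=beta)


def _series_weights(moments, alpha: float, shell: int | None, mode: int | None):
    """S_n / alpha^n, the series weights in the scaled phi_n basis."""
    if (shell is None) == (mode is None):
        raise ValueError("specify exactly one of shell= or mode=")
    S = moments.S_shell[:, shell] if mode is None else moments.S_mode[:, mode]
    n = np.arange(1, moments.n_BW + 1)
    return S / alpha ** n


def assemble_G_BW(fit: GaussianLeafletFit, moments: HeightCorrelationMoments,
                  mode: str, z_centers: np.ndarray, shell: int | None = None,
                  qvec_index: int | None = None, n_BW: int | None = None):
    """Predicted DCF matrices on a z grid for one wavevector shell (or mode).

    mode='total_U' returns the four leaflet quadrants of the single-surface
    series built on rho = rho^+ + rho^-; mode='interlayer_CU' returns the
    +-/-+ quadrants of the interlayer series.  Result: dict of (nb, nb)
    arrays keyed 'pp','mm','pm','mp' (absent quadrants are zero).

    In the scaled basis the series is sum_n (S_n / alpha^n) phi_n(z1) phi_n(z2),
    with phi_n bounded in n: the overflow guard for large n_BW.
    """
    if n_BW is None:
        n_BW = moments.n_BW
    if n_BW > moments.n_BW:
        raise ValueError("requested more terms than the moments carry")
    z = np.asarray(z_centers, dtype=float)
    w = _series_weights(moments, fit.alpha, shell, qvec_index)[:n_BW]
    phi_p = scaled_basis(fit, n_BW, z, sign=1)[1:]    # (n_BW, nb), orders 1..n_BW
    phi_m = scaled_basis(fit, n_BW, z, sign=-1)[1:]
    nb = z.size
    out = {k: np.zeros((nb, nb)) for k in ("pp", "mm", "pm", "mp")}
    if mode == "total_U":
        pairs = (("pp", phi_p, phi_p), ("mm", phi_m, phi_m),
                 ("pm", phi_p, phi_m), ("mp", phi_m, phi_p))
    elif mode == "interlayer_CU":
        pairs = (("pm", phi_p, phi_m), ("mp", phi_m, phi_p))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    for key, b1, b2 in pairs:
        out[key] = np.einsum("n,na,nb->ab", w, b1, b2)
    # convergence diagnostic on the last retained term
    tail = abs(w[-1]) * np.outer(np.abs(phi_p[-1]) + np.abs(phi_m[-1]),
                                 np.abs(phi_p[-1]) + np.abs(phi_m[-1]))
    total = sum(np.abs(v).sum() for v in out.values())
    if total > 0 and tail.sum() / total > 1e-3:
        warnings.warn(f"BW series not converged at n_BW={n_BW}: last term "
                      f"contributes {tail.sum() / total:.2e} of the matrix norm")
    return out


def predict_S_BW(fit: GaussianLeafletFit, moments: HeightCorrelationMoments,
                 mode: str, qz: np.ndarray, shell: int | None = None,
                 z_extent: float = 6.0, dz: float = 0.02) -> StructureFactor:
    """S_BW(q, q_z) by numerical Fourier transform of the assembled G_BW.

    Robust to any (future, non-Gaussian) profile basis; the Gaussian closed
    form in :func:`predict_S_BW_closed_form` serves as its oracle.  The self
    term contributes the constant 1 (in ``total``); intra/inter components
    follow the leaflet quadrants.
    """
    qz = np.asarray(qz, dtype=float)
    if qz.size == 0:
        raise ValueError("q_z grid is empty")
    half = fit.d / 2.0 + z_extent * np.sqrt(fit.alpha)
    nb = int(np.ceil(2 * half / dz))
    z = -half + dz * (np.arange(nb) + 0.5)
    if np.pi / dz < 2 * qz.max():
        raise ValueError("z grid too coarse for the requested q_z range")
    G = assemble_G_BW(fit, moments, mode, z, shell=shell)
    n_lipids = 2.0 * fit.rho0 * moments.grid.area
    pref = moments.grid.area / n_lipids * dz ** 2
    ph1 = np.exp(1j * np.outer(z, qz))
    ph2 = np.exp(-1j * np.outer(z, qz))
    intra = np.zeros(qz.size)
    inter = np.zeros(qz.size)
    for key in ("pp", "mm", "pm", "mp"):
        val = np.real(np.einsum("ab,ak,bk->k", G[key].astype(complex), ph1, ph2))
        if key in ("pp", "mm"):
            intra += pref * val
        else:
            inter += pref * val
    qsel = moments.grid.qvecs[moments.grid.shells[shell][0]][None, :]
    return StructureFactor(qvecs=qsel, qz=qz, intra=intra[None, :], inter=inter[None, :])


def predict_S_BW_closed_form(fit: GaussianLeafletFit,
                             moments: HeightCorrelationMoments, mode: str,
                             qz: np.ndarray, shell: int) -> StructureFactor:
    """Exact Gaussian-profile structure factor of the truncated BW series.

    Uses the analytic transform g_hat_{pm}(k) = rho_o e^{-alpha k^2/2 -+ i k d/2},
    giving per quadrant (a, b):

        S^{ab}(q, q_z) = (1/(2 rho_o)) rho_o^2 e^{-alpha q_z^2}
                          e^{i q_z (z_a - z_b)} sum_n (S_n/n!) q_z^{2n}.
    """
    qz = np.asarray(qz, dtype=float)
    S = moments.S_shell[:, shell]
    n = np.arange(1, moments.n_BW + 1)
    from scipy.special import gammaln
    # sum_n S_n/n! qz^{2n}, evaluated in log space for large qz^{2n}
    terms = S[:, None] * np.exp(2 * np.outer(n, np.log(np.maximum(np.abs(qz), 1e-300)))
                                - gammaln(n + 1)[:, None])
    series = terms.sum(axis=0)
    env = (fit.rho0 / 2.0) * np.exp(-fit.alpha * qz ** 2) * series
    osc = np.cos(qz * fit.d)
    if mode == "total_U":
        intra = 2 * env
        inter = 2 * env * osc
    elif mode == "interlayer_CU":
        intra = np.zeros_like(env)
        inter = 2 * env * osc
    else:
        raise ValueError(f"unknown mode {mode!r}")
    qsel = moments.grid.qvecs[moments.grid.shells[shell][0]][None, :]
    return StructureFactor(qvecs=qsel, qz=qz, intra=intra[None, :], inter=inter[None, :])
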