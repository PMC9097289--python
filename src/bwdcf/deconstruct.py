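"""Deconstruction of the interlayer DCF into the CU fluctuation spectrum.

The inverse of the forward BW series: assuming the interlayer DCF has the
form  G^{+-}(z1,z2,q) = sum_n [S_n^{CU}(q)/n!] g_+^{(n)}(z1) g_-^{(n)}(z2),
project it onto products of Gaussian-derivative basis functions,

    A_nm     = int g^{(n)}(z) g^{(m)}(z) dz                        (q-independent),
    B_nm(q)  = (1/A_o) < [sum_{i in +} g_+^{(n)}(z_i) e^{-i q.x_i}]
                         [sum_{j in -} g_-^{(m)}(z_j) e^{+i q.x_j}] >,

and solve the matrix equation C(q) = A^{-1} B(q) A^{-1}.  When the model
holds, C is diagonal with C_nn = S_n^{CU}(q)/n!, and the wavevector-dependent
surface tension of the coupled-undulatory mode follows from the first element:

    gamma^CU(q) = 1 / (beta q^2 C_11(q)).

Matrix indices run n = 1..n_BW; the n = 0 (mean-profile) direction belongs to
q = 0, which is excluded.  All internal algebra uses the rescaled basis
phi_n = alpha^{n/2} g^{(n)}/sqrt(n!) and parity-blocked solves (A_nm = 0 for
odd n + m by Gaussian parity), which keeps the problem well conditioned in
double precision up to n_BW ~ 20; an extended-precision fallback engages if a
parity block becomes numerically singular.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .dcf import DCFMatrix, WavevectorGrid, phase_matrix
from .profiles import GaussianLeafletFit, scaled_basis

__all__ = [
    "ProjectionMatrices",
    "CUSpectrum",
    "build_A",
    "accumulate_B",
    "project_B_from_dcf",
    "solve_C_and_gamma",
]

_COND_LIMIT = 1e12


@dataclass
class AMatrix:
    """Overlap matrix in the scaled basis, with its parity-blocked inverse.

    ``scale[n-1] = alpha^{n/2}/sqrt(n!)`` maps scaled to raw basis entries:
    A_raw = D^-1 A_scaled D^-1 with D = diag(scale).
    """

    A: np.ndarray          # (n_BW, n_BW), scaled basis, orders 1..n_BW
    Ainv: np.ndarray
    scale: np.ndarray
    alpha: float
    n_BW: int
    cond: float


def _parity_blocks(n_BW: int):
    idx = np.arange(n_BW)          # order n = idx + 1
    return idx[(idx + 1) % 2 == 1], idx[(idx + 1) % 2 == 0]  # odd orders, even orders


def _block_inverse(A: np.ndarray, n_BW: int):
    Ainv = np.zeros_like(A)
    conds = [1.0]
    for blk in _parity_blocks(n_BW):
        if blk.size == 0:
            continue
        sub = A[np.ix_(blk, blk)]
        conds.append(np.linalg.cond(sub))
        if conds[-1] > _COND_LIMIT:
            try:
                import mpmath
                mp_sub = mpmath.matrix(sub.tolist())
                inv = np.array(mpmath.inverse(mp_sub).tolist(), dtype=float)
            except ImportError:
                raise np.linalg.LinAlgError(
                    f"parity block condition number {conds[-1]:.2e} exceeds "
                    f"{_COND_LIMIT:.0e}; reduce n_BW or install mpmath") from None
        else:
            inv = np.linalg.inv(sub)
        Ainv[np.ix_(blk, blk)] = inv
    return Ainv, max(conds)


def build_A(fit: GaussianLeafletFit, n_BW: int,
            z_grid: np.ndarray | None = None) -> AMatrix:
    """Overlap matrix of the single-leaflet Gaussian derivative basis.

    With ``z_grid`` omitted the integrals are done by Gauss-Hermite quadrature,
    exact for the polynomial-times-Gaussian integrands (the right companion
    for the particle route, whose z integrals are exact point evaluations).
    With a ``z_grid`` the overlaps are midpoint sums on those bin centers --
    the algebraically consistent companion of the binned-G projection route.

    The mirror-leaflet overlap matrix equals this one entrywise: odd n + m
    entries vanish by parity and even ones are sign-free.
    """
    if not 1 <= n_BW <= 24:
        raise ValueError("n_BW must be in [1, 24]")
    if z_grid is None:
        t, w = np.polynomial.hermite.hermgauss(max(64, n_BW + 8))
        # psi_n(t) = phi_n(z(t)) e^{t^2/2}: polynomial recursion, no underflow
        psi = np.zeros((n_BW + 1, t.size))
        psi[0] = fit.rho0 / np.sqrt(2 * np.pi * fit.alpha)
        if n_BW >= 1:
            psi[1] = -t * psi[0]
        for n in range(1, n_BW):
            psi[n + 1] = (-t * psi[n] - np.sqrt(n) * psi[n - 1]) / np.sqrt(n + 1)
        A = np.sqrt(fit.alpha) * (psi[1:] * w) @ psi[1:].T
    else:
        z = np.asarray(z_grid, dtype=float)
        dz = z[1] - z[0]
        phi = scaled_basis(fit, n_BW, z, sign=1)[1:]
        A = dz * phi @ phi.T
    orders = np.arange(1, n_BW + 1)
    A[(orders[:, None] + orders[None, :]) % 2 == 1] = 0.0
    A = 0.5 * (A + A.T)
    Ainv, cond = _block_inverse(A, n_BW)
    n = orders.astype(float)
    from scipy.special import gammaln
    scale = np.exp(0.5 * (n * np.log(fit.alpha) - gammaln(n + 1)))
    return AMatrix(A=A, Ainv=Ainv, scale=scale, alpha=fit.alpha, n_BW=n_BW, cond=cond)


@dataclass
class BMatrix:
    """Frame-averaged projections B(q), per wavevector and shell-averaged.

    ``B_mode`` holds the complex per-wavevector matrices over the grid's half
    set (Hermitian symmetry fixes the rest); ``B_shell`` is the real part of
    the shell average, the quantity inverted for gamma^CU(q).  Scaled basis
    throughout (same diagonal as :class:`AMatrix`).
    """

    grid: WavevectorGrid
    n_BW: int
    B_mode: np.ndarray       # (n_half, n_BW, n_BW) complex
    half_index: np.ndarray   # indices into grid.qvecs
    n_frames: int

    @property
    def shell_map(self):
        """List of (shell_index, member positions in half set)."""
        out = []
        pos_of = {m: k for k, m in enumerate(self.half_index)}
        for si, members in enumerate(self.grid.shells):
            pos = [pos_of[m] for m in members if m in pos_of]
            if pos:
                out.append((si, np.asarray(pos)))
        return out

    @property
    def B_shell(self):
        idx = self.shell_map
        return (np.stack([self.B_mode[pos].real.mean(axis=0) for _, pos in idx]),
                np.asarray([self.grid.shell_q[si] for si, _ in idx]))


@dataclass
class ProjectionMatrices:
    """A, shell-averaged B(q), and C(q) = A^-1 B(q) A^-1 of the deconstruction."""

    A: AMatrix
    B: BMatrix
    C_shell: np.ndarray
    shell_q: np.ndarray


@dataclass
class CUSpectrum:
    """gamma^CU(q) per shell with degenerate-wavevector standard errors."""

    q: np.ndarray
    gamma_cu: np.ndarray
    stderr: np.ndarray
    n_modes: np.ndarray          # degenerate wavevectors per shell (half set)
    offdiag_frac: np.ndarray
    imag_frac: np.ndarray
    n_BW: int
    beta: float = 1.0

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "q": self.q, "gamma_cu": self.gamma_cu, "stderr": self.stderr,
            "nshell": self.n_modes, "offdiag_frac": self.offdiag_frac,
        })


def accumulate_B(frames, fit: GaussianLeafletFit, grid: WavevectorGrid,
                 n_BW: int) -> BMatrix:
    """Direct factorized-particle route for B(q) (no G binning).

    Per frame and leaflet, the weighted Fourier sums F^{pm}_n(q) =
    sum_i phi_n^{pm}(z_i) e^{-i q.x_i} are formed once; then
    B_nm(q) = (1/A_o) <F^+_n(q) conj(F^-_m(q))>.  Only one representative per
    (q, -q) pair is accumulated; B(-q) = conj(B(q)).
    """
    half = np.flatnonzero(grid.half)
    qv = grid.qvecs[half]
    acc = np.zeros((half.size, n_BW, n_BW), dtype=complex)
    n_frames = 0
    for cfg in frames:
        n_frames += 1
        F = {}
        for lbl, sign in (("p", 1), ("m", -1)):
            sel = cfg.leaflet == sign
            W = scaled_basis(fit, n_BW, cfg.z[sel], sign=sign)[1:]
            E = phase_matrix(cfg.xy[sel], qv)
            F[lbl] = W.astype(complex) @ E          # (n_BW, n_half)
        acc += np.einsum("nq,mq->qnm", F["p"], np.conj(F["m"]))
    if n_frames == 0:
        raise ValueError("no frames supplied")
    acc /= grid.area * n_frames
    return BMatrix(grid=grid, n_BW=n_BW, B_mode=acc, half_index=half,
                   n_frames=n_frames)


def project_B_from_dcf(dcfm: DCFMatrix, fit: GaussianLeafletFit,
                       n_BW: int) -> BMatrix:
    """Binned route for B(q): project the stored G^{+-}(z1, z2, q) matrices.

    Midpoint quadrature on the DCF's z bins; pair with
    ``build_A(fit, n_BW, z_grid=dcfm.z_centers)`` for algebraic consistency.
    """
    grid = dcfm.grid
    half = np.flatnonzero(grid.half)
    z = dcfm.z_centers
    dz = dcfm.dz
    phi_p = scaled_basis(fit, n_BW, z, sign=1)[1:]
    phi_m = scaled_basis(fit, n_BW, z, sign=-1)[1:]
    # G^{+-}(q) carries e^{-iq.(x_j - x_i)}; the factorized B(q) carries the
    # conjugate phase, so project the conjugate matrix.
    Gpm = np.conj(dcfm.G["pm"][half])
    B = dz * dz * np.einsum("na,qab,mb->qnm", phi_p.astype(complex), Gpm, phi_m.astype(complex))
    return BMatrix(grid=grid, n_BW=n_BW, B_mode=B, half_index=half,
                   n_frames=dcfm.n_frames)


def solve_C_and_gamma(A: AMatrix, B: BMatrix, beta: float = 1.0,
                      drop_nonpositive: bool = True) -> CUSpectrum:
    """Invert the projection, C(q) = A^-1 B(q) A^-1, and read off gamma^CU(q).

    Shell averaging happens on B before inversion; per-wavevector inversions
    are done solely for the shell standard errors.  C_11 <= 0 shells (signal
    below background) are dropped with a warning, never extrapolated.
    Reported diagnostics per shell: off-diagonal energy fraction of C and the
    imaginary residual of the per-mode C_11 values.
    """
    if A.n_BW != B.n_BW:
        raise ValueError("A and B were built with different n_BW")
    alpha = A.alpha
    smap = B.shell_map
    q_list, g_list, e_list, n_list, od_list, im_list = [], [], [], [], [], []
    for si, pos in smap:
        q = B.grid.shell_q[si]
        Bbar = B.B_mode[pos].real.mean(axis=0)
        C = A.Ainv @ Bbar @ A.Ainv
        S1 = alpha * C[0, 0]                      # scaled C_11 -> S_1
        diag = np.abs(np.diag(C))
        off = np.abs(C - np.diag(np.diag(C)))
        offdiag = off.sum() / max(np.abs(C).sum(), 1e-300)
        # per-mode values for error bars and the imaginary-part sanity metric
        c11 = np.array([alpha * (A.Ainv[0] @ B.B_mode[p] @ A.Ainv[:, 0]) for p in pos])
        imag_frac = (np.abs(c11.imag).mean() / max(np.abs(c11.real).mean(), 1e-300)
                     if pos.size else np.nan)
        if S1 <= 0:
            if drop_nonpositive:
                warnings.warn(f"C_11 <= 0 at shell q={q:.3f}; shell dropped "
                              "(BW signal below background)")
                continue
        gam = 1.0 / (beta * q * q * S1)
        if pos.size >= 2:
            g_modes = 1.0 / (beta * q * q * c11.real)
            err = np.nanstd(g_modes, ddof=1) / np.sqrt(pos.size)
        else:
            err = np.nan
        q_list.append(q); g_list.append(gam); e_list.append(err)
        n_list.append(pos.size); od_list.append(offdiag); im_list.append(imag_frac)
        if imag_frac > 0.10:
            warnings.warn(f"imaginary residual {imag_frac:.1%} of C_11 at "
                          f"q={q:.3f}: insufficient sampling")
    return CUSpectrum(q=np.asarray(q_list), gamma_cu=np.asarray(g_list),
                      stderr=np.asarray(e_list), n_modes=np.asarray(n_list),
                      offdiag_frac=np.asarray(od_list),
                      imag_frac=np.asarray(im_list), n_BW=A.n_BW, beta=beta)


def projection_matrices(A: AMatrix, B: BMatrix) -> ProjectionMatrices:
    """Bundle A, shell-averaged B and the full C matrices (diagnostics)."""
    Bs, qs = B.B_shell
    C = np.einsum("ij,qjk,kl->qil", A.Ainv, Bs, A.Ainv)
    return ProjectionMatrices(A=A, B=B, C_shell=C, shell_q=qs)
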