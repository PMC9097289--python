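"""Elastic moduli from the coupled-undulatory fluctuation spectrum.

The deconstructed gamma^CU(q) is fitted with the tilt-curvature form

    1/gamma^CU(q) = 1/(gamma_o + kappa q^2) + D(q)/kappa_theta,

where kappa is the bending modulus (k_BT), kappa_theta the tilt modulus
(k_BT/nm^2), and the one-parameter decoupling function D(q) -- 1 at low q,
-> 0 beyond the decoupling wavevector q_d -- collects the q^4 and higher
terms of the monolayer decoupling.  Two admissible forms are provided
(rational_q4, default, and exp_q4); both reduce to the same quadratic
expansion 1/gamma = 1/(gamma_o + kappa q^2) + q^0/kappa_theta - O(q^4) at
low q, so the fitted kappa is insensitive to the choice.

For tensionless membranes the low-q behavior is analyzed through
q^2/gamma^CU(q), whose q -> 0 intercept is 1/kappa; the weighted fit is
performed on that quantity.  The fit window is iterated to q <= 0.9 q_d
until q_d is stable, and the reported uncertainties combine the
least-squares covariance with a fit-range jackknife.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .synthgen import decoupling_function
from .units import kbt_per_nm2_to_mn_per_m, unit_convert  # noqa: F401  (re-export)

__all__ = [
    "ElasticFitResult",
    "PeristalticConstant",
    "fit_moduli",
    "quadratic_fit",
    "peristaltic_spring",
    "unit_convert",
]


@dataclass
class ElasticFitResult:
    """Fitted (gamma_o, kappa, kappa_theta, q_d) with uncertainties.

    ``stderr`` combines the weighted-least-squares covariance with the
    fit-range jackknife spread in quadrature, mirroring the two error
    sources of the analysis: (a) statistical sampling, (b) choice of fitted
    q window.  Reduced units; ``kappa_theta_mn_per_m`` converts at the given
    temperature.
    """

    kappa: float
    kappa_theta: float
    q_d: float
    gamma0: float
    stderr: dict
    covariance: np.ndarray
    fit_range: tuple
    n_shells: int
    chi2_dof: float
    d_form: str
    gamma0_mode: str
    extrapolated_qd: bool = False
    history: list = field(default_factory=list)

    def kappa_theta_mn_per_m(self, temperature: float = 320.0) -> float:
        return kbt_per_nm2_to_mn_per_m(self.kappa_theta, temperature)

    def summary(self) -> dict:
        return {
            "kappa_kbt": self.kappa,
            "kappa_theta_kbt_nm2": self.kappa_theta,
            "q_d_nm": self.q_d,
            "gamma0_kbt_nm2": self.gamma0,
            "stderr": self.stderr,
            "fit_range_nm": list(self.fit_range),
            "n_shells": self.n_shells,
            "chi2_dof": self.chi2_dof,
            "d_form": self.d_form,
        }


def _prepare(spectrum, default_rel_err=0.05):
    q = np.asarray(spectrum.q, dtype=float)
    g = np.asarray(spectrum.gamma_cu, dtype=float)
    e = np.asarray(spectrum.stderr, dtype=float).copy()
    good = np.isfinite(q) & np.isfinite(g) & (g > 0)
    q, g, e = q[good], g[good], e[good]
    # shells with a single member have no spread estimate: interpolate the
    # relative error from neighbours (or a flat default)
    bad = ~np.isfinite(e) | (e <= 0)
    if bad.all():
        e = default_rel_err * g
    elif bad.any():
        rel = e / g
        rel[bad] = np.interp(q[bad], q[~bad], rel[~bad])
        e = rel * g
    return q, g, e


def _model_y(q, gamma0, kappa, kappa_theta, q_d, form):
    inv = 1.0 / (gamma0 + kappa * q * q) + decoupling_function(q, q_d, form) / kappa_theta
    return q * q * inv


def fit_moduli(spectrum, gamma0_mode: str = "fixed_zero", d_form: str = "rational_q4",
               gamma0_value: float = 0.0, beta: float = 1.0,
               qd_tol: float = 0.01, max_iter: int = 25) -> ElasticFitResult:
    """Weighted nonlinear least-squares fit of q^2/gamma^CU(q).

    gamma0_mode: 'fixed_zero' (tensionless), 'fixed_value' (barostat record),
    or 'free'.  The fit window [q_min, 0.9 q_d] is iterated until q_d moves
    by less than ``qd_tol`` relatively; a q_d outside the data range is
    flagged extrapolated/unreliable.
    """
    q, g, e = _prepare(spectrum)
    if q.size < 6:
        raise ValueError("need at least 6 usable shells to fit the moduli")
    y = q * q / g
    ey = q * q * e / g ** 2
    fixed_g0 = {"fixed_zero": 0.0, "fixed_value": gamma0_value}.get(gamma0_mode)
    if fixed_g0 is None and gamma0_mode != "free":
        raise ValueError(f"unknown gamma0_mode {gamma0_mode!r}")

    # initial guesses from the data: kappa from the lowest shells, q_d from
    # the upper end of the window, kappa_theta from the mid-q excess
    kappa0 = max(q[0] ** 2 / y[0] - (fixed_g0 or 0.0) / max(q[0] ** 2, 1e-12), 1.0)
    qd0 = 0.7 * q.max()
    kth0 = 10.0 * (fixed_g0 or 0.0) + kappa0  # same order as kappa, in kT/nm^2

    def run_fit(window_mask):
        qq, yy, ee = q[window_mask], y[window_mask], ey[window_mask]
        if qq.size < (4 if gamma0_mode == "free" else 3):
            raise ValueError("fit window too narrow")
        if gamma0_mode == "free":
            def f(x, g0, k, kt, qd):
                return _model_y(x, g0, k, kt, qd, d_form)
            p0 = (max(g[0] - kappa0 * q[0] ** 2, 1e-3), kappa0, kth0, qd0)
            bounds = ([0, 1e-6, 1e-6, q[0] / 4], [np.inf] * 4)
        else:
            def f(x, k, kt, qd):
                return _model_y(x, fixed_g0, k, kt, qd, d_form)
            p0 = (kappa0, kth0, qd0)
            bounds = ([1e-6, 1e-6, q[0] / 4], [np.inf] * 3)
        popt, pcov = curve_fit(f, qq, yy, p0=p0, sigma=ee, absolute_sigma=True,
                               bounds=bounds, maxfev=20000)
        resid = (f(qq, *popt) - yy) / ee
        dof = max(qq.size - len(popt), 1)
        return popt, pcov, float(resid @ resid / dof), qq.size

    def unpack(popt):
        if gamma0_mode == "free":
            g0, k, kt, qd = popt
        else:
            g0 = fixed_g0
            k, kt, qd = popt
        return g0, k, kt, qd

    history = []
    mask = np.ones_like(q, dtype=bool)
    popt, pcov, chi2, nsh = run_fit(mask)
    qd_prev = unpack(popt)[3]
    history.append(dict(zip(("gamma0", "kappa", "kappa_theta", "q_d"), unpack(popt))))
    for _ in range(max_iter):
        qcut = 0.9 * qd_prev
        mask = q <= qcut
        if mask.sum() < 6:
            mask = np.zeros_like(q, dtype=bool)
            mask[:6] = True
            qcut = q[5]
        popt, pcov, chi2, nsh = run_fit(mask)
        g0, k, kt, qd = unpack(popt)
        history.append(dict(gamma0=g0, kappa=k, kappa_theta=kt, q_d=qd))
        if abs(qd - qd_prev) <= qd_tol * qd_prev:
            qd_prev = qd
            break
        qd_prev = qd
    else:
        warnings.warn("fit-window iteration did not stabilize q_d to tolerance")
    g0, k, kt, qd = unpack(popt)

    extrap = not (q.min() <= qd <= q.max())
    if extrap:
        warnings.warn(f"q_d={qd:.3f} nm^-1 outside the data range "
                      f"[{q.min():.3f}, {q.max():.3f}]: flagged unreliable")

    # fit-range jackknife: rescale the window and drop edge shells
    jk = []
    for factor in (0.8, 1.0):
        try:
            alt, *_ = run_fit(q <= factor * qd)
            jk.append(unpack(alt))
        except (ValueError, RuntimeError):
            pass
    try:
        m2 = mask.copy()
        m2[np.flatnonzero(mask)[-1]] = False
        alt, *_ = run_fit(m2)
        jk.append(unpack(alt))
    except (ValueError, RuntimeError):
        pass
    names = ("gamma0", "kappa", "kappa_theta", "q_d")
    central = dict(zip(names, (g0, k, kt, qd)))
    spread = {n: (np.std([v[i] for v in jk], ddof=0) if jk else 0.0)
              for i, n in enumerate(names)}
    perr = np.sqrt(np.clip(np.diag(pcov), 0, None))
    if gamma0_mode == "free":
        cov_err = dict(zip(names, perr))
    else:
        cov_err = {"gamma0": 0.0, **dict(zip(names[1:], perr))}
    stderr = {n: float(np.hypot(cov_err[n], spread[n])) for n in names}

    qfit = q[mask]
    return ElasticFitResult(
        kappa=central["kappa"], kappa_theta=central["kappa_theta"],
        q_d=central["q_d"], gamma0=central["gamma0"],
        stderr=stderr, covariance=pcov,
        fit_range=(float(qfit.min()), float(qfit.max())), n_shells=int(nsh),
        chi2_dof=chi2, d_form=d_form, gamma0_mode=gamma0_mode,
        extrapolated_qd=extrap, history=history)


def quadratic_fit(spectrum, q_cut: float):
    """Plain gamma_o + kappa q^2 least squares below q_cut (comparison only).

    On spectra shaped by monolayer decoupling this systematically
    underestimates the bending modulus of tensionless membranes -- the
    documented bias the tilt-curvature form corrects.  Returns
    (gamma0, kappa, stderr_gamma0, stderr_kappa).
    """
    q, g, e = _prepare(spectrum)
    m = q <= q_cut
    if m.sum() < 2:
        raise ValueError("fewer than 2 shells below q_cut")
    X = np.column_stack([np.ones(m.sum()), q[m] ** 2])
    W = np.diag(1.0 / e[m] ** 2)
    cov = np.linalg.inv(X.T @ W @ X)
    coef = cov @ X.T @ W @ g[m]
    err = np.sqrt(np.diag(cov))
    return float(coef[0]), float(coef[1]), float(err[0]), float(err[1])


@dataclass
class PeristalticConstant:
    """q -> 0 spring constant of the peristaltic thickness mode."""

    u_P: float        # k_BT/nm^4
    mean_thickness: float
    var_thickness: float
    n_frames: int


def peristaltic_spring(thickness, area: float, beta: float = 1.0) -> PeristalticConstant:
    """u_P = [beta A_o <(d - <d>)^2>]^-1 from a per-frame mean-thickness series.

    ``thickness`` may be a sequence of per-frame thicknesses or of
    Configurations (thickness = mean z of + leaflet minus mean z of -).
    """
    vals = []
    for item in thickness:
        if np.isscalar(item):
            vals.append(float(item))
        else:
            zp = item.z[item.leaflet == 1].mean()
            zm = item.z[item.leaflet == -1].mean()
            vals.append(float(zp - zm))
    vals = np.asarray(vals)
    if vals.size < 100:
        raise ValueError("need at least 100 frames for the thickness variance")
    var = vals.var(ddof=1)
    if var <= 0:
        raise ValueError("thickness series has zero variance; u_P undefined")
    return PeristalticConstant(u_P=1.0 / (beta * area * var),
                               mean_thickness=float(vals.mean()),
                               var_thickness=float(var), n_frames=vals.size)
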