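"""Synthetic bilayer configurations from two coupled capillary-wave surfaces.

The generator realizes the capillary-wave picture directly: each leaflet is a
Gaussian-fluctuating surface z = +-d/2 + xi^{pm}(x) whose Fourier amplitudes
have prescribed monolayer variance

    <|xi_q^{pm}|^2>       = 1 / (beta A_o q^2 gamma^m(q))

and interlayer cross-correlation

    <xi_q^+ xi_{-q}^->    = 1 / (beta A_o q^2 gamma^CU(q)),

plus independent Gaussian protrusion noise of width sigma_intr on every
particle.  Because gamma^m and gamma^CU are inputs, every downstream
estimator can be validated against exactly known ground truth.

Lateral positions are an ideal 2D gas (uniform i.i.d.): the in-plane
correlation background that the interlayer analysis is designed to filter
out is absent by construction.  Surfaces are evaluated at the off-grid
particle positions by direct Fourier summation (exact, no grid artifacts).
Reduced units: lengths nm, energies k_BT, beta = 1.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

from .dcf import WavevectorGrid

__all__ = [
    "SpectrumModel",
    "BilayerGeometry",
    "Configuration",
    "SurfacePair",
    "sample_surface_pair",
    "place_particles",
    "generate_frames",
    "write_frames",
    "read_frames",
    "ground_truth_table",
    "default_fixture",
]


def decoupling_function(q, q_d: float, form: str = "rational_q4"):
    """D(q): 1 at q -> 0, -> 0 beyond the monolayer-decoupling scale q_d.

    Two admissible one-parameter forms with identical q -> 0 (1 - O(q^4)) and
    large-q behavior are provided; ``rational_q4`` is the default.
    """
    x4 = (np.asarray(q, dtype=float) / q_d) ** 4
    if form == "rational_q4":
        return 1.0 / (1.0 + x4)
    if form == "exp_q4":
        return np.exp(-x4)
    raise ValueError(f"unknown D(q) form {form!r}")


@dataclass(frozen=True)
class SpectrumModel:
    """Parametric fluctuation spectra of a tensionless or tensioned bilayer.

    gamma_cu(q) follows the tilt-curvature form

        1/gamma^CU(q) = 1/(gamma0 + kappa q^2) + D(q)/kappa_theta,

    with D(q) selected by ``form`` and the decoupling wavevector q_d.  The
    monolayer spectrum adds an independent protrusion channel,

        1/gamma^m(q) = 1/gamma^CU(q) + 1/(gamma_p + kappa_p q^2),

    which guarantees gamma^m <= gamma^CU everywhere (positive-semidefinite
    two-surface covariance) and makes the leaflets decouple at high q.  The
    protrusion channel is this package's own construction for synthetic data;
    see docs/methods.md.

    Units: gamma0, kappa_theta, gamma_p in k_BT/nm^2; kappa, kappa_p in k_BT;
    q_d in 1/nm.
    """

    gamma0: float = 0.0
    kappa: float = 25.0
    kappa_theta: float = 30.0
    q_d: float = 1.1
    form: str = "rational_q4"
    gamma_p: float = 7.0
    kappa_p: float = 1.0

    def __post_init__(self):
        if self.gamma0 < 0 or self.kappa <= 0 or self.kappa_theta <= 0 or self.q_d <= 0:
            raise ValueError("require gamma0 >= 0, kappa > 0, kappa_theta > 0, q_d > 0")
        if self.gamma_p <= 0 or self.kappa_p < 0:
            raise ValueError("require gamma_p > 0 and kappa_p >= 0")

    def gamma_cu(self, q):
        q = np.asarray(q, dtype=float)
        inv = 1.0 / (self.gamma0 + self.kappa * q * q) \
            + decoupling_function(q, self.q_d, self.form) / self.kappa_theta
        return 1.0 / inv

    def gamma_m(self, q):
        q = np.asarray(q, dtype=float)
        return 1.0 / (1.0 / self.gamma_cu(q) + 1.0 / (self.gamma_p + self.kappa_p * q * q))

    def gamma_u(self, q):
        """Undulatory (mean-surface) spectrum: 1/g^U = (1/g^m + 1/g^CU)/2."""
        return 2.0 / (1.0 / self.gamma_m(q) + 1.0 / self.gamma_cu(q))


@dataclass(frozen=True)
class BilayerGeometry:
    """Box and sampling geometry of the synthetic bilayer (reduced units)."""

    L: float = 25.0
    d: float = 4.0
    n_per_leaflet: int = 1000
    sigma_intr: float = 0.3
    beta: float = 1.0

    def __post_init__(self):
        if self.L <= 0 or self.d <= 0:
            raise ValueError("L and d must be positive")
        if self.n_per_leaflet < 4:
            raise ValueError("need at least 4 particles per leaflet")
        if self.sigma_intr < 0:
            raise ValueError("sigma_intr must be nonnegative")

    @property
    def area(self) -> float:
        return self.L * self.L


@dataclass
class Configuration:
    """One frame of labeled head-group particles in an orthorhombic box.

    leaflet is +1 (upper) / -1 (lower); x, y are wrapped into [0, L); z is
    unbounded and centered so that the mean over all particles is zero.
    """

    leaflet: np.ndarray
    xy: np.ndarray
    z: np.ndarray
    L: float
    frame: int = 0

    def center(self) -> "Configuration":
        self.z = self.z - self.z.mean()
        return self


@dataclass
class SurfacePair:
    """Fourier amplitude maps of the two leaflet surfaces.

    Amplitudes are stored for one representative of each (q, -q) pair
    (``grid.half``); the other half is fixed by Hermitian symmetry
    xi_{-q} = conj(xi_q), so the real-space surfaces are real by
    construction.
    """

    grid: WavevectorGrid
    amp_plus: np.ndarray   # (n_half,) complex
    amp_minus: np.ndarray

    def evaluate(self, xy: np.ndarray, sign: int) -> np.ndarray:
        """xi^{sign}(x) at arbitrary lateral positions by direct Fourier sum."""
        amps = self.amp_plus if sign > 0 else self.amp_minus
        qh = self.grid.qvecs[self.grid.half]
        phases = np.exp(1j * (np.asarray(xy) @ qh.T))
        return 2.0 * np.real(phases @ amps)

    def mode_variance_target(self, spectrum: SpectrumModel, geom: BilayerGeometry):
        qh = self.grid.qmod[self.grid.half]
        return 1.0 / (geom.beta * geom.area * qh ** 2 * spectrum.gamma_m(qh))


def sample_surface_pair(spectrum: SpectrumModel, geom: BilayerGeometry,
                        qmax: float, seed=None) -> SurfacePair:
    """Draw one realization of the coupled surface pair (xi^+, xi^-).

    For each representative wavevector the pair of complex amplitudes is
    jointly Gaussian with per-surface variance s_m(q) and cross-covariance
    s_cu(q); decomposing into a common and two independent channels,

        xi^{pm}_q = sqrt(s_cu) C_q + sqrt(s_m - s_cu) I^{pm}_q,

    reproduces the prescribed covariance exactly.  Raises if the implied
    covariance is not positive semidefinite (gamma^CU < gamma^m somewhere).

    ``seed`` may be an int or a numpy Generator (to draw successive frames
    from one stream).
    """
    grid = qmax if isinstance(qmax, WavevectorGrid) else WavevectorGrid.build(geom.L, qmax)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    qh = grid.qmod[grid.half]
    s_m = 1.0 / (geom.beta * geom.area * qh ** 2 * spectrum.gamma_m(qh))
    s_cu = 1.0 / (geom.beta * geom.area * qh ** 2 * spectrum.gamma_cu(qh))
    resid = s_m - s_cu
    bad = resid < -1e-15 * s_m
    if bad.any():
        qs = np.unique(np.round(qh[bad], 6))
        raise ValueError(
            "two-surface covariance not positive semidefinite "
            f"(gamma_cu < gamma_m) at shells q={qs}")
    resid = np.clip(resid, 0.0, None)
    n = qh.size

    def cgauss(scale2):
        re, im = rng.standard_normal((2, n))
        return np.sqrt(scale2 / 2.0) * (re + 1j * im)

    common = cgauss(s_cu)
    amp_p = common + cgauss(resid)
    amp_m = common + cgauss(resid)
    return SurfacePair(grid=grid, amp_plus=amp_p, amp_minus=amp_m)


def place_particles(surfaces: SurfacePair, geom: BilayerGeometry, seed=None,
                    frame: int = 0) -> Configuration:
    """Realize a particle configuration on the sampled surfaces.

    Lateral positions are uniform i.i.d.; z_i = +-d/2 + xi^{pm}(x_i) + eta_i
    with eta ~ N(0, sigma_intr^2).  The frame is centered (mean z = 0).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = geom.n_per_leaflet
    leaflet = np.concatenate([np.ones(n, dtype=int), -np.ones(n, dtype=int)])
    xy = rng.uniform(0.0, geom.L, size=(2 * n, 2))
    z = np.empty(2 * n)
    for sign, sl in ((1, slice(0, n)), (-1, slice(n, 2 * n))):
        z[sl] = sign * geom.d / 2.0 + surfaces.evaluate(xy[sl], sign)
    if geom.sigma_intr > 0:
        z += rng.normal(0.0, geom.sigma_intr, size=2 * n)
    return Configuration(leaflet=leaflet, xy=xy, z=z, L=geom.L, frame=frame).center()


def generate_frames(spectrum: SpectrumModel, geom: BilayerGeometry,
                    n_frames: int, qmax: float = 3.0, seed: int = 0):
    """Yield ``n_frames`` independent configurations (fresh surfaces per frame).

    A single Generator seeded once drives surfaces, lateral positions and
    protrusions, so identical seed + parameters give bit-identical output.
    """
    grid = WavevectorGrid.build(geom.L, qmax)
    rng = np.random.default_rng(seed)
    for k in range(n_frames):
        surf = sample_surface_pair(spectrum, geom, grid, rng)
        yield place_particles(surf, geom, rng, frame=k)


_COLUMNS = "frame leaflet x y z"


def write_frames(configs, path, fmt: str = "tsv") -> None:
    """Write frames to a columnar TSV (frame, leaflet, x, y, z) or HDF5 file."""
    configs = list(configs)
    if not configs:
        raise ValueError("no frames to write")
    if fmt == "tsv":
        with open(path, "w") as fh:
            fh.write(f"# L={configs[0].L!r}\n")
            fh.write("# " + _COLUMNS.replace(" ", "\t") + "\n")
            for cfg in configs:
                block = np.column_stack([
                    np.full(cfg.z.size, cfg.frame, dtype=float), cfg.leaflet,
                    cfg.xy[:, 0], cfg.xy[:, 1], cfg.z])
                np.savetxt(fh, block, fmt="%d\t%d\t%.9f\t%.9f\t%.9f")
    elif fmt == "h5":
        import h5py
        with h5py.File(path, "w") as h5:
            h5.attrs["L"] = configs[0].L
            for cfg in configs:
                g = h5.create_group(f"frame{cfg.frame:06d}")
                g.create_dataset("leaflet", data=cfg.leaflet)
                g.create_dataset("xy", data=cfg.xy)
                g.create_dataset("z", data=cfg.z)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_frames(path, fmt: str = "tsv"):
    """Read frames written by :func:`write_frames`; returns a list."""
    if fmt == "tsv":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("# L="):
                raise ValueError("not a synthetic frame file (missing box header)")
            L = float(header.split("=", 1)[1])
            data = np.loadtxt(io.StringIO(fh.read()))
        data = np.atleast_2d(data)
        out = []
        for fidx in np.unique(data[:, 0]).astype(int):
            rows = data[data[:, 0] == fidx]
            out.append(Configuration(
                leaflet=rows[:, 1].astype(int), xy=rows[:, 2:4].copy(),
                z=rows[:, 4].copy(), L=L, frame=int(fidx)))
        return out
    if fmt == "h5":
        import h5py
        out = []
        with h5py.File(path, "r") as h5:
            L = float(h5.attrs["L"])
            for name in sorted(h5.keys()):
                g = h5[name]
                out.append(Configuration(
                    leaflet=g["leaflet"][...], xy=g["xy"][...], z=g["z"][...],
                    L=L, frame=int(name.replace("frame", ""))))
        return out
    raise ValueError(f"unknown format {fmt!r}")


def ground_truth_table(spectrum: SpectrumModel, grid: WavevectorGrid):
    """DataFrame of the exact input spectra per shell (q, gamma_m, gamma_cu, gamma_u)."""
    import pandas as pd
    q = grid.shell_q
    return pd.DataFrame({
        "q": q,
        "gamma_m": spectrum.gamma_m(q),
        "gamma_cu": spectrum.gamma_cu(q),
        "gamma_u": spectrum.gamma_u(q),
    })


def default_fixture():
    """The default membrane-like study conditions used throughout validation.

    L = 25 nm, d = 4 nm, 1000 particles per leaflet, sigma_intr = 0.3 nm,
    beta*kappa = 25, beta*kappa_theta = 30 nm^-2, q_d = 1.1 nm^-1, tensionless.
    """
    return SpectrumModel(), BilayerGeometry()
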