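# Methods

`bwdcf` measures the elastic constants of a lipid bilayer from nothing but
the per-frame coordinates of one reference atom per lipid head group.  No
mesoscopic surface, no regular-grid Fourier transform and no tail-orientation
field is ever constructed.  This note records the model, the estimators, the
numerical choices, and what the validation on synthetic data does and does
not demonstrate.

## Model

### Capillary-wave description and the coupled-undulatory mode

Each leaflet surface is described by height fluctuations
`z = ±d/2 + ξ^±(x)` over the bilayer midplane, with Fourier amplitudes
`ξ̂_q` on the discrete wavevectors `q = (2π/L)(n_x, n_y)` of the periodic
box.  A wavevector-dependent surface tension γ(q) summarizes the free-energy
cost per mode,

    ⟨|ξ̂_q|²⟩ = 1 / (β A_o q² γ(q)),     A_o = L².

Different surface definitions give different γ(q).  The monolayer spectrum
γ^m(q) is softened at high q by molecular protrusions; the undulatory (mean
surface) spectrum γ^U(q) mixes in peristaltic thickness fluctuations.  The
*coupled-undulatory* (CU) spectrum is instead defined from the interlayer
cross-correlation,

    ⟨ξ̂_q^+ ξ̂_{-q}^-⟩ = 1 / (β A_o q² γ^CU(q)),

which keeps only the fluctuations common to both leaflets — precisely the
single-sheet bending physics — and filters protrusions and in-plane
structure automatically, because uncorrelated single-leaflet noise does not
survive the cross-correlation.

### The Bedeaux–Weeks series for the interlayer DCF

For jointly Gaussian surfaces shifting a Gaussian intrinsic profile, the
interlayer density correlation function has an exact series representation
(a Mehler-kernel expansion of the bivariate Gaussian):

    G^{+-}(z₁, z₂, q) = Σ_{n≥1} [S_n(q)/n!] g₊⁽ⁿ⁾(z₁) g₋⁽ⁿ⁾(z₂),

where g_±(z) are the per-leaflet Gaussian profile fits (areal density ρ_o,
separation d, mean-square width α), and S_n(q) is A_o times the Fourier
coefficient of the n-th power of the interlayer height–height correlation
h(x) = Σ_q ⟨ξ̂_q^+ ξ̂_{-q}^-⟩ e^{iqx}, normalized so that

    S_1(q) = 1/(β q² γ^CU(q)).

Truncating at n = 1 gives the classical Wertheim form
ρ′(z₁)ρ′(z₂)/(βq²γ), divergent as q⁻²; membrane-scale parameters need the
series up to n_BW ≈ 12–20 for convergence.  All moments are computed in the
discrete, box-periodic convention: the strong system-size dependence of the
n ≥ 2 moments is physical and must not be replaced by continuum integrals.

### The deconstruction (inverse problem)

Projecting the measured interlayer DCF onto products of profile derivatives
defines two matrices (indices n, m = 1..n_BW),

    A_nm    = ∫ g⁽ⁿ⁾(z) g⁽ᵐ⁾(z) dz                    (q-independent),
    B_nm(q) = (1/A_o) ⟨ [Σ_{i∈+} g₊⁽ⁿ⁾(z_i) e^{-iq·x_i}]
                        [Σ_{j∈-} g₋⁽ᵐ⁾(z_j) e^{+iq·x_j}] ⟩.

If the series form holds, B(q) = A S̃(q) A with S̃ = diag(S_n/n!), so

    C(q) = A⁻¹ B̄(q) A⁻¹  is diagonal, and  γ^CU(q) = 1/(β q² C₁₁(q)),

where B̄ is the mean over the degenerate wavevectors of a modulus shell.
Off-diagonal leakage of C and the imaginary residual of C₁₁ are reported as
diagnostics; shells with C₁₁ ≤ 0 (signal below background) are dropped,
never extrapolated.  The factorized second form of B needs no (z₁, z₂)
binning; the binned route (projecting a stored G^{+-} matrix) is kept as a
cross-check estimator.

### Elastic moduli

The CU spectrum is fitted with the tilt-curvature form

    1/γ^CU(q) = 1/(γ_o + κ q²) + D(q)/κ_θ,

with bending modulus κ (k_BT), tilt modulus κ_θ (k_BT/nm², convertible to
mN/m), and a one-parameter decoupling function D(q) → 1 at low q and → 0
beyond the decoupling wavevector q_d, which bundles the q⁴ and higher terms
of the monolayer decoupling.  The printed form of D is not uniquely pinned
down by theory at this order; two admissible choices with identical q → 0
and q → ∞ behavior are implemented — `rational_q4`, D = 1/(1+(q/q_d)⁴)
(default) and `exp_q4`, D = exp(−(q/q_d)⁴).  The fitted κ is a q → 0
property and is insensitive to the choice (asserted in tests); both results
can be reported.  For tensionless membranes the fit is performed on
q²/γ^CU(q), whose intercept is 1/κ; a plain γ_o + κq² quadratic fit is
provided for comparison and is documented as biased low for tensionless
membranes.  The fit window is iterated to q ≤ 0.9 q_d until q_d is stable to
1%; uncertainties combine the weighted-least-squares covariance with a
fit-range jackknife (window rescaling and edge-shell removal), reflecting
the two error sources: finite sampling (estimated from the spread over
degenerate wavevectors within a shell) and window choice.

The q → 0 peristaltic spring constant u_P = [β A_o ⟨(d − ⟨d⟩)²⟩]⁻¹ is
estimated from the per-frame mean-thickness series.  The identity relating
γ^U, γ^CU and u_P at quadratic order is not implemented as a constraint;
only the estimator is exposed.

## Synthetic-data generator

The generator draws, per frame, a fresh pair of coupled Gaussian surfaces
with exactly prescribed spectra and places particles on them:

* amplitudes: ξ̂^± = √s_cu C_q + √(s_m − s_cu) I^±_q with independent
  complex Gaussians C, I^± — reproducing ⟨|ξ̂^±|²⟩ = s_m(q) and
  ⟨ξ̂^+ξ̂^-*⟩ = s_cu(q) exactly; rejected with a per-shell diagnostic if
  γ^CU < γ^m anywhere (covariance not PSD);
* lateral positions uniform i.i.d. (ideal 2D gas): the in-plane correlation
  background is absent by construction;
* z = ±d/2 + ξ^±(x_i) + η_i with protrusion noise η ~ N(0, σ_intr²);
  surfaces are evaluated at the off-grid particle positions by direct
  Fourier summation (exact — no interpolation-grid artifacts);
* frames centered on the mean z (as for the center-of-mass convention used
  on real trajectories).

γ^CU(q) uses the tilt-curvature form above.  No parametric monolayer
spectrum is established in the literature for this construction, so the
generator defines one: 1/γ^m = 1/γ^CU + 1/(γ_p + κ_p q²), an independent
protrusion channel with protrusion tension γ_p and stiffness κ_p.  This
guarantees γ^m ≤ γ^CU (positive-semidefinite covariance) and
protrusion-dominated decoupling at high q.  It is a modeling choice of this
package, not a literature value.

Defaults (the reference study conditions used throughout the tests):
L = 25 nm, d = 4 nm, 1000 particles per leaflet, σ_intr = 0.3 nm, β = 1,
βκ = 25, βκ_θ = 30 nm⁻², q_d = 1.1 nm⁻¹, γ_o = 0 (tensionless),
γ_p = 7 k_BT/nm² (≈31 mN/m at 320 K), κ_p = 1 k_BT, generator mode cutoff
q_max = 3.0 nm⁻¹ (well beyond the ≤1.5 nm⁻¹ analysis window; spectral
weight beyond the cutoff is protrusion-dominated and is represented by
σ_intr).  These give a leaflet width α ≈ 0.25 nm², i.e. clearly separated
leaflet peaks.

What the generator emulates: Gaussian coupled capillary waves, protrusion
broadening, finite-size discreteness of the mode spectrum, shell degeneracy
statistics.  What it does not emulate: in-plane liquid structure (the 2D
compressibility background), non-Gaussian fluctuations, peristaltic
soft-mode dynamics beyond independent ± construction, frame-to-frame
correlation of an MD trajectory (synthetic frames are independent, so a
synthetic "frame" is worth roughly one statistically independent MD
snapshot).  Consequently, passing the recovery tests demonstrates estimator
correctness and statistical calibration under the model's own assumptions —
not that any real membrane follows those assumptions, nor how large the
correlation background of a particular force field is.

## Numerical choices

* **Scaled basis.** All projections use φ_n = α^{n/2} g⁽ⁿ⁾/√(n!), which
  obeys the Hermite-function recursion φ_{n+1} = (−uφ_n − √n φ_{n−1})/√(n+1)
  and stays O(1) across orders; A and B are formed directly in this basis
  (results are invariant under the rescaling, asserted to 1e-10).
* **A matrix.** Gauss–Hermite quadrature (64 nodes), exact for the
  polynomial×Gaussian integrands up to n_BW = 24; odd n+m entries are zeroed
  by parity and the inverse is taken per parity block (condition number
  ~6e8 per block at n_BW = 20 in the scaled basis; an mpmath
  extended-precision inverse engages above 1e12).  When the binned-G route
  is used, A is instead formed by the same midpoint rule on the same z grid,
  which makes the projection algebraically consistent with the quadrature
  of B (the noiseless round trip is then exact to ~1e-10 at n_BW = 12 and
  ~2e-7 at n_BW = 20).
* **Matrix indices start at n = 1**: the n = 0 direction belongs to the
  q = 0 mean profile, which is excluded (the method requires q > 0);
  including it would only add a null/noise direction.
* **Shells.** Wavevectors are grouped by the integer norm n_x²+n_y² (exact
  ties, no floating-point tolerance); B̄ is shell-averaged before inversion;
  per-wavevector inversions are done only for the shell standard errors.
  Hermitian symmetry halves the mode set.
* **Moments by FFT.** h(x) is synthesized on a periodic grid of linear size
  ≥ (n_BW+1)·n_max+1 (next fast FFT length), so powers h^n cannot alias
  back onto the analysis window; an explicit fft_size below the bound is
  rejected.  S_1 is pinned to 1/(βq²γ) exactly.
* **Structure factors.** S_BW(q, q_z) is produced by numerical Fourier
  transform of the assembled G_BW (robust to future non-Gaussian profile
  bases); the closed Gaussian form Σ_n (S_n/n!) q_z^{2n} ρ_o² e^{−αq_z²}
  e^{iq_z d} serves as its oracle in tests.
* **Profiles.** Default bin width 0.05 nm; α is insensitive to the bin
  width within 1% over [0.02, 0.1] nm (asserted).  Moments and
  least-squares Gaussian fits are both provided (they agree within 2% on
  synthetic data); moments is the default.  The two leaflets are
  symmetrized into a single (ρ_o, d, α) triple; asymmetric fits are not
  supported by the deconstruction contract.
* **Degenerate inputs.** Empty leaflets, zero-variance profiles,
  non-positive γ, non-PSD covariances, C₁₁ ≤ 0 shells, fewer than 6 usable
  shells, and non-orthorhombic boxes all raise explicit errors or drop data
  with warnings; nothing is silently extrapolated.
* **Box fluctuations.** For constant-tension trajectories the wavevector
  grid uses the trajectory-mean box length (a common q grid is required to
  accumulate B̄); the per-frame spread is logged in the provenance record.

## Validation problem sizes

The full reference conditions (5000 frames, many seeds) are more sampling
than needed to exercise every property, so the test suite scales the
*sampling* down while keeping every physical parameter of the study
conditions unchanged:

* end-to-end recovery: 8 seeds × 1250 frames × 2000 particles — per-seed βκ
  recovered within 10%, seed-mean within 5%, seed-mean βκ_θ within 25%
  (βκ_θ carries intrinsically larger uncertainty, as expected for a
  parameter encoded at the upper end of the fitted window);
* estimator cross-validation: 50 frames at the full particle count;
* the exact (noiseless) forward–inverse round trip, truncation-convergence
  and structure-factor identities need no sampling at all.

The acceptance script pools 4 seeds × 1500 frames into a single
deconstruction (statistically equivalent to one long run) before fitting.
The truncation-convergence check compares n_BW = 12 vs 20 on the exact
forward model of the fixture: on sampled data the two inversions respond
differently to the *same* sampling noise, which would measure noise
response (already covered by the end-to-end test), not series truncation.

## Known limitations

* The method reads γ^CU only up to q ≈ 1–1.3 nm⁻¹ at these conditions;
  beyond, G_BW decays below the statistical background and shells are
  dropped or carry large errors.  This mirrors the intrinsic window of the
  interlayer signal and bounds the smallest usable box (≥6 shells below
  0.9·q_d are required to fit).
* κ_θ and q_d are strongly correlated in the fit when q_d lies near the
  upper end of the data window; their per-run scatter is several times that
  of κ.  The reported jackknife + covariance error reflects this.
* Leaflet assignment assumes no flip-flop on the analysis timescale; an
  override file is accepted for systems where that fails.
* Only orthorhombic boxes are supported.
* The undulatory (total) mode is *not* deconstructed: its DCF carries a
  large non-capillary background; the forward U-mode prediction is provided
  for difference maps only.
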