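# bwdcf

**Bending and tilt moduli of lipid bilayers from density correlation
functions.**

Measuring the bending modulus κ of a membrane from molecular simulation
usually means building a smooth mesoscopic surface (and often a
tail-orientation field) from the lipid coordinates, Fourier-transforming it
on a regular grid, and fitting the fluctuation spectrum — with the result
depending on every one of those construction choices.  `bwdcf` implements an
alternative that needs none of them: the elastic constants are extracted
directly from the number-density correlations of a single head-group
reference atom (e.g. the phosphorus of a PC lipid), using the Bedeaux–Weeks
(BW) representation of the density correlation function (DCF) of a
fluctuating interface and the *coupled-undulatory* (CU) mode defined by the
correlation between the two leaflets.

It is intended for simulators of lipid membranes (coarse-grained or
all-atom) who want κ, the tilt modulus κ_θ, and the leaflet-decoupling
wavevector q_d from an existing trajectory, without intrinsic-surface
machinery.

## Method in brief

For a fluctuating surface, capillary-wave theory assigns each wavevector a
mean-square amplitude ⟨|ξ̂_q|²⟩ = 1/(βA₀q²γ(q)).  Defining γ from the
*interlayer* cross-correlation ⟨ξ̂_q⁺ξ̂₋_q⁻⟩ yields γ^CU(q), the spectrum of
the fluctuations the two leaflets share — bending physics with protrusions
and in-plane structure filtered out by construction.  The BW theory writes
the interlayer DCF as a series over derivatives of the Gaussian leaflet
profiles g_±(z):

    G⁺⁻(z₁,z₂,q) = Σₙ [Sₙ(q)/n!] g₊⁽ⁿ⁾(z₁) g₋⁽ⁿ⁾(z₂),   S₁(q) = 1/(βq²γ^CU(q)).

`bwdcf` *deconstructs* this series: it projects particle sums onto the
derivative basis, forming matrices A (basis overlaps) and B̄(q) (weighted
interlayer Fourier sums, shell-averaged), and solves C(q) = A⁻¹B̄(q)A⁻¹,
whose (1,1) element gives γ^CU(q) per shell.  The spectrum is then fitted
with the tilt-curvature form

    1/γ^CU(q) = 1/(γ₀ + κq²) + D(q)/κ_θ,       D(q) = 1/(1 + (q/q_d)⁴),

giving κ, κ_θ and q_d with uncertainties (shell statistics + fit-range
jackknife).  A synthetic-bilayer generator with exactly known γ^m, γ^CU
provides ground truth for every stage; see `docs/methods.md` for the full
account.

## Worked example

Generate a synthetic tensionless bilayer at the default study conditions
(25 nm box, 2000 head groups, βκ = 25, βκ_θ = 30 nm⁻², q_d = 1.1 nm⁻¹) and
recover the moduli:

```python
import warnings; warnings.simplefilter("ignore")
from bwdcf import (WavevectorGrid, default_fixture, generate_frames,
                   compute_profiles, fit_gaussian, build_A, accumulate_B,
                   solve_C_and_gamma, fit_moduli, unit_convert)

spectrum, geometry = default_fixture()
frames = list(generate_frames(spectrum, geometry, n_frames=1000, seed=0))

profile = compute_profiles(frames, bin_width=0.05)
fit = fit_gaussian(profile)
print(f"Gaussian fit: rho0={fit.rho0:.3f} nm^-2, d={fit.d:.3f} nm, alpha={fit.alpha:.3f} nm^2")

grid = WavevectorGrid.build(geometry.L, qmax=1.5)
A = build_A(fit, n_BW=20)
B = accumulate_B(frames, fit, grid, n_BW=20)
cu = solve_C_and_gamma(A, B)
for q, g, e in list(zip(cu.q, cu.gamma_cu, cu.stderr))[:4]:
    print(f"q={q:.3f} /nm   gamma_CU={g:6.3f} +- {e:.3f} kT/nm^2")

res = fit_moduli(cu)
print(f"beta*kappa       = {res.kappa:.1f} +- {res.stderr['kappa']:.1f}")
print(f"beta*kappa_theta = {res.kappa_theta:.1f} +- {res.stderr['kappa_theta']:.1f} /nm^2"
      f"  ({unit_convert(res.kappa_theta, 'kBT/nm2', 'mN/m', 320.0):.0f} mN/m at 320 K)")
print(f"q_d              = {res.q_d:.2f} /nm")
```

Output (about a minute on one core):

```
Gaussian fit: rho0=1.600 nm^-2, d=4.001 nm, alpha=0.253 nm^2
q=0.251 /nm   gamma_CU= 1.492 +- 0.023 kT/nm^2
q=0.355 /nm   gamma_CU= 2.926 +- 0.065 kT/nm^2
q=0.503 /nm   gamma_CU= 5.336 +- 0.148 kT/nm^2
q=0.562 /nm   gamma_CU= 6.388 +- 0.066 kT/nm^2
beta*kappa       = 24.9 +- 0.5
beta*kappa_theta = 33.0 +- 5.2 /nm^2  (146 mN/m at 320 K)
q_d              = 1.21 /nm
```

Reading the numbers: the fitted leaflet profiles (areal density 1.6 nm⁻²,
head-to-head distance 4 nm, width α ≈ 0.25 nm²) define the projection
basis; γ^CU(q) rises from ≈ κq² at the lowest shells (bending-dominated)
and the tilt-curvature fit returns the bending modulus within ~1% of the
generator's βκ = 25 at 1000 frames, with the tilt modulus — intrinsically
the noisier parameter — within its quoted error of βκ_θ = 30 nm⁻².

The same analysis runs on an MD trajectory from the shell:

```sh
bwdcf spectrum --top system.gro --traj traj.xtc --select "name P*" \
      --nbw 20 --qmax 1.5 --out spectrum.tsv
bwdcf fit --spectrum spectrum.tsv --gamma0 0 --out moduli.json
```

Other subcommands: `synth` (synthetic frames + exact spectra), `profile`,
`forward` (BW structure-factor prediction), `pipeline` (YAML-driven
end-to-end run).

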