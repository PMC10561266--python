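# Methods

## The question the package answers

In solution, the Coulomb interaction between two ions is attenuated by the
electronic polarization of the medium even when the solvent has no permanent
dipoles. The electronic continuum correction (ECC) captures this in
nonpolarizable force fields by scaling ionic charges with

    s = 1 / sqrt(ε_el),

where ε_el is the high-frequency (electronic) dielectric constant of the
environment. `ionscreen` measures this screening directly: it simulates a
like-charged ion pair held at fixed separation r in an argon-like solvent
whose *only* dielectric response is electronic, extracts the Coulombic part of
the pairing free energy, and fits the scaled Coulomb law

    U_C(r) = s² · k_C · q₁q₂ / r + b       (k_C = e²/4πε₀ = 1389.3546 kJ·Å/mol)

to recover s as a function of separation. For liquid argon
(ε_el = 1.52 from the refractive index) the expected factor is s = 0.81;
water's ε_el = 1.78 gives 0.75, and the 1.7–2.2 range typical of biological
environments gives 0.77–0.67.

## The solvent model

The solvent is a Lennard-Jones fluid (OPLS-style argon: σ = 3.401 Å,
ε = 0.9786 kJ/mol, m = 39.948 g/mol) in which every atom carries an isotropic
induced point dipole μᵢ = αᵢ·Eᵢ and no permanent moment, so ε_nuc = 1 by
construction. The polarizability volume α′ (Å³) is chosen from the target
ε_el through the Clausius–Mossotti relation

    (ε_el − 1)/(ε_el + 2) = (4π/3) ρ α′,

which at the liquid-argon number density ρ = 21.228 nm⁻³ (i.e. 35 250 mol/m³)
gives α′ = 1.661 Å³ for ε_el = 1.52 — within 1.5% of argon's experimental
polarizability, so the model fluid is a faithful electronic stand-in for the
real one.

Dipoles are converged self-consistently (successive substitution, mixing 0.7,
warm-started from the previous MD step, max per-dipole change < 1e-6 e·Å).
Short-range charge–dipole and dipole–dipole interactions are Thole-damped
(exponential form, λ₃/λ₅/λ₇ screening with dimensionless strength a = 0.39,
reduced distance u = r/(αᵢαⱼ)^(1/6)), which prevents the polarization
catastrophe at unphysical contact; at liquid-argon distances the damping is
inactive to machine precision. A uniform-polarization mean-field term
(4π/3V)·Σμ is added to every site's field (tin-foil/Lorentz-cavity k = 0
treatment), so the fluid's weak-field susceptibility reproduces the
Clausius–Mossotti ε_el: the packaged response test measures ε within 0.5% of
the target on liquid-density configurations. The polarization energy is the
variational minimum U = −½ Σ μᵢ·E⁰ᵢ and forces are its exact gradient at
fixed converged dipoles, verified against central differences at 1e-5
relative accuracy.

## Electrostatics of the net-charged cell

The cell contains two like ions (net ±2e). Three permanent-charge schemes are
implemented:

* `ewald_background` (library default) — full Ewald summation with the
  implicit uniform neutralizing background (validated against the Wigner
  lattice self-energy −2.837297·k_C/2L);
* `shifted_force_cutoff` — minimum-image shifted-force Coulomb, for speed;
* `none` — direct cutoff-free Coulomb between the ions as placed.

The desk-scale study configurations use `none`. Reason: in a 128-solvent box
(L ≈ 18.3 Å) the periodic-image correction to the ion–ion force,
≈ (4π/3V)·k_C·r for a charge pair plus background, reaches tens of percent of
the bare k_C/r² in the long-range fitting region r > 6.5 Å and would bias the
fitted slope; the direct scheme measures the screening of an isolated pair by
the (still fully periodic) solvent. Charge–dipole and dipole–dipole terms are
always minimum-image; with only two permanent charges and r⁻³ dipole decay, a
dipole Ewald would change the forces negligibly at these densities.

## Constrained sampling and thermodynamic integration

The interionic distance is a holonomic constraint (closed-form SHAKE/RATTLE
projections inside velocity Verlet, dt = 2 fs, constraint satisfied to 1e-6
relative at every step). Temperature is held at 300 K — a dense supercritical
state at the fixed liquid density, chosen to enhance sampling; the
polarizability depends only on the number density, so the dielectric response
is unaffected — by stochastic velocity rescaling (time constant 50 fs in
equilibration, 200 fs in production). NVE runs with the thermostat off
conserve energy to < 0.01 kJ/mol per particle over 10 ps.

At each window the recorded observable is the antisymmetric projection
½(F₁ − F₂)·r̂ of the *potential* forces on the interionic axis. This choice
(over the raw Lagrange multiplier, which also carries a centrifugal term
−2k_BT/r on average) pairs with adding the volume-entropy term analytically:
the profile is F(r) = −∫ᵣ^rmax ⟨f⟩ dr′ (cumulative trapezoid, anchored
F(r_max) = 0) plus 2k_BT·ln(r/r_max). Using the multiplier *and* adding the
ln-term would double-count the angular entropy. The correction cancels
exactly in the later subtraction, so the fitted s is independent of this
convention; profiles carry a `corrected` flag and refuse a second
application.

Window uncertainties are block standard errors (non-overlapping 1 ps blocks)
and are propagated through the trapezoid weights in quadrature, treating
windows as independent simulations (a linear sum of errors would be more
conservative but overstates the uncertainty of independent windows).

## Decomposition and fit

Writing F = U_C + U_vdW − TS and running the identical system with all
charges and polarizabilities zeroed (`zerocharge_lj` mode) removes U_vdW and
TS by subtraction: the engine guarantees identical LJ parameters between
modes, so the cancellation assumption is exact at the force-field level (it
remains an approximation insofar as electrostriction perturbs the solvent
structure around charged ions). The zero-charge profile is linearly
interpolated onto the charged grid; interpolation error vanishes as O(h²) and
is zero on the shared default grid.

U_C is linearized against 1/r and fitted by unweighted OLS separately in a
short (r ≤ 6.5 Å) and a long (r > 6.5 Å) region — 6.5 Å splits the ~3–10 Å
range into roughly equal halves; the boundary point belongs to the short
region and both choices are configurable. s = sqrt(a/(k_C q₁q₂)) from each
region's slope. Errors on s come from a within-window moving-block bootstrap
(1 ps blocks, 1000 resamples by default, charged and zero-charge windows
both resampled) re-running the entire chain per resample; reported as 1.96σ
(95% confidence). Resamples whose fitted slope turns non-positive are dropped
and counted; more than 5% drops aborts.

## Synthetic-data modes and what they show

* **Analytic mode** generates window force series from the closed-form
  oracle f(r) = s²k_C q²/r² + f_vdW(r) with i.i.d. Gaussian noise (default
  σ = 20 kJ/mol/Å per 2 fs sample, the magnitude of projected-force
  fluctuations observed in the MD at this system size). It validates the
  extraction chain end to end: the recovered s must agree with the generator
  within its own bootstrap error. With zero noise the residual error is the
  trapezoid discretization bias, O(h²) in the window spacing (~4e-3 in s on
  the default 10-window grid) — not machine zero, because TI integrates
  sampled forces rather than the analytic potential.
* **MD mode** runs the actual polarizable simulations. Desk-scale defaults:
  128 solvent atoms (L = 18.30 Å), 10 windows from 3.6 to 8.6 Å, 2 fs steps.
  The packaged acceptance run uses 2 ps equilibration + 10 ps production per
  window and 500 bootstrap resamples so a full charged + zero-charge sweep
  completes in minutes on one core; longer runs (5 + 25 ps per window, 19–21
  windows, 512 solvent) shrink the statistical error roughly with the square
  root of the sampling and are plain configuration changes.

What MD-mode agreement does and does not show: the model solvent has, by
construction, exactly the Clausius–Mossotti ε_el and no nuclear response, so
recovering s = 1/√ε_el validates the decomposition-and-fit *method* and the
mean-field ECC picture in a clean dielectric; it does not probe
first-principles effects absent from the model (charge transfer, many-body
dispersion, electronic rearrangement beyond linear response), for which
electronic-structure dynamics would be needed. Deviations between the two
fitting regions remain visible and physically interpretable: in this
classical induced-dipole model the short-range region fits a *smaller* s
(stronger apparent screening) than the long-range one, because
charge–induced-dipole attraction draws polarizable solvent toward the ions
(electrostriction) and perturbs the vdW-cancellation assumption at close
approach. Only the long-range region, where that assumption is clean, is
compared against 1/√ε_el.

## Numerical choices and edge cases

* Units: Å, fs, g/mol, kJ/mol, e; k_B = 0.0083145 kJ/mol/K.
* LJ interactions use a shifted-force cutoff at L/2 (energy and force
  continuous), so forces are exact gradients everywhere; in open
  (non-periodic) boxes the cutoff defaults to infinity and the pure-LJ limit
  is exact.
* Ewald: α = 7/L, reciprocal cutoff at exp(−k²/4α²) = 1e-10; k-vectors
  cached per box.
* Initial configurations: ions straddle the box centre at the target r;
  solvent fills a jittered simple-cubic lattice with no pair closer than
  0.85σ, retrying with shrinking jitter; Maxwell–Boltzmann velocities with
  zero net momentum.
* Pair distances below 0.1 Å, SCF non-convergence (with the last residual),
  constraint-solver failure, and instantaneous temperature above 5× target
  all raise immediately rather than producing silent garbage.
* Degenerate fits: a region with fewer than two points, a non-positive
  fitted slope with like charges, and unlike-charge inputs are rejected with
  named errors.

## Known limitations

* The bootstrap treats 1 ps blocks as independent; force autocorrelation
  times beyond ~1 ps would make the reported errors optimistic.
* The vdW-cancellation assumption ignores electrostriction-induced structure
  differences between charged and zero-charge runs; this is a real (small)
  method error inherited from the decomposition scheme, not a code artifact.
* Single distance constraint only; no multi-ion or multi-constraint support.
* The dielectric-response measurement applies to the induced-dipole fluid
  under tin-foil boundary conditions; no frequency-dependent or
  orientational (ε_nuc > 1) response is modelled.
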