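# ionscreen

**Measuring electronic screening of ion–ion interactions, and the ECC
charge-scaling factor, from constrained molecular dynamics.**

Nonpolarizable biomolecular force fields neglect electronic polarization and
therefore overestimate charge–charge interactions in solution. The
*electronic continuum correction* (ECC) repairs this in a mean-field way by
scaling ionic charges with

&nbsp;&nbsp;&nbsp;&nbsp; *s* = 1/√ε<sub>el</sub>,

where ε<sub>el</sub> is the high-frequency (electronic) dielectric constant
of the environment — ε<sub>el</sub> ≈ 1.78 for water (*s* = 0.75) and
1.7–2.2 across biological environments (*s* = 0.77–0.67). `ionscreen` is for
simulators and force-field developers who want this factor *measured* rather
than assumed: it quantifies how much a purely electronic dielectric screens
the Coulomb repulsion of a like-charged ion pair, as a function of their
separation.

The measurement pipeline:

1. **Polarizable MD** (`ionscreen.windows`, `ionscreen.polarization`): two
   like ions in an argon-like Lennard-Jones solvent carrying self-consistent
   Thole-damped induced point dipoles — electronic polarization is the *only*
   dielectric response (ε<sub>nuc</sub> = 1). The solvent polarizability α′
   is set from a target ε<sub>el</sub> via Clausius–Mossotti,
   (ε−1)/(ε+2) = (4π/3)ρα′. The interionic distance r is held by
   SHAKE/RATTLE and the projected mean force recorded per window (blue-moon
   sampling).
2. **Thermodynamic integration** (`ionscreen.profiles`): cumulative-trapezoid
   integration of the window mean forces plus the volume-entropy term
   2k<sub>B</sub>T·ln r gives the free-energy profile F(r), with block
   standard errors propagated per point.
3. **Decomposition** (`ionscreen.decompose`): subtracting the profile of the
   identical zero-charge, zero-polarizability system removes the van der
   Waals and entropic parts, leaving the screened Coulomb interaction
   U<sub>C</sub>(r).
4. **Scaled-Coulomb fit** (`ionscreen.scaling`): U<sub>C</sub> is linear in
   1/r; OLS in a short (r ≤ 6.5 Å) and a long (r > 6.5 Å) region gives
   slopes a, and *s* = √(a / k<sub>C</sub>q₁q₂) with
   k<sub>C</sub> = e²/4πε₀ = 1389.35 kJ·Å/mol. Errors are a 1.96σ
   within-window block bootstrap of the whole chain.

An *analytic mode* replaces step 1 with the closed-form screened-Coulomb
oracle (plus noise) to validate steps 2–4 independently of any MD.

## Worked example

```python
import ionscreen as isc

cfg = isc.PipelineConfig(seed=7, mode="analytic", epsilon_el=1.52,
                         production_steps=5000, n_resamples=300)
report = isc.run_pipeline(cfg)
print(report.results.summary())
```

prints

```
Scaled Coulomb fit  U_C(r) = s^2 k_C q1 q2 / r + b
charges: q1=+1e q2=+1e   boundary: 6.50 A   points: 10
------------------------------------------------------------------------
region  r-range [A]       n     slope a        b     rms       s +/-1.96sig
short     3.60-6.38      6       920.9   -107.3    0.08   0.814      0.003
long      6.93-8.60      4       925.8   -107.6    0.04   0.816      0.012
------------------------------------------------------------------------
slope in kJ*A/mol, intercept/rms in kJ/mol; errors are 1.96 sigma
```

The generator screened the +1e/+1e Coulomb repulsion with
ε<sub>el</sub> = 1.52, i.e. a true *s* of 1/√1.52 = 0.811. The fitted slopes
(≈ 0.66·k<sub>C</sub>) return *s* = 0.814/0.816 in the two regions — the
long-region value agreeing with 0.811 within its bootstrap 95% interval, the
small residual being the trapezoid discretization bias of the 10-window
grid. Replacing `mode="analytic"` with `mode="md"` runs the real polarizable
simulations; the packaged desk-scale study (128 solvent atoms, 10 windows ×
12 ps) yields a long-range *s* = 0.82 ± 0.04, statistically consistent with
the Clausius–Mossotti expectation 0.81 — the solvent's electronic cloud
screens the ions essentially as the dielectric continuum predicts.

The same workflow is available from the shell:

```bash
ionscreen plan --epsilon-el 1.52          # α′, box side, expected s
ionscreen pipeline --config study.toml --json
ionscreen simulate --distance 6.0 --seed 3 --out w6.0.tsv   # one window
```

with stage-by-stage commands (`integrate`, `decompose`, `fit`, `bootstrap`)
operating on plain TSV files.

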