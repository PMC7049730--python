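# mrbiophys

Quantitative analysis of the conformational cycle of the Mre11–Rad50 (MR)
DNA double-strand-break sensing complex, built around four kinds of
biophysical measurement on Rad50's ABC-family nucleotide-binding domains
(NBDs):

- **LRET lifetime analysis.** Luminescence resonance energy transfer with a
  chelated Tb³⁺ donor and Bodipy FL acceptor. The donor-sensitized acceptor
  lifetime τ_DA gives the transfer efficiency *E* = 1 − τ_DA/τ_D and the
  donor–acceptor distance *R* = R₀·(E⁻¹ − 1)^(1/6) (R₀ = 44.9 Å for this
  pair). A mixture of conformers (ATP-bound *closed* vs *partially open*
  NBDs) produces a multi-exponential decay; the package resolves it either
  as discrete components (multi-start nonlinear least squares) or as a
  lifetime distribution via the exponential series method (nonnegative
  least squares on 200 log-spaced bins, 100–1500 μs), and converts
  amplitudes to molecule fractions with the per-component intensity
  correction A_i/|τ_i − τ_D|. Equilibration time courses after ATP addition
  are fitted with F(t) = (F_max − F₀)(1 − e^(−k_ex·t)) + F₀ for the
  open⇌closed equilibration rate k_ex = k_assoc + k_dissoc.
- **Steady-state ATPase kinetics.** Phosphate-assay absorbances are
  converted through per-condition standard curves and fitted with the Hill
  equation v = V_max[ATP]ⁿ/(K_Mⁿ + [ATP]ⁿ); derived k_cat, k_cat/K_M and
  fold-change comparisons quantify cooperativity and DNA stimulation.
- **Equilibrium ATP binding.** Fluorescence-polarization titrations fitted
  with the two-state quadratic (ligand-depletion) binding function, exact
  when the probe concentration is comparable to K_D. Size-exclusion
  chromatograms yield dimer fractions by box summation.
- **Methyl NMR.** Weighted chemical-shift perturbations
  CSP = √(((ΔδC)/w_C)² + ((ΔδH)/w_H)²) between wild-type and mutant ILVM
  peak lists (class-specific BMRB weights; outliers at ≥ 20 ppb), and
  side-chain dynamics from ¹H triple-quantum build-up curves,
  |I_forbid/I_allow|(T) = C·η·tanh(√(η²+δ²)T)/(√(η²+δ²) − δ·tanh(√(η²+δ²)T))
  with C = 0.75, giving per-methyl η and Δη = η_mut − η_wt maps
  (significance at |Δη| > 16 s⁻¹).

A synthetic-data module generates every one of these inputs from its exact
forward model with explicit noise specifications and seeds, so the entire
pipeline is validated by parameter recovery without any external data.

The package is aimed at structural biologists and biophysicists analysing
lanthanide-based FRET/LRET distance experiments, cooperative ATPase
kinetics, or methyl-TROSY comparative NMR — on MR complexes or any system
with the same measurement types.

## Worked example

Simulate a wild-type apo LRET decay from a known two-conformer truth
(closed 40.0 Å at 15%, partially open 54.2 Å at 85%, donor lifetime
1200 μs) with 1% proportional noise, then recover distances and
populations:

```python
import mrbiophys as mb

truth = mb.ConformerTruth(((40.0, 0.15), (54.2, 0.85)))
trace = mb.simulate_lret_decay(truth, noise=mb.NoiseSpec("gaussian_proportional", 0.01), seed=1)
fit = mb.fit_multiexponential(trace, n_components=2)
pops = mb.populations_from_fit(fit, tau_d_us=1200.0, r0_A=44.9)
print(pops.summary())
```

```
LRET conformer populations
==========================
param                          estimate       std err  units
R(closed)                       39.8061      0.151432  Angstrom
molecules(closed)               14.6037      0.467957  %
R(partially_open)               54.0673      0.212516  Angstrom
molecules(partially_open)       85.3963      0.467957  %
tau_D = 1200.0 us, R0 = 44.9 Angstrom
```

Both distances come back within 0.2 Å of the truth and the closed-state
population within 0.4 percentage points — the level of agreement expected
at 1% decay noise. The same pattern holds for the other fitters, e.g. a
cooperative ATPase dataset (V_max = 10, K_M = 20 μM, n = 2.2, triplicates,
5% noise):

```python
data = mb.simulate_atpase(10.0, 20.0, 2.2, replicates=3,
                          noise=mb.NoiseSpec("gaussian_proportional", 0.05), seed=1)
print(mb.fit_hill(data).summary())
```

```
Hill kinetics fit
=================
param         estimate       std err  units
Vmax           9.89245      0.129097  uM PO4 / uM MR / h
KM             19.9846      0.783694  uM
n (Hill)       2.29332      0.168751
kcat          0.164874            --  1/min
kcat/KM     0.00825007            --  1/(min uM)
n_obs = 27, residual norm = 1.974
```

A thin CLI wraps the same functions
(`mrbiophys simulate decay|kex|atpase|fp|tq`, `fit-decay`, `esm`,
`fit-kex`, `fit-hill`, `fit-fp`, `sec-fraction`, `csp`, `tq`); see
`mrbiophys --help`.

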