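# Methods

This note records the models implemented in `mrbiophys`, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
data do and do not emulate.

## LRET distance and population analysis

**Model.** A donor-sensitized acceptor decay from a mixture of conformers
is a sum of exponentials, I(t) = offset + Σᵢ Aᵢ·exp(−t/τᵢ), where each
lifetime encodes one donor–acceptor distance through
E = 1 − τ_DA/τ_D and R = R₀(E⁻¹ − 1)^{1/6}. The assumptions are the usual
LRET ones: a single isotropically averaged R₀ (κ² folded into it),
conformers that interconvert slowly relative to the millisecond donor
lifetime (so components are distinct rather than averaged), and no
donor-only contamination in the acceptor channel.

**Populations.** The t = 0 amplitude of a component is proportional to the
number of molecules times that component's per-molecule intensity, so the
molecule fraction is Aᵢ/|τᵢ − τ_D| normalised over retained components.
The absolute value is used because the raw difference is negative whenever
τᵢ < τ_D, which is every physically sensible case; sign handling is
otherwise undefined. Components with τᵢ ≥ τ_D (non-positive E) carry no
distance information and are excluded from the normalisation with a
warning. Population and distance uncertainties are delta-method
propagations of the fit covariance (parameters treated as independent),
which is adequate at the percent-level noise these experiments show.

**Component retention.** Two policies are provided. The default
(`mode="footnote_a"`) mirrors common practice for three-exponential fits
of lanthanide decays: the fastest component is attributed to the
instrument response and always discarded, and the remaining two are the
closed / partially open conformers. `mode="threshold"` instead retains all
components with τ ≥ 100 μs. The 100 μs cutoff is the conventional bound
below which these instruments' response dominates.

**Multi-exponential fitting.** Multi-start nonlinear least squares:
16 starting lifetime sets (one deterministic log-spaced set plus seeded
log-uniform draws spanning the acquisition window), amplitudes and offset
solved linearly at each start, then a joint Levenberg–Marquardt refinement
with lifetimes parameterised on a log scale for positivity. The best
converged start wins; iteration stops early when a start reaches a
machine-precision residual. A constant offset (dark counts) is fitted by
default. Lifetime standard errors are transformed back from the log scale
by the delta method.

**Exponential series method.** The decay is expanded on a fixed grid of
200 logarithmically spaced lifetimes from 100 to 1500 μs and the
nonnegative weights are found by NNLS. The default has no regularisation,
so a noiseless decay is reproduced to numerical precision; a Tikhonov
ridge is available (fixed λ, or λ from the corner of the L-curve) for
noisy data where the unregularised distribution becomes spiky. Weights
below 10⁻¹² of the maximum are zeroed. Lifetime bins are mapped to the
distance axis bin-by-bin with weights carried over unchanged; bins at or
above τ_D are dropped with a warning.

**Equilibration kinetics.** F(t) = (F_max − F₀)(1 − e^(−k_ex·t)) + F₀ is
fitted by least squares with data-driven starting values. Only the sum
k_ex = k_assoc + k_dissoc is identifiable from a single trace; the package
deliberately does not attempt to split it. The fit is unit-agnostic
(k_ex is reported in reciprocal units of the supplied time axis), because
published equilibration rates for this system are stated in s⁻¹ while the
described plateaus take minutes; the package takes no position on that
unit discrepancy.

## Steady-state kinetics and binding

**Hill fits.** v = V_max[ATP]ⁿ/(K_Mⁿ + [ATP]ⁿ), fitted to pooled replicate
points (each observation enters the least squares individually) rather
than per-level means — with equal replicate counts per level the estimates
coincide, but pooling keeps the residual degrees of freedom honest for the
parameter covariance. n is bounded in [0.3, 4]: Rad50 has two composite
ATP sites, so physical cooperativity is near 2 and anything outside that
band is a degenerate fit, not biology. k_cat converts V_max
(μM PO₄·μM MR⁻¹·h⁻¹) to min⁻¹ per MR complex by dividing by 60;
per-ATP-site normalisation (a further ÷2) is available as a flag, default
off. Fold-change comparisons propagate relative errors in quadrature.

**Quadratic binding.** The two-state ligand-depletion solution of 1:1
binding is fitted for (K_D, F₀, F_max) with K_D bounded at 0. This form
remains exact when the probe concentration is comparable to K_D, unlike
the hyperbolic approximation. When the fitted K_D far exceeds the
titration range the result is flagged as a lower bound.

**SEC dimer fraction.** Box summation (plain sums of signal inside each
elution window, which makes the ratio independent of the sampling step),
with an optional straight-line baseline between window edges (default on).
The fraction is dimer/(dimer + monomer) and is invariant under uniform
signal rescaling.

## Methyl NMR

**CSPs.** Weighted Euclidean distance in the (δC, δH) plane with
class-specific weights w_C = (1.65, 1.6, 1.4, 1.54) and
w_H = (0.29, 0.28, 0.27, 0.41) ppm for Ile δ1, Leu δ, Val γ and Met ε —
the BMRB standard deviations of those methyl shifts — so different methyl
types are on a comparable scale. Peaks are paired by (residue, methyl
class, stereo tag); unpaired peaks are reported, never dropped. Two
outlier rules are implemented: the default fixed threshold, inclusive at
20 ppb (CSP ≥ 20 ppb flags), and an above-mean rule with strict
comparison. Each record stores which rule produced its flag.

**Triple-quantum dynamics.** The forbidden/allowed ratio model with
C = 0.75 is fitted for (η, δ) by weighted least squares; when a spectral
noise floor σ is attached to a curve, per-point ratio uncertainties
σ_ratio = |ratio|·√((σ/I_forbid)² + (σ/I_allow)²) weight the fit and the
parameter covariance is taken as absolute. η is constrained positive; δ is
initialised nonnegative (external-proton relaxation is nominally ≥ 0) but
its sign is left free. Multi-start over (η₀ from the initial slope
ratio ≈ C·η·T, δ₀ ∈ {0, η₀, 3η₀}) guards against the shallow η–δ
trade-off at small T. Δη = η_mut − η_wt is flagged significant at
|Δη| > 16 s⁻¹ by default (above-mean rule available). Interpreting Δη as a
change in motional amplitude assumes identical global tumbling in the two
samples; the package records this assumption rather than testing it.

## Synthetic data

Every generator is the exact forward model of its analysis stage plus one
of four noise models (none, constant Gaussian, proportional Gaussian,
Poisson counts). Defaults are chosen to emulate the real assay designs:

- LRET decays: donor lifetime 1200 μs (not a printed constant for this
  probe set; chosen inside the 100–1500 μs analysis window and carried in
  provenance metadata), acquisition of 1500 channels of 4 μs over a 6 ms
  window (about five donor lifetimes, typical of a lifetime photometer),
  1% proportional noise. Amplitudes are constructed as
  fraction·|τᵢ − τ_D|, the exact inverse of the population correction, and
  normalised to I(0) = 1 since the analysis is scale-invariant. An
  optional fast extra exponential (default 30 μs) stands in for the
  instrument-response component; no convolution with a measured response
  function is attempted.
- ATPase: 9-point titration over 0–300 μM (log-ish spacing so ~3 points
  sit below a 20 μM K_M), three replicates, 5% proportional noise.
- FP binding: 10-point protein grid over 0–25 μM with a 5 nM probe.
- TQ build-up: the 9 standard delays 2, 4, 6, 8, 10, 15, 20, 25, 30 ms;
  noise can target the ratio directly or the two intensities separately.
- Peak lists: arbitrary base lists with named per-methyl (ΔδC, ΔδH)
  perturbations and optional jitter.

What the synthetic data do **not** emulate: photon-counting statistics
convolved with a real instrument response, wavelength-resolved emission,
baseline drifts, peak overlap or assignment ambiguity in spectra, and
pipetting-correlated (non-independent) replicate errors. Passing
recovery tests therefore demonstrate the correctness and conditioning of
the estimators under the stated noise models, not robustness to every
systematic error of the real instruments.

## Problem sizes and determinism

Monte Carlo recovery tests use 100 seeded trials per scenario (20–25 for
the smaller unit-level checks), sized so the full suite runs in well under
a minute of fitting per scenario. All randomness flows through
`numpy.random.default_rng(seed)`; equal seeds give bit-identical datasets,
and the pipeline report records seed and configuration hash so every
number in a summary table is traceable to its inputs.

## Known limitations

- Closely spaced lifetimes (ratio below ~1.5) are not reliably separable
  by the discrete fit at percent-level noise; the ESM distribution is the
  better view there.
- k_assoc/k_dissoc cannot be separated from a single equilibration trace.
- The ESM L-curve heuristic is a convenience, not a statement of optimal
  regularisation; for quantitative population work the discrete fit with
  the amplitude correction is preferred.
- CSP and Δη significance rules are conventions, not hypothesis tests; no
  multiplicity correction is applied.
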