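# Methods

This note documents the model, the numerical choices, the packaged
parameter sets, and what the synthetic-data generators do and do not
emulate.

## Model and assumptions

The circuit is a one-dimensional chain of Wilson–Cowan motifs with complete
nearest-neighbor connectivity. Units are dimensionless firing-rate
deviations from a quiescent baseline; time is measured in inhibitory
relaxation times (`tau_E` is the excitatory relaxation time in those
units); one unit of length is one motif spacing. The activation functions
are logistics shifted so that `g(0) = 0`, making the quiescent state a
fixed point; their default gain normalizes the slope at the origin to one,
so the linearized chain and the continuum weights coincide. Negative rates
are meaningful (suppression below baseline), as usual for linearized
rate models.

The continuum limit replaces the neighbor sums by second differences:
local weights `W_xy = w_xy + 2 w~_xy`, spread coefficients `D_xy = w~_xy`.
The cubic damping terms `gamma (tau dr/dt + r)^3` inherit their
coefficients from the third derivative of the sigmoids.

Assumptions worth keeping in mind: strictly nearest-neighbor (diffusive)
coupling, isotropy in the 2D extension, no plasticity, no conduction
delays, and input currents that enter additively with a fixed split
`alpha : 1 - alpha` between E and I.

## Intrinsic wave

The static linearized system with a delta input has solutions
`exp(s x)` with `s` the roots of a quadratic in `s²` (the static
characteristic polynomial `P`). Complex conjugate roots give the damped
standing wave with intrinsic frequency `k_n` and decay `lam`; real roots
mean a purely decaying (non-wave) regime, reported as a typed error. The
amplitude coefficients `Gamma`, `Delta` follow from the two jump conditions
obtained by integrating each field equation across the delta; this is the
only self-consistent route given that the weights determine everything.
The implementation cross-checks itself in two independent ways: the
integral of `G` equals the static uniform-input gain (the Fourier zero
mode), and the convolution solution matches the time-stepped field
equations to better than 1% on the moderately damped reference.

## Stability and the two resonance regimes

A finding that shapes the packaged configurations: for this continuum
system, linear stability of the quiescent state at *every* wavenumber
requires `tau_E D_II <= D_EE` (otherwise the trace of the linearized
dynamics turns positive at large `k²`), and under that constraint a
positive `kappa4` forces `kappa_asymp < 0`. The textbook two-regime
picture — spatial resonance rising (regime 1) or falling (regime 2) with
temporal frequency toward a *positive* asymptote — therefore lives in the
parameter region `tau_E D_II > D_EE`, where the continuum is unstable to
very short wavelengths while the discrete chain (whose dispersion is
bounded by the lattice band edge) can remain well behaved. Consequently:

- `regime_1` and `regime_2` are packaged for the algebraic resonance
  analysis (matrix determinants, Cramer solutions, resonance curves), which
  involves no time stepping and is exact regardless of stability;
- `reference_low_damping` and `reference_moderate` are unconditionally
  stable and serve all time-domain simulation.

A related numerical fact: the slowest temporal mode of a stable
configuration relaxes at a rate proportional to `lam²` (the determinant of
the linearized dynamics at `k = k_n` is `4 p2 k_n² lam² / tau_E`). Weakly
damped circuits are therefore physically slow to reach steady state. The
1D integrator is still practical there; for the 2D lattice the package
solves the static linear system per Fourier mode instead
(`simulate_lattice2d(..., method="spectral")`, periodic boundaries, exact
for `gamma = 0`), cross-validated against the explicit Euler path on the
moderately damped configuration.

## Packaged parameter sets

All weight sets were chosen by construction (root placement of the static
polynomial) or small randomized searches against the criteria below; none
are fitted to data.

| name | purpose | properties |
|---|---|---|
| `reference_low_damping` | interference, zones, 2D foci | `k_n = 1.000`, `lam = 0.037`, `lam/k_n = 0.037`, stable at all `k` |
| `reference_moderate` | numerical cross-checks (PDE, chain, 2D Euler) | `k_n = 0.99`, `lam/k_n = 0.17`, spectral abscissa ≈ −0.24 (fast relaxation) |
| `regime_1` / `regime_2` | resonance analysis | `k_n² - lam²` below / above `kappa_asymp`; `kappa4 > 0` |
| `contrast_up` / `contrast_down` | nonlinear contrast shifts | low-damping weights with `(gamma_E, gamma_I) = (0.5, 0.02)` / `(0.02, 0.5)`, giving `xi_E > xi_I` / `xi_E < xi_I` |
| `node_excitatory` / `node_inhibitory` | duration thresholds | single motif, damped-oscillatory; `alpha = 0.9` / `0.2`; E saturates early (`S_E = 1`), I is recruited supralinearly above threshold 1 |

The elliptical-ring default (`DEFAULT_RING`: a = 9.5, b = 8.9, width = 1)
places the focal distance `sqrt(a² - b²) ≈ 3.3` at half the intrinsic
period, which phase-aligns the near- and far-vertex boundary contributions
at each geometric focus; the two interference maxima then land within a
few percent of a period of the foci, and approach them under grid
refinement.

## Numerical choices

- Time integration is explicit Euler. The cubic term contains the time
  derivative; substituting `y = tau dr/dt + r` reduces each update to the
  unique real root of `gamma y³ + y = F` (solved in closed form), so the
  step stays explicit and exact in the nonlinearity.
- Default steps obey a conservative diffusive bound
  (`0.2 · tau_min dx² / 4 D_max`); a step-halving check is part of the test
  suite. Steady state is declared at `max |dr/dt| < 1e-8` (configurable).
- Boundaries: absorbing by default with the domain padded well past the
  stimulus; periodic available for spectral checks. Point sources are
  rendered by splitting the weight over the two bracketing grid nodes
  (keeps the discretization second-order for off-node positions).
- The determinant constants (`mu`, `kappa4`, `kappa2`, `kappa0`) are exact
  closed forms derived from the complex 2×2 representation of the 4×4
  system; `det_coefficients` verifies the identity against the numeric
  determinant at 100 random frequency pairs and refuses to return on
  mismatch. Note the closed form of the asymptote numerator is
  `(W_EE-1) D_EE + tau_E² (W_II+1) D_II - tau_E (W_EI D_IE + W_IE D_EI)`;
  the sign of its middle term is fixed by that identity.
- `spatial_resonance` inverts the closed-form `w²(k_r)` relation by
  bracketed root finding on the branch continuous with
  `sqrt(k_n² - lam²)` at `w = 0`; the response-surface ridge (amplitude
  argmax) tracks it to about 1%, the residual being the `k`-dependence of
  the Cramer numerator.
- The nonlinear fixed point iterates `Y -> M(Y)^{-1} J0` from the linear
  solution, with automatic under-relaxation (factor 0.5) when successive
  steps oscillate; every converged state is checked against the defect
  `M(Y) Y = J0` independently of the iteration path. The structural
  constants (`Psi`, `Phi`, `eta`, `xi`, `sigma`) are first-order-in-gamma
  expansions of the exact Cramer solution; `xi_E = 3 gamma_E D_II / 8 p2`,
  `xi_I = 3 gamma_I D_EE / 8 p2`.
- Tuning-peak smoothing is local polynomial regression (tricube weights,
  default local quadratic, bandwidth 0.5 of the axis range on a log axis;
  leave-one-out cross-validation available). The damped-harmonic fitter
  adds an explicit constant baseline (sensitivity data sit on a nonzero
  operating point), caps the frequency at the probe grid's Nyquist
  frequency to exclude aliases, and declares "no modulation" when the
  explicit `f = 0` (pure-decay) fit comes within 10% of the best residual
  or the best fit completes less than half a cycle over the span.
- `compare_peaks` applies the rank-sum test to bootstrap replicates, as is
  common practice in this literature; because replicates are not
  independent observations this overstates significance, so the overlap of
  the 95% percentile intervals is reported alongside.

## Synthetic data: what it does and does not emulate

The tuning generator plants separable log-Gaussian SF×TF surfaces whose
peak SF moves with contrast (rising by default, fully configurable), with
saturating contrast gain, a baseline rate, and truncated-normal noise with
variance proportional to the mean (dispersion 2 by default — overdispersed,
count-like). Ten trials per condition and five-to-seven contrast levels
mirror common awake-primate designs. It does *not* emulate spike timing,
adaptation, eye movements, correlated noise across neurons, or
cell-to-cell heterogeneity: recovery results on this data certify the
estimators' calibration under the stated noise family, not performance on
raw recordings.

The sensitivity generator draws lateral profiles from the damped-harmonic
family with one shared modulation frequency across flanker conditions (the
wave account's prediction) on a 0–0.5° probe-distance grid; its
`decay_only` scenario generates the null (pure Gaussian decay) that the
single-extremum formula `x_min = ln(A e^{lam (x1-x0)} / B) / 2 lam`
contrasts with a multi-minima wave profile.

The observer is a Weibull 2AFC trial oracle with optional lapses; the
3-down/1-up staircase (start 40%, steps 12% then 3% after the second
reversal, 30 trials, threshold = mean of the last five tested contrasts)
converges near its 79.4%-correct point, which the tests verify over 200
seeded runs.

### Calibration of the bootstrap peak interval

On generator data (12 datasets × 5 contrast conditions, 10 resamples × 500
iterations), the planted peak falls within 1 SD of the estimate in ≈ 76% of
replicates, within 1.5 SD in ≈ 88%, and within 2 SD in ≈ 93% — i.e. the
resampling SD behaves like an honest, approximately Gaussian standard
error (nominal 1-SD coverage is 68%). Checks that demand ≥ 90% coverage
from a 1-SD interval are therefore expected to fail for statistical
reasons, not implementation ones; the unit tests assert the calibrated
rates.

## Problem sizes

Defaults keep everything desk-scale: 1D grids of 256–1024 nodes, 2D
lattices of 128–256², two-point sweeps at 0.01 period resolution,
500-iteration bootstraps, and 100–200 staircase repeats. All randomness
flows through explicit seeds; repeated runs are bit-identical.

## Known limitations

- The chain equals the continuum only when the wave spans many motifs
  (`k_n << pi`); at `k_n ≈ 1` the lattice dispersion `2(1 - cos k)` vs `k²`
  shifts the intrinsic frequency by a few percent (the refinement test
  scales the spread coefficients to verify convergence).
- The spectral 2D path requires `gamma = 0`; nonlinear 2D work must use the
  (slower) Euler path on a fast-relaxing configuration.
- Nonlinear analysis is static (`w = 0`); time-dependent forcing of the
  cubic system is out of scope.
- The regime-1/regime-2 configurations are not meant for continuum time
  stepping (see the stability discussion above).
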