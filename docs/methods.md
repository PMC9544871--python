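# Methods

## Monte-Carlo TCSPC model

Each recorded photon's arrival time is the sum of an exponential emission
delay (lifetime τ, inverse-transform sampled) and a Gaussian excitation
time representing the instrument response (IRF).  Defaults mirror typical
TCSPC acquisition: a 25 ns acquisition window with 256 uniform bins
(Δ ≈ 97.7 ps), IRF centred at t0 = 3.2 ns with standard deviation 150 ps,
and a 20 MHz laser (50 ns inter-pulse period).  The IRF is parameterized
by its actual standard deviation.  Detector after-pulsing is modelled as
`round(Ap·N)` background photons per decay, uniformly distributed over
the acquisition window; `Ap` is the background fraction relative to the
signal photon number N.

Arrival times are wrapped modulo the laser period; times that still land
beyond the acquisition window (possible when the period exceeds the
window, as at 20 MHz) are not recorded.  With the period equal to or
shorter than the window every photon is recorded and histogram totals are
exactly `N + round(Ap·N)`.  The 20 MHz default matters for long
lifetimes: with a 25 ns period, tails of >4 ns decays wrap into the
pre-rise bins, contaminate the background estimate and bias the analysis
— the "incomplete decay" regime, which the complete-decay estimators here
deliberately do not model.

Bins are half-open `[kΔ, (k+1)Δ)`.  Image stacks draw each pixel from an
independent generator seeded by `SeedSequence(seed, spawn_key=(row, col))`,
so stacks are bit-reproducible and sub-regions can be regenerated in
isolation.

What the simulator does **not** emulate: pile-up, detector timing jitter
beyond the Gaussian IRF, time-correlated dark counts, multi-exponential
mixtures, and spatially correlated noise.  Tests that pass on these
synthetic data therefore validate the estimator chain under ideal
single-exponential statistics, not robustness to those real-world
effects.

## CMM estimation chain

1. **Background subtraction.**  The level is the mean of the first
   `n_pre_bins` (default 20) bins, clipped to end before the rising edge
   (first bin above 10% of the peak; if the very first bin already
   qualifies there is no detectable pre-rise region and the requested
   count is used unclipped).  Corrected bins may be negative; clipping
   would re-introduce a positive bias.

   The level can be estimated per decay (`background="pixel"`, the
   default for images, whose background varies spatially) or pooled over
   a batch (`background="shared"`).  Pooling matters quantitatively: per
   decay, the 20-bin mean carries a ~22% relative error at typical
   levels, which roughly doubles the lifetime spread (e.g. 95 ps instead
   of 43 ps at τ = 2.5 ns, N = 5000, Ap = 5%).  A uniform-condition
   region analysed as an image shares one level, which is what the
   repeated-measurement harness and the benchmark studies use.

2. **Discrete centre-of-mass** over the analysis window: weighted mean of
   left bin edges over bins whose left edge lies inside the window, plus
   Δ/2 to re-centre onto midpoints.  For a smooth, well-sampled
   distribution this mid-bin convention reproduces the true mean (the
   Δ/2 cancels the left-edge origin); the IRF moment of the default
   Gaussian IRF is therefore ≈ 3.2 ns.  Windows are anchored at t = 0 of
   the acquisition axis.

3. **IRF moment subtraction**: `τ_CMM = τ_CM − τ_IRF`, with τ_IRF the
   centre-of-mass of the measured IRF histogram (or the centre for a
   parametric Gaussian IRF).

4. **Finite-window correction**: fixed-point iteration
   `τ ← τ_CMM + Ta·e^(−Ta/τ)/(1 − e^(−Ta/τ))` from τ0 = τ_CMM, with the
   effective window `Ta = T_window − τ_IRF`.  The default is 10
   iterations; a tolerance mode iterates until successive iterates change
   by less than a set amount (1 ps typical) and reports the count.  The
   iteration contracts with rate ≈ `(Ta/τ)²·e^(−Ta/τ)/(1−e^(−Ta/τ))²`,
   so 10 iterations suffice below α = τ/Ta ≈ 0.4 — the regime where each
   window is actually used by the fusion — while α = 0.64 needs ~28
   iterations to reach 1 ps.  Inputs at or beyond Ta/2 (the supremum of
   the forward map) have no finite solution and are flagged invalid.

Invalid pixels (non-positive net counts, non-invertible moments) yield
NaN plus a mask channel; image sweeps never raise.

## F3-CMM fusion

Windows default to 25, 12.5, 6.25 ns (binary subdivision of the
acquisition window).  Weights are evaluated at the T2 = 12.5 ns pilot
estimate; when that pixel is invalid but the wide-window estimate is
valid, the latter substitutes, and a pixel with no valid pilot is
invalid.  The fusion coefficients sum to one by construction, and a
window with exactly zero coefficient is ignored even if its own estimate
is invalid (a 4 ns decay that the 6.25 ns window cannot invert is still
fused from the wider windows).  The logistic exponent is clamped at ±700
and saturates exactly to 0/1 — a numerical contract only, with no effect
at b = 20.  Iterative re-estimation of the weights from the fused result
is not implemented; the pilot is already accurate near both cut-offs.

Shipped defaults are A = 3.218, C = 0.07339, b = 20 with B = 0, so
analysis works out of the box; `calibrate` regenerates all coefficients.
Cut-offs are always computed from effective window lengths (total minus
τ_IRF), giving ≈ (2.06, 0.77) ns at the default IRF.

## Calibration protocol

`calibrate` benchmarks CMM at the three windows over a common lifetime
grid (default 0.25–4.5 ns in 0.25 ns steps, N = 5000, Ap = 5%, 1024
repeats per point), computes F′ per point, expresses it against
α = τ/Ta_effective — the three window curves collapse — and fits
`F′(α) = A·α + B + C/α` by unweighted linear least squares over the
pooled points with α ≤ 0.7.  Two deliberate choices:

* the finite-window correction runs in tolerance mode (1 ps) here, since
  at the high-α end 10 fixed iterations leave a pure
  iteration-truncation bias that corrupts the fitted slope (A inflates
  to ≈ 4.8 and R² collapses to ≈ 0.86);
* the fit stops at α = 0.7 because beyond it only the narrowest window
  contributes and its noise amplification departs from the rational
  form.

Under this protocol the fitted C is stable at ≈ 0.072–0.076 and
R² ≈ 0.993–0.995, while A lands at ≈ 3.7–3.9.  A cross-check against the
delta-method optimum for a truncated-exponential moment estimator (the
exact asymptotic F as a function of α, computable in closed form) gives
a slope of ≈ 3.96 over α ∈ [0.3, 0.7] — the simulation study sits at the
statistical limit of the estimator, so the fitted A is a property of the
protocol, and moderate changes to grid support or fit weighting move it
by tens of percent.

## Figures of merit and the benchmark harness

F and F′ use the programmed signal photon number N (excluding
background): only then does the background-free case reach the ideal
F = 1.  σ_τ is the unbiased sample standard deviation over repeats;
grid points where more than half the repeats fail are flagged.
Monte-Carlo standard errors of F follow the χ-distribution delta method,
`σ_F ≈ F/√(2(n−1))`, which sets the tolerances used in tests.

## Least-squares baseline

The comparison method fits `A·(IRF ⊛ e^(−t/τ)) + c` per decay by
unweighted least squares (Levenberg–Marquardt on log τ, amplitude and
offset), with the IRF binned on the acquisition grid and a complete-decay
convolution (no wrap term).  Starting values: τ from the CMM estimate,
amplitude from the peak, background from the pre-rise mean.  Its role is
the qualitative photon-efficiency ordering (F_LSM > F_CMM under identical
data), not a replica of any specific fitting package.

## Problem sizes

The test suite and the acceptance script use 1024 repeats for the
headline conditions and 96–512 repeats for property checks, and the
calibration study runs 3 windows × 18 lifetimes × 1024 repeats — about
10⁸ simulated photons total, a few tens of seconds on one core.  These
sizes put Monte-Carlo standard errors of F near 2–4%, which is what the
stated test tolerances assume.

## Known limitations

* Single-exponential decays only; mixtures are reported as an average
  lifetime with no decomposition.
* Incomplete decays (period-wrapped tails) bias all complete-decay
  estimators here toward shorter lifetimes; fitting an incomplete-decay
  model would be required.
* The per-decay background estimate is noisy at low counts; prefer the
  shared/pooled mode on uniform regions, or supply a known level.
* Exactly three fusion windows; the fusion formula generalizes but the
  calibration and cut-off machinery assume the nested triple.
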