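# f3flim

Photon-efficient fluorescence-lifetime extraction from time-domain FLIM
(TCSPC) data by the centre-of-mass method (CMM) and its three-window
generalization **F3-CMM**, together with a Monte-Carlo TCSPC simulator, a
least-squares single-exponential baseline, and the F / F′ photon-efficiency
figures of merit.

## Who this is for

Researchers analysing time-correlated single-photon-counting FLIM stacks
(time-bin × y × x photon-count histograms) who need lifetime maps that stay
precise **and** accurate across a large lifetime dynamic range — especially
in the presence of detector background (after-pulsing, dark counts), where
a single analysis window cannot serve both short and long lifetimes.

## The method

For a single-exponential decay `I(t) = I0·exp(-t/τ)` observed over a finite
window `[0, Ta]`, the first temporal moment is

    CM(τ) = τ − Ta·e^(−Ta/τ) / (1 − e^(−Ta/τ))

CMM estimates the lifetime per pixel by (i) subtracting the mean of the
pre-rise time bins (background), (ii) computing the discrete centre-of-mass
of the corrected decay over the analysis window, (iii) subtracting the
IRF's own moment `τ_IRF`, and (iv) inverting the relation above by
fixed-point iteration with the effective window `Ta = T_window − τ_IRF`.

With background present, a wide window accumulates noise under short
decays and a narrow window biases long decays.  F3-CMM runs CMM at three
nested windows (25, 12.5, 6.25 ns by default) and blends the results with
logistic weights

    τ_F3 = W12·τ_T1 + (W23 − W12)·τ_T2 + (1 − W23)·τ_T3,
    Wij(τ) = 1 / (1 + e^(−b·(τ − τc_ij)/τc_ij)),   b = 20

evaluated at the mid-window pilot estimate.  The cut-offs
`τc_ij = sqrt(Ta_i·Ta_j·C/A)` come from the empirical photon-efficiency
curve `F′(α) = A·α + B + C/α` (α = lifetime / effective window), which
collapses onto one curve for all window sizes and is refit by `calibrate`.

Quality is scored by the photon-efficiency figures of merit

    F  = √N·σ_τ/τ          (1 for an ideal shot-noise-limited estimator)
    F′ = √N·√(σ_τ² + Δτ²)/τ   (folds the bias Δτ into the cost)

## Worked example

Simulate a uniform 2.5 ns, 32×32 stack with 5000 photons per pixel and 5%
after-pulsing, then extract the fused lifetime map:

```
$ cat sim.yaml
shape: [32, 32]
afterpulsing: 0.05
seed: 7
lifetime_map: {constant: 2.5}
photon_map: {constant: 5000}

$ f3flim simulate --config sim.yaml --out stack.tif
$ f3flim analyze f3cmm --stack stack.tif --irf gauss:3.2,0.15 \
      --background shared --out tau_f3.tif
$ cat tau_f3_summary.txt
method	f3cmm
n	1024
mean	2.500542158879344
std	0.044342135686479565
raw_mean	2.5005527928630693
raw_std	0.043712068631155995
fit	gaussian
```

The fused map recovers the programmed 2.5 ns with no discernible bias and
a 44 ps spread over the 1024 pixels — i.e. `F = √5000·0.0443/2.5 ≈ 1.25`,
close to the shot-noise limit despite the 5% background.  The same
library is scriptable directly:

```python
import numpy as np
from f3flim import SimConfig, CalibrationParams, simulate_irf, irf_moment
from f3flim.f3cmm import f3cmm_batch
from f3flim.tcspc_sim import simulate_decays

cfg = SimConfig(afterpulsing=0.05, seed=7)
tau_irf = irf_moment(simulate_irf(cfg, 10**6, seed=1))
counts = simulate_decays(cfg, 0.5, 5000, 1024, rng=np.random.default_rng(2))
taus = f3cmm_batch(counts, tau_irf, CalibrationParams(), cfg.bin_width)
print(taus.mean(), taus.std(ddof=1))   # ~0.500, ~0.008 (ns)
```

Other commands: `f3flim analyze cmm|lsm` (single-window analyses),
`f3flim calibrate` (refit A, B, C from simulation), `f3flim benchmark`
(F/F′ tables over a lifetime grid, CSV output).

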