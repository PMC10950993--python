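# tumoran

Stochastic modelling of tumour clonal evolution and drug resistance with a
fixed-size Moran birth–death process, for quantitative cancer biologists and
modellers who want to ask: *given a growing tumour that can acquire a fitter,
partially drug-resistant clone, which treatment schedule — a short maximum
tolerated dose (MTD), early dosing, dual targeted dosing, a sustained low
dose, or a pharmacokinetically waning dose — controls it best?*

## The model

A population of fixed size `N` contains healthy cells (`h`), cancer cells
(`c`) and driver-mutant cancer cells (`m`) with fitnesses `f_h, f_c, f_m`.
Each timestep (one cell division) a cell reproduces with probability
proportional to `N_i f_i` and a cell dies with probability `N_i / N`; the
offspring replaces the dying cell. In the two-type case this gives

    P(N_c → N_c+1) = N_c f_c / (N_c f_c + N_h f_h) · N_h / N
    P(N_c → N_c−1) = N_h f_h / (N_c f_c + N_h f_h) · N_c / N

and no change otherwise. A cancer birth becomes a mutant birth with driver
probability `r_m` (no back-mutation). Treatment with efficacy `eff_c` ∈ [0,1]
reduces the cancer clone's fitness to `f_c (1 − eff_c)` inside a dosing
window, or to `f_c (1 − eff_c·2^(−(t−t_start)/t_half))` for a drug waning
with half-life `t_half`; repeated doses superpose and saturate at efficacy 1.
Mutant fitness is reduced by `eff_m` in the same way; healthy cells are
unaffected.

Alongside the stochastic engine there is a deterministic recursion for the
expected counts (with `W = Σ N_i f_i`):

    E[N_c,n | N_c,n−1] = N_c + (1 − r_m) N_c f_c / W − N_c / N

(and analogously for `h` and `m`), which tracks the ensemble mean whenever
every nonzero initial count is at least ~10% of `N`. Because it is cheap, it
drives the calibration: a two-stage exhaustive grid search that minimises the
RMSE between the recursion's tumour burden `(N_c + N_m)/N` and an observed
growth series — stage 1 fits `(f_c/f_h, f_m/f_h, r_m)` to the untreated
(vehicle) arm, stage 2 holds those fixed and fits `(eff_c, eff_m)` to the
treated arm under the actual dosing regimen (e.g. four weekly doses with a
5.8-day half-life, the trastuzumab setting).

## Worked example

```python
import numpy as np
from tumoran import *
from tumoran.fitting import GridSpec

# 1. Stochastic tunneling: can a 3x-fit mutant clone take over before the
#    original cancer does?
cfg = SimulationConfig.from_counts(N=1000, M=20000, n_cancer=100,
                                   n_total=200, seed=0)
res = estimate_tunneling(cfg, FitnessParams(f_h=1, f_c=1.1, f_m=3.0),
                         MutationParams(0.01))
print(res.summary())

# 2. Calibration round-trip on synthetic growth data (no noise, truth on-grid)
spec = SynthSpec(fc_ratio=1.2, fm_ratio=1.4, r_m=0.0, eff_c=0.05,
                 noise_sigma=0.0, seed=1)
vehicle, treated, truth = generate_growth_series(spec)
grid = GridSpec(fc=np.arange(1.0, 1.41, 0.01), fm=np.array([1.0, 1.4]),
                rm=np.array([0.0, 1e-6]))
print(fit_growth(vehicle, grid, N=spec.N).summary())
```

prints

```
Tunneling estimate
  P(mutant fixates first) = 0.9800 +/- 0.0099 (binomial SE, n=200)
  outcomes: mutant=196, none=4

Moran growth model (vehicle fit, grid-search RMSE)
====================================================
observations:   11    N (carrying capacity): 200
grid points:   164    divisions/hour: 25.000
----------------------------------------------------
f_c / f_h      1.2000
f_m / f_h      1.0000
r_m         0.000e+00
RMSE         0.000000  (burden as proportion of N)
====================================================
```

The tunneling estimate says that with a weakly advantaged cancer
(`f_c = 1.1`) seeding mutants at `r_m = 0.01` per cancer birth, a highly fit
mutant (`f_m = 3`) reaches fixation first in ~98% of replicates (the
remaining runs fixate nothing within the 20,000-division horizon). The fit
recovers the generating fitness ratio 1.2 exactly with zero residual, as it
must for noiseless on-grid truth.

## Command line

Every analysis is also a subcommand writing CSV/JSON artifacts plus a
run manifest:

```bash
tumoran tunneling --seed 1 --N 1000 --M 20000 --n-total 1000 \
        --f-c 1.1 --f-m 3.0 --r-m 0.01 --outdir out/tunneling
tumoran simulate --seed 7 --N 100 --M 5000 --n-cancer 10 --f-c 5
tumoran synth --seed 3 --sigma 0.05 --outdir out/synth
tumoran fit --vehicle out/synth/growth.csv --N 200 --outdir out/fit
```

Subcommands: `simulate`, `ensemble`, `expect`, `tunneling`, `scan-fixation`,
`min-fitness`, `strategies`, `scan-treatment`, `fit`, `synth`.

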