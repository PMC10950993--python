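# Methods

## Model

`tumoran` implements a discrete-time Moran birth–death process over a
population of fixed size `N` with three cell types: healthy (`h`), cancer
(`c`) and driver-mutant cancer (`m`). One timestep is one cell division.
The reproducing cell is drawn fitness-weighted (probability `N_i f_i / W`,
`W = Σ_j N_j f_j`), the dying cell count-weighted (`N_i / N`), independently;
the offspring replaces the dying cell, so the total never changes. A
same-type birth/death pair is a no-change event, which makes the event
probabilities collapse to the standard two-type product form. Self-
replacement (the reproducer chosen to die) is allowed; excluding it would
only rescale the no-change mass and is not distinguishable from the printed
transition probabilities.

**Mutation.** Each cancer birth is diverted to a mutant offspring with
probability `r_m`, so the per-step marginal mutation probability is
`r_m N_c f_c / W`. The dying cell is still drawn count-weighted over all
types; a mutant born onto a dying mutant is a net no-change. There is no
back-mutation and healthy cells never mutate. Mutation stays active while
mutants exist (every cancer birth can mutate); see "Known limitations" for
the consequence this has for exact cancer fixation.

**Treatment.** A course reduces clone fitness multiplicatively:
`f_c → f_c (1 − eff_c)` within a constant-mode window, or
`f_c → f_c (1 − eff_c 2^(−(t − t_start)/t_half))` for a waning dose
(first-order pharmacokinetic clearance with half-life `t_half`); identically
for the mutant clone with `eff_m`. Healthy fitness is never modified and
treatment affects reproduction only, not death. When courses overlap, their
instantaneous efficacies add and saturate at 1 — the linear-pharmacokinetics-
with-effect-saturation rule — which also defines how weekly re-administered
waning doses superpose. Schedules are stored in cell divisions; wall-clock
time converts at `N / hours_per_cell_cycle` divisions per hour (default
8-hour cycle, so `N/8` per hour).

**Expectation recursion.** The deterministic surrogate iterates the exact
one-step conditional expectation of the event distribution:

    ΔE[N_h] = N_h f_h / W − N_h / N
    ΔE[N_c] = (1 − r_m) N_c f_c / W − N_c / N
    ΔE[N_m] = (N_m f_m + r_m N_c f_c) / W − N_m / N

with real-valued counts propagated without rounding (it is a mean field, not
a state). This is the unique mean field consistent with the stochastic event
distribution; it reduces to the classical two-type recursion at `r_m = 0`.
Multi-step, it is *not* the exact ensemble mean: a finite-N (Jensen) bias of
order 1/N accumulates because the per-step drift is nonlinear in the counts.
Measured at `N = 1000` (`f_c = 1.5`, start 20% cancer, 1000 replicates) the
bias peaks at ~0.3% of N — about 2 ensemble standard errors at that
replicate count — so agreement tests assert `max(3 SE, 0.005 N)`. Below an
initial count of 10% of N the surrogate additionally diverges from the
ensemble mean because extinct trajectories drag the average down; the
`ExpectedTrajectory.below_validity_threshold` flag marks that regime. The
mean field never absorbs, so it also departs from the stochastic model at
horizons long enough for fixation to dominate.

## Simulation engine and randomness

Ensembles advance all replicates in lock-step through one vectorised NumPy
kernel; per step and replicate three uniforms choose reproducer, mutation
and dier. The stream is keyed by `SeedSequence(seed)`, so an ensemble is
bit-reproducible given `(seed, n_total)`. Single trajectories use
`SeedSequence((seed, replicate))` and are reproducible independently of any
ensemble. (Per-replicate child streams inside the ensemble kernel were
rejected: they force a per-replicate Python loop roughly 50× slower for
identical statistics.) Replicates that reach an absorbing state — all
healthy, all mutant, or all cancer when `r_m = 0` — are frozen, and the
kernel exits early once every replicate is absorbed, padding summaries so
all trajectories have length `M + 1`. Paired strategy comparisons reuse the
same base seed across arms, so arms consume a common uniform stream
(positively coupled outcomes, lower comparison variance); an unpaired mode
draws independent streams.

Fixation bookkeeping is by first passage: a replicate is classified by the
first type whose count reaches `N` within `M` divisions ("tunneling" = the
mutant gets there before the original cancer), `none` if no type fixates.

## Calibration

The grid search scores every parameter combination by the RMSE between the
recursion's tumour burden `(N_c + N_m)/N` and the observed series, linearly
interpolated at the observation times (observed sizes are divided by the
user-supplied carrying capacity `N`, so fitting operates on proportions).
Ties break to the first-encountered combination in lexicographic
`(f_c, f_m, r_m)` order — with a vectorised evaluation this is exactly
`np.argmin` on the C-ordered grid. Stage 1 (vehicle arm) scans
`(f_c/f_h, f_m/f_h, r_m)`; stage 2 (treated arm) freezes stage 1 and scans
`(eff_c, eff_m)` under superposed waning doses; the stages are deliberately
sequential, not a joint refit. The full-resolution fitness grid is 1–2 in
steps of 0.001 and the efficacy grid 0–100% in steps of 0.1%
(`GridSpec.fine()`); default grids are coarser (0.01 fitness, 5% `eff_m`)
because the full product grid multiplies to ~10⁶ recursion sweeps. The
mutation grid is logarithmic over 1e−9…1e−3 — spanning the driver-mutation
probabilities reported in the literature (1e−9…1e−5) with headroom — plus
exactly 0. The initial tumour burden defaults to the first observation.

Two diagnostics are attached to the results objects: the profile RMSE
surface over `(f_m/f_h, r_m)` (minimised over `f_c/f_h`), whose flat valley
expresses that mutant fitness and mutation probability are not practically
identifiable from a single growth curve; and a flat-surface flag on `eff_m`
raised when mutants never reach appreciable numbers inside the fitted
horizon, in which case the data contain no information about efficacy
against them.

## Synthetic data

The generator emulates a trastuzumab-style mouse experiment: a vehicle and a
treated growth series sampled twice weekly over five weeks, four weekly
doses from day 0 with a 5.8-day half-life, cells cycling every 8 hours, and
the tumour starting at 10% of carrying capacity (inside the mean-field
validity region). The default carrying capacity is `N = 200` — small enough
that a recursion sweep over a fitting grid stays interactive, large enough
that the division-rate mapping is meaningful. Noise is multiplicative
Gaussian (`size × (1 + σz)`, clipped at 0), the conventional model for
caliper measurement error; the paper-regime preset (`herceptin_like_spec`)
carries the fitted case-study values `f_c/f_h = 1.033`, `f_m/f_h = 1.289`,
`r_m = 1.1e−6`, `eff_c = 0.052`. Curves come from the expectation model, so
σ = 0 output lies exactly on the recursion and grid-search recovery of
on-grid truth is exact — that round trip is what the test suite verifies.
What the generator does *not* emulate: mouse-to-mouse heterogeneity (random
effects), tumour-volume-to-cell-count conversion error, and any stochastic
demographic noise in the measured arm (the real in-vivo series are means
over animals; per-animal fits would need the stochastic engine). Passing
recovery tests therefore demonstrate correctness of the fitting machinery,
not identifiability on real, noisy, heterogeneous data.

## Experiment drivers and scales

- **Tunneling** (`estimate_tunneling`): `N = 1000`, `M = 20,000`, 1000
  replicates, initial cancer 10% of N (the initial condition is not printed
  with the result it reproduces; 10% matches the package's other
  publication-scale runs and is exposed as configuration). A 3×-fit mutant
  tunnels in ~96.5% of replicates; a 1.5× mutant in ~0% — its selective
  sweep needs ≳ 2N ln N / s ≈ 38,000 divisions, more than the horizon.
- **Fixation-region scan** (`scan_fixation_regions`): classification per
  grid cell is the majority type among fixating replicates, `none` if no
  replicate fixates; 100 replicates per cell. The boundary ratio is the mean
  `f_c/f_m` midpoint between the last mutant-classified and first
  cancer-classified cell per `f_m` row (falling back to the edge against the
  unclassified region when no cancer cell exists). The desk scale used by
  the acceptance script is `N = 150` with `M = 2177`: `N` small enough that
  a mutant-free instant — necessary for exact cancer fixation under
  continuous mutant influx (quasi-stationary mutant count
  `≈ r_m N/(1 − f_m/f_c)`) — is reachable, `M` preserving the
  publication-scale division budget in selective-sweep units
  (`M ∝ N ln N`).
- **Minimum-fitness curve** (`min_fitness_curve`): `N = 100`, a single
  founding cancer cell, 1000 replicates; for each division budget `M` the
  smallest grid fitness whose ensemble-mean cancer count exceeds `0.5 N` at
  division `M`. The threshold applies to the ensemble mean (matching the
  averaged-simulation methodology of the related final-proportion scans);
  the single-run alternative would be stricter. The feasibility asymptote
  lands at 68–69 divisions, consistent with the infinite-fitness first-
  passage oracle `Σ_{k=1..50} 100/(100−k) ≈ 69.8`: a lineage gains at most
  one cell per division, so some minimum time is unavoidable.
- **Strategy comparison / treatment scans**: preset strategies (MTD,
  early MTD, dual, sustained, waning) with defaults `eff_c = 0.8`,
  `eff_m = 0.4`, `t_start = 5000`, `t_length = 5000`, `f_m = 1.6`,
  sustained scaling 1/5 (or 1/3 with length ×5 for the mutation-rate scans),
  waning half-life 5000 divisions. These defaults are reconstructions —
  the underlying study conditions are only partially printed — and every
  one is an explicit keyword argument. Escape is measured as the fraction
  of replicates whose mutant count reaches `0.5 N` within `M`.

## Numerical choices and degenerate inputs

Probabilities are formed from exact integer counts and double-precision
weights; the event distribution sums to 1 within 1e−12 by construction
(the no-change mass is the complement). `W = 0` with cells present (all
effective fitnesses zero, e.g. full-efficacy treatment after healthy
extinction) raises `DegenerateSelectionError` rather than silently freezing.
Zero total population is invalid. Efficacies outside [0, 1], non-positive
window lengths or half-lives, non-monotone observation times, negative
sizes and empty series are rejected at construction. Grid ties break
first-encountered; the min-fitness curve marks infeasible budgets with NaN
rather than a sentinel fitness.

## Known limitations

- Under always-active mutation, exact cancer fixation (`N_c = N`) is
  effectively unreachable for large `N r_m` because mutants are
  continuously regenerated; cancer-classified regions in fixation scans
  therefore only exist at moderate population sizes. An alternative
  "emergence-only" mechanic (mutation only seeds the clone while no mutant
  exists) restores large-N cancer fixation but measurably lowers the
  tunneling probability (~93% vs ~96.5% at the publication setting); this
  package implements the always-active form, which matches the printed
  mutation probability and the tunneling results. At the desk scale above,
  the measured boundary ratio is ~0.8, higher than the ~0.6 of the
  publication-scale figure it emulates — the time-limited sweep regime that
  produces 0.6 at `N = 1000` cannot be fully preserved once `N` is small
  enough for cancer fixation to be observable, because the mutant influx
  per sweep scales with `r_m N ln N` and `r_m` is fixed.
- One driver clone only: the natural extension to mutant types `m₂…mₙ` is
  out of scope, as are spatial structure, continuous-time (Gillespie)
  variants, fitness costs of resistance, toxicity constraints and adaptive
  (feedback-controlled) scheduling.
- The calibration provides point estimates with an RMSE surface, not
  uncertainty quantification; likelihood-based or ABC inference is a
  documented non-goal.
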