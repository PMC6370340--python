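# Methods

## The system and the model

`helifret` models single-molecule FRET measurements of DNA unwinding by a
hexameric, DnaB-family replicative helicase (G40P of phage SPP1) on a 40-bp
fork substrate.  A donor/acceptor pair reports the number of unwound base
pairs: the apparent FRET efficiency falls from ~0.95 (intact duplex) to a
donor-leakage floor of 0.11 (fully unwound), and completion releases the
donor strand, collapsing total fluorescence.

The kinetic core is a continuous-time Markov chain over the number of
unwound base pairs *j* ∈ {0, …, L}:

* **Initiation.**  The helicase loads as a preassembled hexamer; the delay
  from injection is exponential with rate `k_on_init · [hexamer]`, so the
  cohort-mean initiation time is inversely proportional to protein
  concentration.
* **Stepping.**  Forward steps advance one base pair at rate
  `k_fwd(j) = k_step_AT · f_ATP · m(j+1) · temperature_multiplier`, where
  `f_ATP = [ATP]/(K_M,app + [ATP])` is Michaelis–Menten loading saturation
  with `K_M,app = K_M (1 + [ADP]/K_I)` (ADP purely competitive), and
  `m = 1` for an AT base pair or `1/gc_factor` for GC (melting-limited
  step; GC base pairs are thermodynamic barriers).
* **Slippage.**  A nucleotide-poor ring loses grip on the tracking strand:
  at any *j* > 0 a slip hazard `k_slip0 · K_M/(K_M + [ATP])` resets *j* to 0
  (full rezipping; partial slips are not modeled — the measurement only
  bounds slips at ≥ 10 bp, and the FRET signal returns to the intact-duplex
  level).  Bound primase DnaG divides the hazard by
  `dnag_slip_suppression`.
* **ATPγS poisoning.**  Every forward step is preceded by a loading
  lottery: the incoming nucleotide is ATPγS with probability
  `x = ([ATPγS]/K_D,ATPγS) / ([ATP]/K_D,ATP + [ATPγS]/K_D,ATPγS)`; a
  poisoned subunit freezes the ring for an exponential dwell of mean
  `tau_poison` before loading is retried.  One bound ATPγS suffices to
  stall, which is what makes the stalled-trace fraction grow linearly at
  low mole fractions.

Trajectories end at full unwinding (strand release) or at a trace horizon
of 120 s (the movie length); incomplete traces are flagged.  One seeded
generator drives each trajectory, with per-trace seeds spawned
deterministically from a master seed.

## Default parameters (the standard study conditions)

| parameter | default | unit | rationale |
|---|---|---|---|
| `k_step_AT` | 76.4 | 1/s | 40 bp at the maximal unwinding rate 1.91 s⁻¹ |
| `K_M` | 87 | µM | measured Michaelis constant for ATP |
| `K_I` | 418.3 | µM | back-computed from the apparent K_M of 191 µM at 0.5 mM ADP |
| `gc_factor` | 5.5 | — | reproduces the ~79 ms single-GC stall at 1 mM ATP: 0.079 × 76.4 × (1000/1087) |
| `k_on_init` | 1/(6.6·60) | 1/(s·nM) | 6.6 s mean initiation at the standard 60 nM hexamer |
| `k_slip0` | 2.0 | 1/s | not directly measured; chosen once to give order-one slip counts per trace at sub-saturating ATP (≈0.1 at 1 mM rising to ≈1.4 at 100 µM) |
| `dnag_slip_suppression` | 2.5 | — | measured ≈2.5-fold reduction in slips per trace |
| `K_D_ATP`, `K_D_ATPgS` | 3.5, 1.4 | µM | measured by mant-ADP displacement |
| `tau_poison` | 0.44 | s | measured ATPγS stall lifetime, mix-independent |
| `p_offset` | 0.05 | — | baseline (ATPγS-independent) stall probability; the measured value is not printed, 0.05 is a plausible small rate |

The **strong-barrier scenario** used where a rare-completion 3GC cohort is
called for sets `gc_factor = 2000`.  The value was fixed a priori from the
forward-vs-slip competition algebra: at 1 mM ATP the forward rate at a GC
base pair (76.4 × 0.92 / 2000 ≈ 0.035 s⁻¹) then competes with the slip
hazard (0.16 s⁻¹) so that each GC is passed with probability ≈ 0.18 per
attempt, making full passage of three consecutive GC base pairs rare
within the 120 s horizon while each attempt still stalls detectably at
10, 11 or 12 bp.  With defaults (`gc_factor = 5.5`) GC stalls are ~80 ms
pauses and nearly all traces complete, which is the single-GC regime.

## Rendering

A calibration curve maps base pairs unwound to apparent FRET through
measured anchors (0, 0.95), (4, 0.73), (7, 0.61), (10, 0.48), (13, 0.24)
with a linear extension to the 0.11 floor at 16 bp (the knee position is
an implementation choice; the measurement only bounds the floor) and a
flat floor beyond.  Donor leakage is treated as embedded in the apparent
anchor values, so no separate leakage correction is applied.

Per-frame apparent FRET is the *exact* time-weighted average of the
calibration over the frame (piecewise-constant position integrated
analytically), so sub-frame steps blur realistically.  Channel counts are
`A = total·E + background`, `D = total·(1−E) + background` plus additive
Gaussian noise per channel (camera-dominated regime; Poisson shot noise
is second order at these count rates and is omitted — the analysis is
threshold-based and robust to either).  After strand release both
channels contain only background; the release frame carries the
partial-frame signal.

## Codified trace scoring

The original scoring was visual; the analysis module replaces it with
explicit rules, all exposed in `DetectionConfig`:

* FRET: `E = (A−bA) / ((A−bA) + (D−bD))`, clamped to [0, 1]; frames with
  non-positive total are invalid and break plateaus.
* Onset: first frame where the 3-frame running mean drops more than 3
  estimated noise s.d. below the pre-injection high-state mean and stays
  below for ≥ 3 frames (σ̂ floored at 0.01 so noiseless traces behave).
* Release: background-subtracted total below 3 noise s.d. for ≥ 2
  consecutive frames.
* Stalls: maximal runs of ≥ 5 consecutive valid frames within ±0.05 FRET
  of the run mean (the measured stall peaks are ±0.04 wide), at levels at
  least 0.05 inside the (floor, high-state) band.
* Slippage: hysteresis counting on a 150-ms box average — an excursion
  below 0.70 followed by an upward recrossing of 0.80.  The final
  successful descent never recrosses and is not counted.  Slips from
  fewer than ~5 unwound base pairs sit above the 0.70 threshold and are
  invisible by construction, as in the original threshold method.
* Outcomes: `complete` iff release follows an onset; `incomplete` iff
  onset without release; completion fractions use traces with activity as
  the denominator.

## Estimators

* **Gamma step size** — maximum-likelihood Gamma fit on raw unwinding
  times (the bin-free equivalent of a histogram fit);
  `step = n_bp / shape`.  Between-molecule rate heterogeneity broadens
  the distribution and inflates the step size, so it is an upper limit;
  the homogeneous simulator recovers ~1 bp while a 10-fold-dispersed
  cohort reads ~4 bp.  CIs by nonparametric bootstrap.
* **Exponential lifetimes** — MLE (the sample mean) with bootstrap CI.
* **Stall-level mixtures** — scikit-learn Gaussian mixtures, component
  count by BIC with an override to pin it; components whose means are
  closer than 0.02 FRET (half a measured peak width) are moment-matched
  and merged, since BIC on thousands of pooled levels happily splits a
  single slightly non-Gaussian peak into duplicates that carry no
  positional information.
* **Michaelis–Menten / Hill / competitive inhibition** — least squares
  with a deterministic multi-start grid; `K_M,app = K_M (1 + [I]/K_I)`
  inverts exactly for K_I.
* **Tight-binding titration** — the quadratic-root binding model
  `F = F0 + (ΔF_max/[L_tot])·[EL]`, with `[EL]` the smaller root of
  `EL² − (E_tot+L_tot+K_D)·EL + E_tot·L_tot = 0`, valid when enzyme and
  ligand are comparable to K_D.
* **Six-site poisoning model** — `alpha = 1 + [ATPγS]/K_D`,
  `K_M,app = alpha·K_M`, per-site ATP occupancy
  `f_bound = [ATP]/(K_M,app+[ATP])`.  The quantity `1 − f_bound⁶` counts
  every ring with a non-ATP site, including merely nucleotide-free sites
  that cause slippage rather than the long poisoned stalls and that are
  present without any ATPγS; the stall probability therefore uses the
  ATPγS-attributable excess `(1 − f⁶) − (1 − f₀⁶)` over the zero-ATPγS
  baseline, which vanishes correctly at zero ATPγS and is first-order
  (linear) in [ATPγS] below K_D.  The baseline stall rate enters as a
  fitted offset, combined as `p = p_offset + (1−p_offset)·p_poison`
  (keeps probabilities in [0, 1]); a clamped additive rule is available
  behind a flag since the original offset form is not printed.
* **Predicted stall positions** — walks the duplex in 1- or 2-bp
  increments from every loading phase; any step that would unwind a GC
  base pair marks the current position as a stall.  One GC run gives one
  level per entry point at step 1; step 2 adds phase ambiguity (2/3/4
  levels for 1/2/3 GCs), which is how the level counts discriminate the
  step size.

## Statistics

Fisher's exact test (two-sided, summing tables no more probable than
observed) is delegated to scipy; the test suite checks it against an
exhaustive hypergeometric enumeration on every 2×2 table with N ≤ 40.
Bootstrap intervals are seeded percentile intervals of the mean.

## What the synthetic data does and does not emulate

The generator reproduces: MM-saturated single-bp stepping with GC
barriers, full-reset slippage with the measured ATP dependence and DnaG
suppression, single-ATPγS ring freezing, initiation kinetics linear in
protein concentration, the measured FRET-vs-bp calibration, camera noise
and strand-release trace termination.  It does not emulate: photophysics
(blinking, photobleaching other than release), partial slips, enzyme
dissociation/rebinding (incomplete traces arise only from the horizon),
baseline drift, or day-to-day calibration shifts.  Passing tests
therefore demonstrate that the estimators recover the mechanism's
parameters from realistic traces, not that the mechanism is the only one
compatible with real data.

## Numerical choices and problem sizes

Exponential waits by inverse CDF from per-trajectory `numpy` generators
spawned from the master seed; nonlinear fits converge to 1e-8 relative
with multi-start; mixture fits use five k-means initializations at fixed
random state.  Cohort sizes in the analysis scripts and acceptance
script (300 traces for rendered GC cohorts, 2000–5000 trajectories for
distributional checks, 10⁶ draws for lottery enumeration) were chosen so
Monte-Carlo error sits well inside the assertion tolerances.

## Known limitations

* The slip-count ratio without/with DnaG equals the hazard ratio exactly
  only per unit active time; per-trace counts include a
  survival-probability nonlinearity, so the per-trace ratio runs a few
  percent above the configured factor.
* Unwinding times measured trace-side (onset to release) are one frame
  quantized and censored at the horizon; the Gamma fit does not correct
  for censoring (flagged, not corrected).
* The steady-state six-site occupancy formula saturates in [ATPγS] well
  below the mixes where the measured stalled fraction is still linear;
  the per-loading-event lottery in the simulator is the mechanistically
  faithful description and does reproduce the linearity.
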