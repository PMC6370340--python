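# helifret

Simulation and analysis of single-molecule FRET measurements of DNA
unwinding by a hexameric replicative helicase (G40P, DnaB family).

A ring-shaped helicase encircling the tracking strand of a fork substrate
unwinds the duplex while a donor/acceptor FRET pair reports the number of
unwound base pairs: apparent FRET falls from ~0.95 (intact 40-bp duplex)
to a 0.11 donor-leakage floor, and completion releases the donor strand.
Three mechanistic questions drive the analysis:

1. **Step size.**  Does the ring unwind 1 bp per ATP (sequential,
   staircase hydrolysis) or more (concerted)?  GC base pairs inserted at
   positions 11–13 act as barriers; a 1-bp stepper stalls at one FRET
   level per GC base pair, while a 2-bp stepper shows extra levels from
   the phase of the first step.
2. **Slippage.**  A nucleotide-poor ring loses grip and slips backwards,
   rezipping the fork; the slip hazard rises as ATP falls and is
   suppressed ~2.5-fold by the primase DnaG.
3. **Hydrolysis coordination.**  A single bound ATPγS freezes the ring
   for ~0.44 s, so the stalled-trace fraction grows linearly in the
   ATPγS mole fraction — the signature of sequential hydrolysis.

The package provides, as importable modules under `src/helifret/`:

* `kinetics` — continuous-time Markov simulation of stepping
  (Michaelis–Menten ATP loading, `K_M = 87` µM; competitive ADP
  inhibition; GC melting slowdown), full-reset slippage, DnaG
  suppression and ATPγS poisoning;
* `render` — FRET-vs-bp calibration and camera-realistic donor/acceptor
  trace rendering (exact within-frame averaging, Gaussian noise, strand
  release);
* `events` — deterministic trace scoring: apparent FRET, unwinding
  onset/release, ≥5-frame stall plateaus, hysteresis slippage counting
  (0.70/0.80 thresholds on a 150-ms box average);
* `fits` — Gamma kinetic step size, exponential lifetimes, stall-level
  Gaussian mixtures, Michaelis–Menten/Hill/competitive-inhibition fits,
  quadratic tight-binding titration, the six-site ATPγS poisoning model,
  and predicted GC stall positions for 1- vs 2-bp stepping;
* `stats` / `pipeline` / `cli` — Fisher's exact test, bootstrap CIs, and
  the simulate → render → analyze → summarize pipeline (`helifret`
  console command with `simulate`, `analyze`, `fit`, `report`, `run`).

The numbered scripts under `analysis/` run the main analyses and write
their tables to `results/`.

## Worked example

```python
import numpy as np
from helifret import (GC3, KineticParams, ReactionConditions,
                      analyze_trace, fit_stall_levels, render_trace,
                      simulate_cohort)

params = KineticParams(gc_factor=2000.0)        # strong 3-GC barrier
cohort = simulate_cohort(GC3, ReactionConditions(), params, 300, seed=11)
levels = []
for i, traj in enumerate(cohort):
    trace = render_trace(traj, frame_interval=0.1, seed=9000 + i)
    levels += [s.level for s in analyze_trace(trace).stalls]
fit = fit_stall_levels(levels)
print(fit.n_components, np.round(fit.means, 3))
```

prints

```
3 [0.48  0.4   0.319]
```

three stall levels, the calibrated FRET values for 10, 11 and 12 base
pairs unwound — one stall in front of each GC base pair, i.e. the ring
unwinds single base pairs.  Running `python analysis/03_slippage.py`
prints the slippage series (slips per trace rising from 0.10 at 1 mM ATP
to 1.38 at 100 µM, cut ~2.5-fold by DnaG) and the completion contrast on
the strong barrier (25/300 vs 79/300 complete without/with DnaG, Fisher
p = 5.6e-09).

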