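"""Kinetic step size of the helicase from unwinding-time distributions.

Simulates all-AT 40-bp fork cohorts at saturating ATP, checks that the
full unwinding time follows the closed-form Erlang distribution of 40
sequential 1-bp steps, and shows what the Gamma-fit step-size estimator
reports: ~1 bp on homogeneous cohorts, inflated to ~4 bp when
between-molecule rate heterogeneity broadens the distribution (why the
estimate is an upper limit).

Writes results/step_size.json.
"""

import json
from pathlib import Path

import numpy as np
from scipy import stats as sps

from helifret import (AT40, KineticParams, ReactionConditions,
                      fit_gamma_step_size, simulate_cohort)

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    cond = ReactionConditions(atp=1000.0)
    params = KineticParams(k_slip0=0.0)
    rate = params.k_step_AT * cond.atp / (params.K_M + cond.atp)

    cohort = simulate_cohort(AT40, cond, params, 5000, seed=SEED)
    times = np.array([t.unwinding_time for t in cohort])
    ks_stat, ks_p = sps.kstest(times, sps.gamma(a=40, scale=1.0 / rate).cdf)
    fit = fit_gamma_step_size(times, n_bp=40, n_boot=100, seed=SEED)

    rng = np.random.default_rng(SEED)
    mol_rates = rng.gamma(shape=10, scale=rate / 10, size=5000)
    broadened = rng.gamma(shape=40, scale=1.0, size=5000) / mol_rates
    fit_het = fit_gamma_step_size(broadened, n_bp=40, n_boot=100, seed=SEED)

    out = {
        "mean_unwinding_time_s": float(np.mean(times)),
        "erlang_mean_s": 40.0 / rate,
        "ks_p_vs_erlang40": ks_p,
        "step_size_homogeneous_bp": fit.kinetic_step_size,
        "step_size_homogeneous_ci_bp": list(fit.step_size_ci),
        "step_size_heterogeneous_bp": fit_het.kinetic_step_size,
        "n_traces": len(times),
    }
    OUT.mkdir(exist_ok=True)
    with open(OUT / "step_size.json", "w") as fh:
        json.dump(out, fh, indent=1)

    print(f"mean unwinding time {np.mean(times):.3f} s "
          f"(Erlang prediction {40 / rate:.3f} s), KS p = {ks_p:.3f}")
    print(f"Gamma step size, homogeneous cohort: "
          f"{fit.kinetic_step_size:.2f} bp "
          f"[{fit.step_size_ci[0]:.2f}, {fit.step_size_ci[1]:.2f}]")
    print(f"Gamma step size with molecule-to-molecule rate spread: "
          f"{fit_het.kinetic_step_size:.2f} bp -> heterogeneity inflates the "
          "apparent step; the estimate is an upper limit")


if __name__ == "__main__":
    main()
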