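"""Cohort statistics: Fisher's exact test and bootstrap intervals."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

__all__ = ["fisher_exact", "bootstrap_counts", "BootstrapResult", "CohortSummary"]


def fisher_exact(table) -> float:
    """Two-sided Fisher's exact p-value for a 2x2 contingency table.

    Exact hypergeometric test with the standard two-sided convention:
    the p-value sums the probabilities of all tables (at fixed margins)
    no more probable than the observed one.  A zero margin makes the
    table degenerate; p = 1 is returned with a warning.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or np.any(t != np.floor(t)):
        raise ValueError("table entries must be non-negative integers")
    t = t.astype(int)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        warnings.warn("zero margin: association is undefined, p = 1", stacklevel=2)
        return 1.0
    return float(sps.fisher_exact(t, alternative="two-sided")[1])


@dataclass(frozen=True)
class BootstrapResult:
    mean: float
    ci_low: float
    ci_high: float
    n_boot: int
    ci_level: float


def bootstrap_counts(values: Sequence[float], n_boot: int = 1000, seed: int = 0,
                     ci_level: float = 0.95) -> BootstrapResult:
    """Seeded percentile-bootstrap interval for the mean of ``values``."""
    x = np.asarray(values, dtype=float)
    if len(x) == 0:
        raise ValueError("cannot bootstrap an empty sample")
    if n_boot < 200:
        raise ValueError("n_boot must be at least 200")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(x), size=(n_boot, len(x)))
    means = x[idx].mean(axis=1)
    q = 100 * np.array([(1 - ci_level) / 2, 1 - (1 - ci_level) / 2])
    lo, hi = np.percentile(means, q)
    return BootstrapResult(mean=float(np.mean(x)), ci_low=float(lo),
                           ci_high=float(hi), n_boot=n_boot, ci_level=ci_level)


@dataclass
class CohortSummary:
    """Aggregate statistics of one analyzed cohort."""

    n_traces: int
    n_active: int                    # traces with an unwinding onset
    n_complete: int
    complete_fraction: float         # n_complete / n_active (active-trace denominator)
    mean_slip_count: float
    slip_ci: Tuple[float, float]
    mean_t_init: Optional[float]
    mean_t_unw: Optional[float]
    stall_levels: Tuple[float, ...] = ()
    stall_mixture: Optional[dict] = None

    def __post_init__(self) -> None:
        if self.n_complete > self.n_active or self.n_active > self.n_traces:
            raise ValueError("inconsistent counts")
        if not 0.0 <= self.complete_fraction <= 1.0:
            raise ValueError("complete_fraction outside [0, 1]")

    def to_dict(self) -> dict:
        return {
            "n_traces": self.n_traces,
            "n_active": self.n_active,
            "n_complete": self.n_complete,
            "complete_fraction": self.complete_fraction,
            "mean_slip_count": self.mean_slip_count,
            "slip_ci": list(self.slip_ci),
            "mean_t_init": self.mean_t_init,
            "mean_t_unw": self.mean_t_unw,
            "n_stall_levels": len(self.stall_levels),
            "stall_mixture": self.stall_mixture,
        }
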