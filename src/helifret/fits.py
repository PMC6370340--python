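"""Model fitting and closed-form enzymology.

Covers the estimation stack of the unwinding analysis: Gamma fits of
unwinding-time distributions (kinetic step size), exponential stall
lifetimes, Gaussian mixtures of stall FRET levels, Michaelis-Menten /
Hill ATP titrations with competitive ADP inhibition, the quadratic
tight-binding titration for nucleotide affinity, the single-ATPgS
poisoning model, and the combinatorics of expected GC-induced stall
positions for 1-bp vs 2-bp stepping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats
from sklearn.mixture import GaussianMixture

from .render import CalibrationCurve
from .substrate import SubstrateSpec

__all__ = [
    "GammaFitResult", "ExpFitResult", "GaussianMixtureResult", "MMFitResult",
    "BindingFitResult", "PoisonModelResult",
    "fit_gamma_step_size", "fit_exponential_lifetime", "fit_stall_levels",
    "fit_michaelis_menten", "fit_hill", "competitive_km", "fit_ki",
    "binding_model", "fit_binding_titration",
    "poison_stall_probability", "fit_poison_model", "predict_stall_positions",
]


# ---------------------------------------------------------------------------
# result containers

@dataclass(frozen=True)
class GammaFitResult:
    n_steps: float                   # Gamma shape = number of rate-limiting steps
    rate: float                      # per-step rate (1/s)
    kinetic_step_size: float         # bp per rate-limiting step = n_bp / n_steps
    n_steps_ci: Tuple[float, float]
    rate_ci: Tuple[float, float]
    step_size_ci: Tuple[float, float]
    n_bp: int
    n_samples: int


@dataclass(frozen=True)
class ExpFitResult:
    tau: float                       # mean lifetime (s); MLE = sample mean
    ci: Tuple[float, float]
    n_samples: int


@dataclass(frozen=True)
class GaussianMixtureResult:
    n_components: int
    means: Tuple[float, ...]         # sorted descending (FRET units)
    sigmas: Tuple[float, ...]
    weights: Tuple[float, ...]
    bic: float


@dataclass(frozen=True)
class MMFitResult:
    K_M: float                       # µM (K_half for the Hill variant)
    k_max: float                     # 1/s
    K_M_se: float
    k_max_se: float
    hill_n: float = 1.0
    hill_n_se: float = 0.0
    K_I: Optional[float] = None      # µM, when fitted from inhibition data


@dataclass(frozen=True)
class BindingFitResult:
    F0: float                        # unbound fluorescence (a.u.)
    dFmax: float                     # amplitude (a.u.)
    K_D: float                       # µM
    F0_se: float
    dFmax_se: float
    K_D_se: float
    E_tot: float


@dataclass(frozen=True)
class PoisonModelResult:
    alpha: float                     # K_M inflation factor 1 + [ATPgS]/K_D
    K_M_app: float                   # µM
    f_bound: float                   # probability a site carries ATP
    p_stall: float
    p_offset: float


# ---------------------------------------------------------------------------
# dwell-time fits

def fit_gamma_step_size(unwind_times: Sequence[float], n_bp: int,
                        n_boot: int = 200, seed: int = 0,
                        ci_level: float = 0.95) -> GammaFitResult:
    """Kinetic step size from the unwinding-time distribution.

    Full unwinding through ``n`` identical rate-limiting steps of rate
    ``k`` gives Gamma(n, k)-distributed total times; the maximum-
    likelihood Gamma shape therefore estimates the number of steps and
    ``n_bp / shape`` the base pairs unwound per step.  The fit is done
    on the raw times (the bin-free equivalent of a histogram fit).
    Between-molecule rate heterogeneity broadens the distribution and
    deflates the fitted shape, so the step size is an upper limit.
    Confidence intervals are nonparametric-bootstrap percentiles.
    """
    t = np.asarray(unwind_times, dtype=float)
    if len(t) < 20:
        raise ValueError(f"need at least 20 unwinding times, got {len(t)}")
    if np.any(t <= 0) or not np.all(np.isfinite(t)):
        raise ValueError("unwinding times must be positive and finite")

    def mle(x):
        shape, _, scale = stats.gamma.fit(x, floc=0)
        return shape, 1.0 / scale

    shape, rate = mle(t)
    rng = np.random.default_rng(seed)
    boots = np.array([mle(rng.choice(t, size=len(t), replace=True))
                      for _ in range(n_boot)])
    q = 100 * np.array([(1 - ci_level) / 2, 1 - (1 - ci_level) / 2])
    s_lo, s_hi = np.percentile(boots[:, 0], q)
    r_lo, r_hi = np.percentile(boots[:, 1], q)
    return GammaFitResult(
        n_steps=shape, rate=rate, kinetic_step_size=n_bp / shape,
        n_steps_ci=(s_lo, s_hi), rate_ci=(r_lo, r_hi),
        step_size_ci=(n_bp / s_hi, n_bp / s_lo),
        n_bp=n_bp, n_samples=len(t),
    )


def fit_exponential_lifetime(lifetimes: Sequence[float], n_boot: int = 500,
                             seed: int = 0, ci_level: float = 0.95) -> ExpFitResult:
    """Exponential MLE of a lifetime distribution: tau = sample mean,
    with a bootstrap percentile confidence interval."""
    t = np.asarray(lifetimes, dtype=float)
    if len(t) == 0:
        raise ValueError("empty lifetime sample")
    if len(t) < 10:
        raise ValueError(f"need at least 10 lifetimes, got {len(t)}")
    if np.any(t < 0):
        raise ValueError("lifetimes must be non-negative")
    tau = float(np.mean(t))
    rng = np.random.default_rng(seed)
    boots = np.array([np.mean(rng.choice(t, size=len(t), replace=True))
                      for _ in range(n_boot)])
    q = 100 * np.array([(1 - ci_level) / 2, 1 - (1 - ci_level) / 2])
    lo, hi = np.percentile(boots, q)
    return ExpFitResult(tau=tau, ci=(float(lo), float(hi)), n_samples=len(t))


def _merge_close_components(means, sigmas, weights, min_separation):
    """Moment-matched merge of components whose means nearly coincide.

    With thousands of pooled stall levels BIC will happily split a
    single, slightly non-Gaussian peak into two components with almost
    identical means; such splits carry no positional information.
    Components closer than ``min_separation`` (FRET units) are merged.
    """
    means = list(means)
    sigmas = list(sigmas)
    weights = list(weights)
    merged = True
    while merged and len(means) > 1:
        merged = False
        for i in range(len(means) - 1):
            if abs(means[i] - means[i + 1]) < min_separation:
                w = weights[i] + weights[i + 1]
                m = (weights[i] * means[i] + weights[i + 1] * means[i + 1]) / w
                second = (weights[i] * (sigmas[i] ** 2 + means[i] ** 2)
                          + weights[i + 1] * (sigmas[i + 1] ** 2 + means[i + 1] ** 2)) / w
                means[i], sigmas[i], weights[i] = m, np.sqrt(max(second - m * m, 0.0)), w
                del means[i + 1], sigmas[i + 1], weights[i + 1]
                merged = True
                break
    return means, sigmas, weights


def fit_stall_levels(levels: Sequence[float], max_components: int = 4,
                     n_components: Optional[int] = None,
                     seed: int = 0, min_separation: float = 0.02,
                     ) -> GaussianMixtureResult:
    """Gaussian-mixture fit of stall FRET levels.

    Fits mixtures with 1..``max_components`` components and selects by
    the Bayesian information criterion, unless ``n_components`` pins
    the count (the substrate design fixes the expected number of GC-
    induced levels at 1, 2 or 3).  Components whose means sit closer
    than ``min_separation`` (default 0.02, half the ~0.04 width of a
    measured stall peak) are merged: they are not resolvable stall
    positions.
    """
    x = np.asarray(levels, dtype=float).reshape(-1, 1)
    if len(x) < 30:
        raise ValueError(f"need at least 30 stall levels, got {len(x)}")
    candidates = ([n_components] if n_components is not None
                  else list(range(1, max_components + 1)))
    best = None
    for k in candidates:
        if len(x) < 3 * k:
            raise ValueError(f"too few samples ({len(x)}) for {k} components")
        gm = GaussianMixture(n_components=k, n_init=5, random_state=seed,
                             covariance_type="full", reg_covar=1e-6).fit(x)
        bic = gm.bic(x)
        if best is None or bic < best[0]:
            best = (bic, k, gm)
    bic, k, gm = best
    order = np.argsort(-gm.means_.ravel())
    means = gm.means_.ravel()[order]
    sigmas = np.sqrt(gm.covariances_.reshape(k)[order])
    weights = gm.weights_[order] / gm.weights_.sum()
    means, sigmas, weights = _merge_close_components(means, sigmas, weights,
                                                     min_separation)
    return GaussianMixtureResult(
        n_components=len(means),
        means=tuple(float(m) for m in means),
        sigmas=tuple(float(s) for s in sigmas),
        weights=tuple(float(w) for w in weights),
        bic=float(bic),
    )


# ---------------------------------------------------------------------------
# ATP titrations

def _mm_model(s, k_max, km):
    return k_max * s / (km + s)


def _hill_model(s, k_max, khalf, n):
    sn = np.power(s, n)
    return k_max * sn / (np.power(khalf, n) + sn)


def _multistart_curve_fit(model, x, y, starts, bounds):
    best = None
    for p0 in starts:
        try:
            popt, pcov = optimize.curve_fit(model, x, y, p0=p0, bounds=bounds,
                                            maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        ssr = float(np.sum((model(x, *popt) - y) ** 2))
        if best is None or ssr < best[0] - 1e-12:
            best = (ssr, popt, pcov)
    if best is None:
        raise RuntimeError("all fit starts failed to converge")
    return best[1], best[2]


def fit_michaelis_menten(atp: Sequence[float], rates: Sequence[float]) -> MMFitResult:
    """Least-squares Michaelis-Menten fit ``v = k_max [S]/(K_M + [S])``."""
    s = np.asarray(atp, dtype=float)
    v = np.asarray(rates, dtype=float)
    if len(np.unique(s)) < 4:
        raise ValueError("need at least 4 distinct concentrations spanning K_M")
    k0 = max(float(np.max(v)), 1e-9)
    starts = [(k0, km0) for km0 in (np.median(s), np.min(s[s > 0]), np.max(s))]
    popt, pcov = _multistart_curve_fit(_mm_model, s, v, starts,
                                       bounds=([0, 0], [np.inf, np.inf]))
    se = np.sqrt(np.diag(pcov))
    return MMFitResult(K_M=float(popt[1]), k_max=float(popt[0]),
                       K_M_se=float(se[1]), k_max_se=float(se[0]))


def fit_hill(atp: Sequence[float], rates: Sequence[float]) -> MMFitResult:
    """Hill fit ``v = k_max [S]^n/(K_half^n + [S]^n)`` (MM with the
    exponent free; n = 1 recovers Michaelis-Menten exactly)."""
    s = np.asarray(atp, dtype=float)
    v = np.asarray(rates, dtype=float)
    if len(np.unique(s)) < 4:
        raise ValueError("need at least 4 distinct concentrations spanning K_half")
    k0 = max(float(np.max(v)), 1e-9)
    starts = [(k0, km0, n0)
              for km0 in (np.median(s), np.max(s) / 10)
              for n0 in (0.5, 1.0, 2.0)]
    popt, pcov = _multistart_curve_fit(_hill_model, s, v, starts,
                                       bounds=([0, 0, 0.1], [np.inf, np.inf, 10]))
    se = np.sqrt(np.diag(pcov))
    return MMFitResult(K_M=float(popt[1]), k_max=float(popt[0]),
                       K_M_se=float(se[1]), k_max_se=float(se[0]),
                       hill_n=float(popt[2]), hill_n_se=float(se[2]))


def competitive_km(K_M: float, K_I: float, inhibitor: float) -> float:
    """Apparent Michaelis constant under competitive inhibition:
    ``K_M_app = K_M (1 + [I]/K_I)``."""
    if K_M <= 0 or K_I <= 0 or inhibitor < 0:
        raise ValueError("K_M and K_I must be positive, inhibitor non-negative")
    return K_M * (1.0 + inhibitor / K_I)


def fit_ki(K_M: float, K_M_app: float, inhibitor: float) -> float:
    """Invert the competitive-inhibition relation for ``K_I``."""
    if K_M <= 0 or inhibitor <= 0:
        raise ValueError("K_M and inhibitor must be positive")
    if K_M_app <= K_M:
        raise ValueError("K_M_app <= K_M: data show no competitive inhibition")
    return inhibitor / (K_M_app / K_M - 1.0)


# ---------------------------------------------------------------------------
# quadratic tight-binding titration

def binding_model(L_tot, F0, dFmax, K_D, E_tot):
    """Fluorescence of a tight-binding titration.

    ``F = F0 + (dFmax/[L_tot]) * EL`` where ``EL`` is the equilibrium
    complex concentration, the smaller root of
    ``EL^2 - (E_tot + L_tot + K_D) EL + E_tot L_tot = 0``.  Because the
    complex is resolved exactly (no free-ligand approximation) the form
    is valid when enzyme and ligand concentrations are comparable to
    ``K_D``.  In the K_D -> infinity limit no complex forms and
    ``F -> F0``.
    """
    L = np.asarray(L_tot, dtype=float)
    half = (E_tot + L + K_D) / 2.0
    el = half - np.sqrt(np.maximum(half ** 2 - E_tot * L, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(L > 0, el / L, E_tot / (E_tot + K_D))
    return F0 + dFmax * frac


def fit_binding_titration(ligand: Sequence[float], fluorescence: Sequence[float],
                          E_tot: float) -> BindingFitResult:
    """Fit ``(F0, dFmax, K_D)`` of the quadratic tight-binding model."""
    L = np.asarray(ligand, dtype=float)
    F = np.asarray(fluorescence, dtype=float)
    if len(L) < 6:
        raise ValueError("need at least 6 titration points")
    if E_tot <= 0:
        raise ValueError("E_tot must be positive")
    dF0 = F[np.argmax(L)] - F[np.argmin(L)]
    if np.corrcoef(L, F)[0, 1] * np.sign(dF0 if dF0 != 0 else 1) < 0:
        warnings.warn("titration curve is grossly non-monotone", stacklevel=2)

    def model(l, f0, df, kd):
        return binding_model(l, f0, df, kd, E_tot)

    starts = [(float(F[np.argmax(L)]), float(dF0 if dF0 != 0 else np.ptp(F)), kd0)
              for kd0 in (0.1, 1.0, 10.0, float(np.median(L[L > 0]) if np.any(L > 0) else 1.0))]
    popt, pcov = _multistart_curve_fit(
        model, L, F, starts,
        bounds=([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, np.inf]))
    se = np.sqrt(np.diag(pcov))
    if not np.all(np.isfinite(se)):
        raise RuntimeError("singular binding fit: parameters not identifiable")
    return BindingFitResult(F0=float(popt[0]), dFmax=float(popt[1]),
                            K_D=float(popt[2]), F0_se=float(se[0]),
                            dFmax_se=float(se[1]), K_D_se=float(se[2]),
                            E_tot=E_tot)


# ---------------------------------------------------------------------------
# ATPgS poisoning

def poison_stall_probability(atp: float, atpgs: float, K_M: float,
                             K_D_atpgs: float, p_offset: float = 0.0,
                             rule: str = "complement") -> PoisonModelResult:
    """Probability that a hexamer is stalled by bound ATPgS.

    ATPgS acts as a competitive, non-hydrolysable inhibitor: it
    inflates the apparent Michaelis constant by
    ``alpha = 1 + [ATPgS]/K_D_ATPgS``, so the per-site ATP occupancy is
    ``f_bound = [ATP]/(alpha K_M + [ATP])`` and all six sites carry ATP
    with probability ``f_bound^6``.  The ATPgS-attributable poisoning
    probability is the excess of ``1 - f_bound^6`` over its value
    without ATPgS (sites can be nucleotide-free even then, which causes
    slippage, not the long poisoned stalls), so it vanishes at zero
    ATPgS.  Baseline (ATPgS-independent) stalls enter through
    ``p_offset``; the default combination
    ``p = p_offset + (1 - p_offset) * p_poison`` keeps the probability
    in [0, 1], ``rule="additive"`` clamps the plain sum.
    """
    if atp < 0 or atpgs < 0:
        raise ValueError("concentrations must be non-negative")
    if K_M <= 0 or K_D_atpgs <= 0:
        raise ValueError("K_M and K_D must be positive")
    if not 0 <= p_offset <= 1:
        raise ValueError("p_offset must lie in [0, 1]")
    alpha = 1.0 + atpgs / K_D_atpgs
    km_app = alpha * K_M
    if atp == 0.0 and atpgs == 0.0:
        warnings.warn("no nucleotide present: f_bound = 0", stacklevel=2)
    f_bound = atp / (km_app + atp) if atp > 0 else 0.0
    # 1 - f^6 also counts sites that are merely nucleotide-free (it is
    # nonzero without any ATPgS); only the ATPgS-attributable excess over
    # the zero-ATPgS baseline produces the long poisoned stalls
    f_baseline = atp / (K_M + atp) if atp > 0 else 0.0
    p_poison = max((1.0 - f_bound ** 6) - (1.0 - f_baseline ** 6), 0.0)
    if rule == "complement":
        p_stall = p_offset + (1.0 - p_offset) * p_poison
    elif rule == "additive":
        p_stall = min(p_offset + p_poison, 1.0)
    else:
        raise ValueError(f"unknown combination rule {rule!r}")
    return PoisonModelResult(alpha=alpha, K_M_app=km_app, f_bound=f_bound,
                             p_stall=p_stall, p_offset=p_offset)


def fit_poison_model(atpgs_fractions: Sequence[float],
                     stall_fractions: Sequence[float],
                     K_M: float, K_D: float, total_nucleotide: float = 1000.0,
                     rule: str = "complement",
                     fit_kd: bool = False):
    """Fit the baseline stall probability (and optionally K_D) of the
    single-ATPgS poisoning model to observed stall fractions.

    ``atpgs_fractions`` are mole fractions of ATPgS at constant total
    nucleotide.  Returns ``(PoisonModelResult at the first mixture,
    fitted p_offset, p_offset_se[, fitted K_D])``.
    """
    x = np.asarray(atpgs_fractions, dtype=float)
    y = np.asarray(stall_fractions, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 mixture points")
    if np.all(y == 0):
        raise ValueError("all stall fractions are zero: nothing to fit")

    def model(frac, p_off, kd):
        return np.array([
            poison_stall_probability((1 - f) * total_nucleotide,
                                     f * total_nucleotide,
                                     K_M, kd, p_off, rule=rule).p_stall
            for f in np.atleast_1d(frac)
        ])

    if fit_kd:
        popt, pcov = _multistart_curve_fit(
            model, x, y, [(0.05, K_D), (0.2, K_D * 3), (0.0, K_D / 3)],
            bounds=([0.0, 1e-6], [1.0, np.inf]))
        p_off, kd = float(popt[0]), float(popt[1])
        se = np.sqrt(np.diag(pcov))
        res = poison_stall_probability((1 - x[0]) * total_nucleotide,
                                       x[0] * total_nucleotide,
                                       K_M, kd, p_off, rule=rule)
        return res, p_off, float(se[0]), kd

    def model_fixed(frac, p_off):
        return model(frac, p_off, K_D)

    popt, pcov = _multistart_curve_fit(model_fixed, x, y,
                                       [(0.05,), (0.3,), (0.0,)],
                                       bounds=([0.0], [1.0]))
    p_off = float(popt[0])
    se = float(np.sqrt(pcov[0, 0]))
    res = poison_stall_probability((1 - x[0]) * total_nucleotide,
                                   x[0] * total_nucleotide,
                                   K_M, K_D, p_off, rule=rule)
    return res, p_off, se


# ---------------------------------------------------------------------------
# expected GC-induced stall positions

def predict_stall_positions(substrate: SubstrateSpec, step_size: int,
                            calibration: Optional[CalibrationCurve] = None,
                            ) -> List[Tuple[int, float]]:
    """Expected GC-induced stall positions and FRET levels for a given step size.

    Walks the duplex from every loading phase (``step_size`` phases) in
    increments of ``step_size`` bp; whenever the next step would unwind
    at least one GC base pair, the current position is a potential
    stall.  The union over phases is returned as sorted
    ``(bp_unwound, apparent_FRET)`` pairs.  A 1-bp stepper stalls at one
    position per GC entry point; a 2-bp stepper's stall positions
    depend on the phase of the first step, yielding more distinct
    levels than GC base pairs.
    """
    if step_size not in (1, 2):
        raise ValueError("step_size must be 1 or 2")
    calibration = calibration or CalibrationCurve()
    L = substrate.length
    positions = set()
    for phase in range(step_size):
        j = phase
        if phase and any(substrate.is_gc(b) for b in range(1, phase + 1)):
            # the phase-setting first step itself crosses a GC
            positions.add(0)
        while j < L:
            nxt = min(j + step_size, L)
            if any(substrate.is_gc(b) for b in range(j + 1, nxt + 1)):
                positions.add(j)
            j = nxt
    return [(p, float(calibration.fret_at(p))) for p in sorted(positions)]
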