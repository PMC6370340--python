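"""Continuous-time Markov simulation of hexameric-helicase DNA unwinding.

The mechanistic picture: the ring motor loads onto the fork as a
preassembled hexamer (initiation is a single bimolecular event, so the
initiation delay is exponential with rate ``k_on_init * [hexamer]``),
then unwinds the duplex in single base-pair steps.  Each step requires
an ATP-loading event (Michaelis-Menten saturation in [ATP], with ADP
acting as a purely competitive inhibitor) followed by melting of the
next base pair, which is ``gc_factor``-fold slower for a GC base pair
than for AT.  A nucleotide-free ring loses grip on the tracking strand
and can slip backwards, rezipping the duplex completely; the slip
hazard therefore falls with ATP occupancy and is divided by a constant
factor when the primase DnaG is bound.  ATPgS competes with ATP for
each loading event; a single bound ATPgS freezes the ring for an
exponential dwell before stepping resumes.

All times are seconds, nucleotide concentrations µM, protein nM.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from typing import List, Optional, Tuple

import numpy as np

from .substrate import SubstrateSpec

__all__ = [
    "KineticParams",
    "ReactionConditions",
    "Trajectory",
    "TrajectoryEvent",
    "NoInitiationError",
    "simulate_initiation_time",
    "simulate_trajectory",
    "simulate_cohort",
]


class NoInitiationError(ValueError):
    """Raised when no helicase is present, so loading can never occur."""


@dataclass(frozen=True)
class KineticParams:
    """Rate constants of the stepping/slippage/poisoning model.

    Defaults are the package's standard conditions, fixed from the
    measured enzymology of the G40P hexamer: a 40-bp duplex unwound at
    a maximal rate of 1.91 s⁻¹ gives ``k_step_AT = 76.4`` bp/s at
    saturating ATP; the ~79 ms GC stall at 1 mM ATP gives
    ``gc_factor ≈ 5.5``; ``K_M = 87`` µM; the competitive-inhibition
    constant for ADP back-computes to ``K_I ≈ 418`` µM from the
    apparent K_M at 0.5 mM ADP; initiation at 60 nM hexamer averages
    6.6 s.  ``k_slip0`` (basal slip hazard at zero ATP) is not directly
    measured; the default gives order-one slip counts per trace at
    sub-saturating ATP.
    """

    k_step_AT: float = 76.4          # per-bp melting-limited rate at saturating ATP (1/s)
    gc_factor: float = 5.5           # fold slowdown of the melting step for a GC bp
    K_M: float = 87.0                # Michaelis constant for ATP (µM)
    K_I: float = 418.3               # ADP competitive-inhibition constant (µM)
    k_on_init: float = 1.0 / (6.6 * 60.0)   # bimolecular loading rate (1/(s·nM))
    k_slip0: float = 2.0             # slippage hazard at zero ATP (1/s)
    dnag_slip_suppression: float = 2.5      # hazard divisor when DnaG is present
    K_D_ATP: float = 3.5             # ATP dissociation constant (µM)
    K_D_ATPgS: float = 1.4           # ATPgS dissociation constant (µM)
    tau_poison: float = 0.44         # mean ATPgS-induced stall duration (s)
    p_offset: float = 0.05           # ATPgS-independent stall probability

    def __post_init__(self) -> None:
        positive = {
            "k_step_AT": self.k_step_AT, "K_M": self.K_M, "K_I": self.K_I,
            "k_on_init": self.k_on_init, "dnag_slip_suppression": self.dnag_slip_suppression,
            "K_D_ATP": self.K_D_ATP, "K_D_ATPgS": self.K_D_ATPgS,
            "tau_poison": self.tau_poison,
        }
        for name, v in positive.items():
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be strictly positive and finite, got {v}")
        if not np.isfinite(self.k_slip0) or self.k_slip0 < 0:
            raise ValueError("k_slip0 must be non-negative and finite")
        if self.gc_factor < 1:
            raise ValueError("gc_factor must be >= 1")
        if self.dnag_slip_suppression < 1:
            raise ValueError("dnag_slip_suppression must be >= 1")
        if not 0.0 <= self.p_offset <= 1.0:
            raise ValueError("p_offset must lie in [0, 1]")

    def with_overrides(self, **kwargs) -> "KineticParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ReactionConditions:
    """Solution conditions of one unwinding experiment."""

    atp: float = 1000.0              # µM
    atpgs: float = 0.0               # µM
    adp: float = 0.0                 # µM
    hexamer: float = 60.0            # nM
    dnag_present: bool = False
    temperature_multiplier: float = 1.0   # scalar on melting rates

    def __post_init__(self) -> None:
        for name in ("atp", "atpgs", "adp", "hexamer"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be a non-negative finite concentration")
        if self.temperature_multiplier <= 0:
            raise ValueError("temperature_multiplier must be positive")

    def with_overrides(self, **kwargs) -> "ReactionConditions":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class TrajectoryEvent:
    time: float
    kind: str       # initiation | step | slip | poison_stall_start | poison_stall_end | completion
    position: int


@dataclass
class Trajectory:
    """Ground-truth unwinding trajectory, event times relative to injection."""

    times: np.ndarray                # event times (s), monotone increasing
    positions: np.ndarray            # bp unwound after each event
    event_log: List[TrajectoryEvent]
    t_init: float                    # injection -> first possible step (initiation event)
    completed: bool
    length: int                      # substrate length in bp
    horizon: float                   # trace duration (s)

    @property
    def slip_count(self) -> int:
        return sum(1 for e in self.event_log if e.kind == "slip")

    @property
    def poison_stall_count(self) -> int:
        return sum(1 for e in self.event_log if e.kind == "poison_stall_start")

    @property
    def completion_time(self) -> Optional[float]:
        """Time of full unwinding relative to injection, if reached."""
        for e in reversed(self.event_log):
            if e.kind == "completion":
                return e.time
        return None

    @property
    def unwinding_time(self) -> Optional[float]:
        """Initiation-to-completion duration (s), ``None`` if incomplete."""
        tc = self.completion_time
        return None if tc is None else tc - self.t_init

    def position_steps(self) -> Tuple[np.ndarray, np.ndarray]:
        """Breakpoints of the piecewise-constant position vs time.

        Returns ``(knots, values)`` where ``values[i]`` holds on
        ``[knots[i], knots[i+1])`` and the last value holds to the horizon.
        """
        knots = [0.0]
        values = [0]
        for e in self.event_log:
            if e.kind in ("step", "slip"):
                knots.append(e.time)
                values.append(e.position)
        return np.asarray(knots), np.asarray(values)

    def to_records(self) -> dict:
        return {
            "times": [float(t) for t in self.times],
            "positions": [int(p) for p in self.positions],
            "events": [
                {"time": float(e.time), "kind": e.kind, "position": int(e.position)}
                for e in self.event_log
            ],
            "t_init": float(self.t_init),
            "completed": bool(self.completed),
            "length": int(self.length),
            "horizon": float(self.horizon),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_records(), fh, indent=1)

    def to_tsv(self, path) -> None:
        """Flat export: one row per event, columns ``time_s`` and ``position_bp``."""
        with open(path, "w") as fh:
            fh.write("time_s\tposition_bp\n")
            for t, p in zip(self.times, self.positions):
                fh.write(f"{t:.6f}\t{int(p)}\n")


# ---------------------------------------------------------------------------
# propensities

def _atp_saturation(conditions: ReactionConditions, params: KineticParams) -> float:
    """ATP occupancy factor: MM saturation with ADP as competitive inhibitor."""
    km_app = params.K_M * (1.0 + conditions.adp / params.K_I)
    if conditions.atp == 0.0:
        return 0.0
    return conditions.atp / (km_app + conditions.atp)


def _slip_hazard(conditions: ReactionConditions, params: KineticParams) -> float:
    """Slippage hazard: basal rate scaled by the ATP-free probability of a site."""
    h = params.k_slip0 * params.K_M / (params.K_M + conditions.atp)
    if conditions.dnag_present:
        h /= params.dnag_slip_suppression
    return h


def _poison_fraction(conditions: ReactionConditions, params: KineticParams) -> float:
    """Probability an individual loading event picks ATPgS over ATP."""
    a = conditions.atp / params.K_D_ATP
    g = conditions.atpgs / params.K_D_ATPgS
    if a + g == 0.0:
        return 0.0
    return g / (a + g)


# ---------------------------------------------------------------------------
# simulation

def simulate_initiation_time(conditions: ReactionConditions, params: KineticParams,
                             seed: int) -> float:
    """Draw one initiation delay (injection to helicase loading), in seconds.

    The delay is exponential with rate ``k_on_init * [hexamer]``: loading of a
    preassembled hexamer is a single bimolecular event, so the cohort-mean
    initiation time is inversely proportional to the protein concentration.
    """
    if conditions.hexamer <= 0:
        raise NoInitiationError("no helicase present: initiation can never occur")
    rng = np.random.default_rng(seed)
    rate = params.k_on_init * conditions.hexamer
    return float(rng.exponential(1.0 / rate))


def _simulate_with_rng(substrate: SubstrateSpec, conditions: ReactionConditions,
                       params: KineticParams, rng: np.random.Generator,
                       horizon: float) -> Trajectory:
    if conditions.hexamer <= 0:
        raise NoInitiationError("no helicase present: initiation can never occur")
    L = substrate.length
    f_atp = _atp_saturation(conditions, params)
    h_slip = _slip_hazard(conditions, params)
    x_poison = _poison_fraction(conditions, params)
    temp = conditions.temperature_multiplier

    # per-position forward propensity toward base pair j+1
    melt = np.where(
        [substrate.is_gc(j + 1) for j in range(L)],
        1.0 / params.gc_factor, 1.0,
    )
    k_fwd = params.k_step_AT * f_atp * temp * melt
    if not np.all(np.isfinite(k_fwd)):
        raise ValueError("non-finite forward rates; check parameterization")

    events: List[TrajectoryEvent] = []
    t_init = rng.exponential(1.0 / (params.k_on_init * conditions.hexamer))
    t = t_init
    j = 0
    completed = False
    if t <= horizon:
        events.append(TrajectoryEvent(t, "initiation", 0))
        while True:
            kf = k_fwd[j] if j < L else 0.0
            ks = h_slip if j > 0 else 0.0
            total = kf + ks
            if total == 0.0:
                break
            t += rng.exponential(1.0 / total)
            if t > horizon:
                break
            if rng.random() < kf / total:
                # a loading event precedes the step; ATPgS freezes the ring
                while x_poison > 0.0 and rng.random() < x_poison:
                    events.append(TrajectoryEvent(t, "poison_stall_start", j))
                    t += rng.exponential(params.tau_poison)
                    if t > horizon:
                        break
                    events.append(TrajectoryEvent(t, "poison_stall_end", j))
                if t > horizon:
                    break
                j += 1
                events.append(TrajectoryEvent(t, "step", j))
                if j == L:
                    completed = True
                    events.append(TrajectoryEvent(t, "completion", j))
                    break
            else:
                j = 0
                events.append(TrajectoryEvent(t, "slip", 0))

    times = np.array([e.time for e in events])
    positions = np.array([e.position for e in events], dtype=int)
    return Trajectory(times=times, positions=positions, event_log=events,
                      t_init=t_init, completed=completed, length=L, horizon=horizon)


def simulate_trajectory(substrate: SubstrateSpec, conditions: ReactionConditions,
                        params: KineticParams, seed: int,
                        horizon: float = 120.0) -> Trajectory:
    """Simulate one unwinding trajectory (kinetic Monte Carlo).

    State is the number of unwound base pairs ``j``.  From ``j`` the
    competing hazards are a forward step (rate
    ``k_step_AT * f_ATP * m(j+1) * temperature_multiplier`` with ``m = 1``
    for AT and ``1/gc_factor`` for GC) and, for ``j > 0``, a slip that
    rezips the duplex to ``j = 0``.  Each forward step is preceded by a
    nucleotide-loading lottery; with probability
    ``(atpgs/K_D_ATPgS) / (atp/K_D_ATP + atpgs/K_D_ATPgS)`` the loaded
    nucleotide is ATPgS and the ring freezes for an exponential dwell of
    mean ``tau_poison`` before loading is retried.  The trajectory ends
    at full unwinding (strand release) or at the time ``horizon``.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    rng = np.random.default_rng(seed)
    return _simulate_with_rng(substrate, conditions, params, rng, horizon)


def simulate_cohort(substrate: SubstrateSpec, conditions: ReactionConditions,
                    params: KineticParams, n: int, seed: int,
                    horizon: float = 120.0) -> List[Trajectory]:
    """Simulate ``n`` independent trajectories with per-trace seeds spawned
    deterministically from the master ``seed``."""
    if n == 0:
        warnings.warn("empty cohort requested (n = 0)", stacklevel=2)
        return []
    if n < 0:
        raise ValueError("n must be >= 0")
    children = np.random.SeedSequence(seed).spawn(n)
    return [
        _simulate_with_rng(substrate, conditions, params,
                           np.random.default_rng(child), horizon)
        for child in children
    ]
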