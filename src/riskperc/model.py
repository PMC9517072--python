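"""Limited-memory dynamics of public risk perception during an epidemic.

The model tracks a scalar risk-perception level ``y_t`` of an individual who
receives ``N_t`` items of epidemic-related information per period, each item
carrying a perception stimulus ``S_t``.  Two memory parameters govern the
dynamics:

* the **memory rate** ``rho`` — the fraction of the previous period's
  perception retained one period later (the recency effect; a per-period
  discrete analogue of the Ebbinghaus exponential decay), and
* the **association rate** ``k`` — the fraction of perception of past
  information that newly received information re-awakens.

Within a period the ``N_t`` items are assumed evenly spaced, so each item is
discounted by ``rho**(1/N_t)`` (or ``k**(1/N_t)``) relative to its neighbour.
Summing the within-period geometric ladders in closed form gives a
deterministic first-order recursion: the first period is

    y_1 = S_1 * F(rho, k, N_1)

and subsequent periods follow

    y_t = rho * y_{t-1}
          + S_t * [ (rho - k)/(u_t - v_t) * (1 - k) * A_t  +  F(rho, k, N_t) ]

with ``u_t = rho**(1/N_t)``, ``v_t = k**(1/N_t)``, the stimulus kernel

    F(rho, k, n) = u*rho/((u-v)(u-1)) - v*k/((u-v)(v-1)) + 1/((u-1)(v-1))

and the association sum ``A_t = sum_{i=1..t} g(k, N_i) * k**(t-i)`` where
``g(k, n) = k**(1/n) / (1 - k**(1/n))``.  The recursion is linear in the
stimulus sequence and contains no randomness.

This module is organised in the order the method runs: configuration and
errors, domain types, the perception recursion core, information-release
schedule generators and packaged COVID-19 fixtures, trajectory analysis
(peaks, lags, parameter sweeps, shape diagnostics), and CSV/JSON input and
output with a run orchestrator used by the command-line interface.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EPSILON_PK",
    "DegenerateParameterError",
    "ScheduleError",
    "MemoryProfile",
    "InformationSchedule",
    "PerceptionTrajectory",
    "ScenarioSpec",
    "SweepSummary",
    "SweepEntry",
    "SweepResult",
    "ShapeReport",
    "RunConfig",
    "kernel_F",
    "association_weight",
    "first_period_perception",
    "association_sum",
    "step_perception",
    "simulate",
    "steady_state_limit",
    "constant_schedule",
    "linear_N_schedule",
    "gaussian_N_schedule",
    "sinusoidal_N_schedule",
    "linear_S_schedule",
    "gaussian_S_schedule",
    "covid_fixture",
    "memory_grid",
    "scenario_bundle",
    "SCENARIO_NAMES",
    "peak_period",
    "local_maxima",
    "perception_lag",
    "parameter_sweep",
    "shape_diagnostics",
    "parse_schedule_csv",
    "write_schedule_csv",
    "sweep_frame",
    "sweep_summary",
    "run",
]

# --------------------------------------------------------------------------
# Configuration & errors
# --------------------------------------------------------------------------

logger = logging.getLogger("riskperc")

#: Minimum separation |rho - k|.  The kernel denominators contain
#: rho**(1/n) - k**(1/n); rho == k is a removable singularity the model
#: never uses, so near-equal values are rejected rather than handled by a
#: limit formula.
EPSILON_PK: float = 1e-6

#: Held-constant stimulus used when the information *count* is the varying
#: quantity (two perception units per item).
DEFAULT_BASE_S: float = 2.0

#: Held-constant information count used when the *stimulus* is the varying
#: quantity (forty items per period).
DEFAULT_BASE_N: float = 40.0

#: Default horizon for the synthetic release scenarios.
DEFAULT_T: int = 20


class DegenerateParameterError(ValueError):
    """Memory parameters make a kernel denominator vanish (or nearly so)."""


class ScheduleError(ValueError):
    """An information schedule violates its validity constraints."""


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class MemoryProfile:
    """An individual's memory parameters.

    Parameters
    ----------
    rho : float
        Memory rate — fraction of the previous period's perception retained
        one period later.  Strictly in (0, 1).
    k : float
        Association rate — fraction of past perception re-awakened by new
        information.  Strictly in (0, 1), and at least ``EPSILON_PK`` away
        from ``rho``.
    label : str
        Optional provenance tag (e.g. a grid combo number).
    """

    rho: float
    k: float
    label: str = ""

    def __post_init__(self) -> None:
        _check_memory_params(self.rho, self.k)


def _check_memory_params(rho: float, k: float) -> None:
    if not (0.0 < rho < 1.0):
        raise DegenerateParameterError(f"memory rate rho={rho!r} must lie strictly in (0, 1)")
    if not (0.0 < k < 1.0):
        raise DegenerateParameterError(f"association rate k={k!r} must lie strictly in (0, 1)")
    if abs(rho - k) < EPSILON_PK:
        raise DegenerateParameterError(
            f"rho={rho!r} and k={k!r} are closer than {EPSILON_PK}; "
            "the kernel denominator rho**(1/n) - k**(1/n) vanishes"
        )


@dataclass(frozen=True)
class InformationSchedule:
    """Aligned per-period information counts and single-item stimuli.

    ``N[t-1]`` is the number of information items received in (1-based)
    period ``t`` and ``S[t-1]`` the perception stimulus of one such item.
    Counts must be strictly positive (the model uses the exponent ``1/N_t``);
    stimuli may be any real.  ``period_labels`` optionally carries
    provenance strings (e.g. calendar date ranges) per period.
    """

    N: tuple[float, ...]
    S: tuple[float, ...]
    label: str = ""
    period_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "N", tuple(float(n) for n in self.N))
        object.__setattr__(self, "S", tuple(float(s) for s in self.S))
        if len(self.N) != len(self.S):
            raise ScheduleError(
                f"schedule {self.label!r}: len(N)={len(self.N)} != len(S)={len(self.S)}"
            )
        if len(self.N) == 0:
            raise ScheduleError(f"schedule {self.label!r} is empty")
        for t, n in enumerate(self.N, start=1):
            if not (n > 0.0) or not math.isfinite(n):
                raise ScheduleError(
                    f"schedule {self.label!r}: N_{t} = {n!r} must be a positive finite real"
                )
        if self.period_labels and len(self.period_labels) != len(self.N):
            raise ScheduleError(f"schedule {self.label!r}: period_labels length mismatch")

    @property
    def T(self) -> int:
        """Number of periods."""
        return len(self.N)

    def is_constant(self) -> bool:
        """True when both N and S are constant over the horizon."""
        return len(set(self.N)) == 1 and len(set(self.S)) == 1

    def scaled_stimulus(self, factor: float) -> "InformationSchedule":
        """Return a copy with every stimulus multiplied by ``factor``."""
        return InformationSchedule(
            N=self.N,
            S=tuple(factor * s for s in self.S),
            label=f"{self.label}*S{factor:g}" if self.label else f"*S{factor:g}",
            period_labels=self.period_labels,
        )


@dataclass(frozen=True)
class PerceptionTrajectory:
    """A simulated perception path ``y_1..y_T`` with its provenance."""

    y: tuple[float, ...]
    profile: MemoryProfile
    schedule: InformationSchedule

    def __post_init__(self) -> None:
        object.__setattr__(self, "y", tuple(float(v) for v in self.y))
        if len(self.y) != self.schedule.T:
            raise ScheduleError(
                f"trajectory length {len(self.y)} != schedule horizon {self.schedule.T}"
            )

    @property
    def T(self) -> int:
        return len(self.y)


@dataclass(frozen=True)
class ScenarioSpec:
    """Declarative description of an information-release scenario.

    ``family`` selects the generator; ``params`` carries its named
    parameters; ``T`` the horizon; ``base_N``/``base_S`` the held-constant
    counterpart sequence value where applicable; ``rounding`` optionally
    rounds generated counts to the nearest integer (``"none"`` or
    ``"nearest"``).
    """

    family: str
    params: Mapping[str, float] = field(default_factory=dict)
    T: int = DEFAULT_T
    base_N: float = DEFAULT_BASE_N
    base_S: float = DEFAULT_BASE_S
    rounding: str = "none"

    _FAMILIES = ("constant", "linear_N", "gaussian_N", "sinusoidal_N", "linear_S", "gaussian_S", "fixture")

    def __post_init__(self) -> None:
        if self.family not in self._FAMILIES:
            raise ScheduleError(f"unknown scenario family {self.family!r}; expected one of {self._FAMILIES}")
        if self.rounding not in ("none", "nearest"):
            raise ScheduleError(f"rounding must be 'none' or 'nearest', got {self.rounding!r}")

    def build(self) -> InformationSchedule:
        """Materialise the schedule this spec describes."""
        p = dict(self.params)
        if self.family == "constant":
            return constant_schedule(p.get("N", self.base_N), p.get("S", self.base_S), self.T)
        if self.family == "linear_N":
            return linear_N_schedule(p["a"], p["b"], self.T, s_const=self.base_S, rounding=self.rounding)
        if self.family == "gaussian_N":
            return gaussian_N_schedule(p["C"], p["mu"], p["sigma"], self.T, s_const=self.base_S, rounding=self.rounding)
        if self.family == "sinusoidal_N":
            return sinusoidal_N_schedule(
                p.get("amplitude", 30.0), p.get("offset", 50.0), self.T,
                s_const=self.base_S, rounding=self.rounding,
            )
        if self.family == "linear_S":
            return linear_S_schedule(p["c"], p["d"], self.T, n_const=self.base_N)
        if self.family == "gaussian_S":
            return gaussian_S_schedule(p["C"], p["mu"], p["sigma"], self.T, n_const=self.base_N)
        return covid_fixture(str(p["id"]))


@dataclass(frozen=True)
class SweepSummary:
    """Per-combo summary statistics of a sweep entry."""

    peak_period: int
    peak_value: float
    final_value: float
    steady_state: float | None


@dataclass(frozen=True)
class SweepEntry:
    label: str
    profile: MemoryProfile
    trajectory: PerceptionTrajectory
    summary: SweepSummary


@dataclass(frozen=True)
class SweepResult:
    """Trajectories and summaries for a grid of memory profiles on one schedule."""

    schedule: InformationSchedule
    entries: tuple[SweepEntry, ...]


@dataclass(frozen=True)
class ShapeReport:
    """Classification of a trajectory's shape from its first differences."""

    classification: str  # monotone-increasing-saturating | rise-then-fall | oscillating | other
    sign_pattern: str  # one char per first difference: '+', '-', '0'
    steady_state_gap: float | None  # |y_T - y*|/|y*| for constant schedules, else None


@dataclass
class RunConfig:
    """Declarative configuration of one orchestrated run.

    ``scenario`` is a :class:`ScenarioSpec`, an already-built
    :class:`InformationSchedule`, or a path to a schedule CSV; ``profiles``
    an explicit list of (rho, k) pairs or a grid id
    (``"table3"``/``"table12"``); ``outdir`` receives the artifacts in the
    requested ``formats`` (any of ``"csv"``, ``"json"``); ``plot`` adds an
    advisory PNG of the trajectories.
    """

    scenario: "ScenarioSpec | InformationSchedule | str | Path"
    profiles: Sequence[tuple[float, float]] | str
    outdir: Path = Path(".")
    formats: tuple[str, ...] = ("csv", "json")
    plot: bool = False
    stem: str = "riskperc"


# --------------------------------------------------------------------------
# Perception recursion core
# --------------------------------------------------------------------------


def kernel_F(rho: float, k: float, n: float) -> float:
    """Per-period stimulus-to-perception kernel.

    With ``u = rho**(1/n)`` and ``v = k**(1/n)``::

        F = u*rho/((u-v)(u-1)) - v*k/((u-v)(v-1)) + 1/((u-1)(v-1))

    ``F(rho, k, 1) == 1`` identically: a single item per period contributes
    exactly its stimulus.  For ``n > 1`` the within-period ladder of
    partially remembered and re-associated items amplifies the stimulus.
    """
    _check_memory_params(rho, k)
    if not (n > 0.0):
        raise ScheduleError(f"information count n={n!r} must be positive")
    u = rho ** (1.0 / n)
    v = k ** (1.0 / n)
    # Literal operation order of the reference recursion, so that arbitrary-
    # precision transcriptions agree bit-for-bit at matching precision.
    return u * rho / (u - v) / (u - 1.0) - v * k / (u - v) / (v - 1.0) + 1.0 / (u - 1.0) / (v - 1.0)


def association_weight(k: float, n: float) -> float:
    """Per-period association factor ``g(k, n) = k**(1/n) / (1 - k**(1/n))``.

    Strictly increasing in ``n``: the more items a period holds, the closer
    consecutive items sit and the more past perception each one re-awakens.
    """
    if not (0.0 < k < 1.0):
        raise DegenerateParameterError(f"association rate k={k!r} must lie strictly in (0, 1)")
    if not (n > 0.0):
        raise ScheduleError(f"information count n={n!r} must be positive")
    v = k ** (1.0 / n)
    return v / (1.0 - v)


def first_period_perception(profile: MemoryProfile, n1: float, s1: float) -> float:
    """Perception after the first period: ``y_1 = S_1 * F(rho, k, N_1)``.

    The first period has no past to associate with, so no association sum
    appears.
    """
    return s1 * kernel_F(profile.rho, profile.k, n1)


def association_sum(profile: MemoryProfile, N_history: Sequence[float], t: int) -> float:
    """Accumulated association pressure at period ``t`` (1-based).

    ``A_t = sum_{i=1..t} g(k, N_i) * k**(t-i)`` — every past period's items
    (including the current period ``i = t``) re-awaken perception, decayed
    by the association rate per elapsed period.  Summed in increasing ``i``.
    """
    if t < 1:
        raise IndexError(f"period index t={t} must be >= 1")
    if t > len(N_history):
        raise IndexError(f"period index t={t} exceeds history length {len(N_history)}")
    k = profile.k
    total = 0.0
    for i in range(1, t + 1):
        total += association_weight(k, N_history[i - 1]) * k ** (t - i)
    return total


def step_perception(
    y_prev: float, profile: MemoryProfile, schedule: InformationSchedule, t: int
) -> float:
    """One recursion step: ``y_t`` from ``y_{t-1}`` for period ``t >= 2``."""
    if t < 2:
        raise ValueError(f"step_perception requires t >= 2 (got t={t}); period 1 uses first_period_perception")
    if t > schedule.T:
        raise IndexError(f"period index t={t} exceeds schedule horizon {schedule.T}")
    rho, k = profile.rho, profile.k
    n_t = schedule.N[t - 1]
    s_t = schedule.S[t - 1]
    u = rho ** (1.0 / n_t)
    v = k ** (1.0 / n_t)
    cycle = association_sum(profile, schedule.N, t)
    return rho * y_prev + s_t * ((rho - k) / (u - v) * (1.0 - k) * cycle + kernel_F(rho, k, n_t))


def simulate(profile: MemoryProfile, schedule: InformationSchedule) -> PerceptionTrajectory:
    """Run the full deterministic recursion over the schedule horizon.

    ``y_1`` from the first-period formula, ``y_2..y_T`` from the recursion.
    Identical inputs give bit-identical outputs.  Negative perception levels
    are representable (decreasing-stimulus regimes can undershoot zero) and
    are reported via a log warning, not clamped.
    """
    y = [first_period_perception(profile, schedule.N[0], schedule.S[0])]
    for t in range(2, schedule.T + 1):
        y.append(step_perception(y[-1], profile, schedule, t))
    neg = [t for t, v in enumerate(y, start=1) if v < 0.0]
    if neg:
        logger.warning(
            "perception went negative at period %d (%d periods total) for rho=%g k=%g on %r",
            neg[0], len(neg), profile.rho, profile.k, schedule.label,
        )
    return PerceptionTrajectory(y=tuple(y), profile=profile, schedule=schedule)


def steady_state_limit(profile: MemoryProfile, n: float, s: float) -> float:
    """Closed-form limit of the recursion under constant ``N == n, S == s``.

    With constant counts the association sum is a geometric series,
    ``A_t = g(k,n) * (1-k**t)/(1-k) -> g(k,n)/(1-k)``, so the fixed point of
    ``y = rho*y + s*((rho-k)/(u-v)*(1-k)*A + F)`` is::

        y* = s * ( (rho-k)*g(k,n)/(u-v) + F(rho,k,n) ) / (1 - rho)

    Constant-schedule trajectories increase strictly toward this limit.
    """
    rho, k = profile.rho, profile.k
    u = rho ** (1.0 / n)
    v = k ** (1.0 / n)
    g = association_weight(k, n)
    return s * ((rho - k) * g / (u - v) + kernel_F(rho, k, n)) / (1.0 - rho)


# --------------------------------------------------------------------------
# Information-release schedules & fixtures
# --------------------------------------------------------------------------


def _apply_rounding(values: Iterable[float], rounding: str) -> list[float]:
    if rounding == "none":
        return list(values)
    if rounding == "nearest":
        return [float(round(v)) for v in values]
    raise ScheduleError(f"rounding must be 'none' or 'nearest', got {rounding!r}")


def constant_schedule(n: float, s: float, T: int = DEFAULT_T, label: str = "") -> InformationSchedule:
    """Constant counts and stimuli: the baseline regime."""
    if T < 1:
        raise ScheduleError(f"horizon T={T} must be >= 1")
    return InformationSchedule(
        N=(float(n),) * T, S=(float(s),) * T,
        label=label or f"constant(N={n:g},S={s:g})",
    )


def linear_N_schedule(
    a: float, b: float, T: int = DEFAULT_T, s_const: float = DEFAULT_BASE_S,
    rounding: str = "none",
) -> InformationSchedule:
    """Linearly changing information count ``N_t = a*t + b``, constant stimulus.

    A positive slope emulates a monotonically worsening outbreak, a negative
    slope a receding one.  Every count must stay positive over the horizon.
    """
    N = [a * t + b for t in range(1, T + 1)]
    for t, n in enumerate(N, start=1):
        if n <= 0.0:
            raise ScheduleError(f"linear count a*t+b is non-positive at period {t}: N_{t} = {n:g}")
    return InformationSchedule(
        N=tuple(_apply_rounding(N, rounding)), S=(float(s_const),) * T,
        label=f"linear_N(a={a:g},b={b:g})",
    )


def gaussian_N_schedule(
    C: float, mu: float, sigma: float, T: int = DEFAULT_T, s_const: float = DEFAULT_BASE_S,
    rounding: str = "none",
) -> InformationSchedule:
    """Bell-shaped count ``N_t = C * exp(-(t-mu)^2/(2 sigma^2)) / (sqrt(2 pi) sigma)``.

    Emulates a single information wave that rises and then recedes; ``C``
    scales the overall volume, ``mu`` places the peak period, ``sigma`` its
    spread.
    """
    if C <= 0.0 or sigma <= 0.0:
        raise ScheduleError(f"gaussian schedule requires C > 0 and sigma > 0 (got C={C!r}, sigma={sigma!r})")
    N = [C / (math.sqrt(2.0 * math.pi) * sigma) * math.exp(-((t - mu) ** 2) / (2.0 * sigma**2)) for t in range(1, T + 1)]
    return InformationSchedule(
        N=tuple(_apply_rounding(N, rounding)), S=(float(s_const),) * T,
        label=f"gaussian_N(C={C:g},mu={mu:g},sigma={sigma:g})",
    )


def sinusoidal_N_schedule(
    amplitude: float = 30.0, offset: float = 50.0, T: int = DEFAULT_T,
    s_const: float = DEFAULT_BASE_S, rounding: str = "none",
) -> InformationSchedule:
    """Oscillating count ``N_t = amplitude * sin(pi*t/5) + offset`` (period 10).

    Emulates recurring information waves.  Positivity requires
    ``offset > amplitude >= 0``.
    """
    if not (offset > amplitude >= 0.0):
        raise ScheduleError(f"sinusoid requires offset > amplitude >= 0 (got amplitude={amplitude!r}, offset={offset!r})")
    N = [amplitude * math.sin(math.pi * t / 5.0) + offset for t in range(1, T + 1)]
    return InformationSchedule(
        N=tuple(_apply_rounding(N, rounding)), S=(float(s_const),) * T,
        label=f"sinusoidal_N(A={amplitude:g},offset={offset:g})",
    )


def linear_S_schedule(
    c: float, d: float, T: int = DEFAULT_T, n_const: float = DEFAULT_BASE_N
) -> InformationSchedule:
    """Linearly changing stimulus ``S_t = c*t + d`` with a constant count."""
    if n_const <= 0.0:
        raise ScheduleError(f"constant count n_const={n_const!r} must be positive")
    return InformationSchedule(
        N=(float(n_const),) * T, S=tuple(c * t + d for t in range(1, T + 1)),
        label=f"linear_S(c={c:g},d={d:g})",
    )


def gaussian_S_schedule(
    C: float, mu: float, sigma: float, T: int = DEFAULT_T, n_const: float = DEFAULT_BASE_N
) -> InformationSchedule:
    """Bell-shaped stimulus with a constant count — one wave of content severity."""
    if C <= 0.0 or sigma <= 0.0:
        raise ScheduleError(f"gaussian schedule requires C > 0 and sigma > 0 (got C={C!r}, sigma={sigma!r})")
    if n_const <= 0.0:
        raise ScheduleError(f"constant count n_const={n_const!r} must be positive")
    S = tuple(C / (math.sqrt(2.0 * math.pi) * sigma) * math.exp(-((t - mu) ** 2) / (2.0 * sigma**2)) for t in range(1, T + 1))
    return InformationSchedule(
        N=(float(n_const),) * T, S=S,
        label=f"gaussian_S(C={C:g},mu={mu:g},sigma={sigma:g})",
    )


# COVID-19 case-study schedules, transcribed verbatim as decimal strings so
# the values remain auditable.  T1: 4-day cycles, 27 Dec 2019 - 2 May 2020.
# T2: 8-day cycles, 27 Dec 2019 - Apr 2021.  Each row: (date range, period,
# single-item stimulus S, information count N).
_T1_ROWS: tuple[tuple[str, int, str, str], ...] = (
    ("27 December 2019~30 December 2019", 1, "1", "2"),
    ("31 December 2019~3 January 2020", 2, "1.1", "3"),
    ("4 January 2020~7 January 2020", 3, "1.2", "4"),
    ("8 January 2020~11 January 2020", 4, "1.3", "5"),
    ("12 January 2020~15 January 2020", 5, "1.4", "6"),
    ("16 January 2020~19 January 2020", 6, "1.5", "7"),
    ("20 January 2020~23 January 2020", 7, "1.6", "8"),
    ("24 January 2020~27 January 2020", 8, "2", "18"),
    ("28 January 2020~31 January 2020", 9, "3", "28"),
    ("1 February 2020~4 February 2020", 10, "4", "38"),
    ("5 February 2020~8 February 2020", 11, "5", "48"),
    ("9 February 2020~12 February 2020", 12, "4.8", "46"),
    ("13 February 2020~16 February 2020", 13, "4.6", "47"),
    ("17 February 2020~20 February 2020", 14, "4.4", "49"),
    ("21 February 2020~24 February 2020", 15, "4.2", "45"),
    ("25 February 2020~28 February 2020", 16, "3.9", "43"),
    ("29 February 2020~3 March 2020", 17, "3.6", "41"),
    ("4 March 2020~7 March 2020", 18, "3.3", "39"),
    ("8 March 2020~11 March 2020", 19, "3", "37"),
    ("12 March 2020~15 March 2020", 20, "2.7", "35"),
    ("16 March 2020~19 March 2020", 21, "2.4", "33"),
    ("20 March 2020~23 March 2020", 22, "2.1", "31"),
    ("24 March 2020~27 March 2020", 23, "1.8", "29"),
    ("28 March 2020~31 March 2020", 24, "1.5", "27"),
    ("1 April 2020~4 April 2020", 25, "1.495", "25"),
    ("5 April 2020~8 April 2020", 26, "1.48", "22"),
    ("9 April 2020~12 April 2020", 27, "1.465", "26"),
    ("13 April 2020~16 April 2020", 28, "1.46", "24"),
    ("17 April 2020~20 April 2020", 29, "1.455", "27"),
    ("21 April 2020~24 April 2020", 30, "1.44", "22"),
    ("25 April 2020~28 April 2020", 31, "1.425", "24"),
    ("29 April 2020~2 May 2020", 32, "1.42", "28"),
)

_T2_ROWS: tuple[tuple[str, int, str, str], ...] = (
    ("27 December 2019~3 January 2020", 1, "1.05", "3"),
    ("4 January 2020~11 January 2020", 2, "1.25", "5"),
    ("12 January 2020~19 January 2020", 3, "1.45", "7"),
    ("20 January 2020~27 January 2020", 4, "1.8", "13"),
    ("28 January 2020~4 February 2020", 5, "3.5", "33"),
    ("5 February 2020~12 February 2020", 6, "4.9", "47"),
    ("13 February 2020~20 February 2020", 7, "4.5", "48"),
    ("21 February 2020~28 February 2020", 8, "4.05", "44"),
    ("29 February 2020~7 March 2020", 9, "3.45", "40"),
    ("8 March 2020~15 March 2020", 10, "2.85", "36"),
    ("16 March 2020~23 March 2020", 11, "2.25", "32"),
    ("24 March 2020~30 March 2020", 12, "1.65", "28"),
    ("1 April 2020~8 April 2020", 13, "1.4875", "23.5"),
    ("9 April 2020~16 April 2020", 14, "1.4625", "25"),
    ("17 April 2020~24 April 2020", 15, "1.4475", "24.5"),
    ("25 April 2020~2 May 2020", 16, "1.4225", "26"),
    ("3 May 2020~10 May 2020", 17, "1.4025", "24"),
    ("11 May 2020~18 May 2020", 18, "1.3815", "24"),
    ("19 May 2020~26 May 2020", 19, "1.3605", "23"),
    ("27 May 2020~3 June 2020", 20, "1.3395", "23"),
    ("4 June 2020~11 June 2020", 21, "1.3185", "24"),
    ("12 June 2020~19 June 2020", 22, "1.2975", "21"),
    ("20 June 2020~27 June 2020", 23, "1.2765", "22"),
    ("28 June 2020~5 July 2020", 24, "1.2555", "22"),
    ("6 July 2020~13 July 2020", 25, "1.2345", "23"),
    ("14 July 2020~21 July 2020", 26, "1.2135", "21"),
    ("22 July 2020~29 July 2020", 27, "1.1925", "21"),
    ("30 July 2020~6 August 2020", 28, "1.1715", "20"),
    ("7 August 2020~14 August 2020", 29, "1.1505", "20"),
    ("15 August 2020~22 August 2020", 30, "1.1295", "21"),
    ("23 August 2020~30 August 2020", 31, "1.1085", "20"),
    ("31 August 2020~7 September 2020", 32, "1.0875", "20"),
    ("8 September 2020~15 September 2020", 33, "1.0665", "19"),
    ("16 September 2020~23 September 2020", 34, "1.0455", "19"),
    ("24 September 2020~1 October 2020", 35, "1.0245", "20"),
    ("2 October 2020~9 October 2020", 36, "1.0035", "18"),
    ("10 October 2020~17 October 2020", 37, "0.9825", "18"),
    ("18 October 2020~25 October 2020", 38, "0.9615", "16"),
    ("26 October 2020~2 November 2020", 39, "0.9405", "17"),
    ("3 November 2020~10 November 2020", 40, "0.9195", "17"),
    ("11 November 2020~18 November 2020", 41, "0.8985", "17"),
    ("19 November 2020~26 November 2020", 42, "0.8775", "17"),
    ("27 November 2020~4 December 2020", 43, "0.8565", "16"),
    ("5 December 2020~12 December 2020", 44, "0.8355", "18"),
    ("13 December 2020~20 December 2020", 45, "0.8145", "16"),
    ("21 December 2020~28 December 2020", 46, "0.7935", "15"),
    ("29 December 2020~5 January 2021", 47, "0.7725", "14"),
    ("6 January 2021~13 January 2021", 48, "0.7515", "15"),
    ("14 January 2021~21 January 2021", 49, "0.7305", "14"),
    ("22 January 2021~29 January 2021", 50, "0.7095", "13"),
    ("30 January 2021~6 February 2021", 51, "0.6885", "14"),
    ("7 February 2021~14 February 2021", 52, "0.6675", "14"),
    ("15 February 2021~22 February 2021", 53, "0.6465", "13"),
    ("23 February 2021~2 March 2021", 54, "0.6255", "16"),
    ("3 March 2021~10 March 2021", 55, "0.6045", "13"),
    ("11 March 2021~18 March 2021", 56, "0.5835", "12"),
    ("19 March 2021~26 March 2021", 57, "0.5625", "10"),
    ("27 March 2021~3 April 2021", 58, "0.5415", "12"),
    ("4 April 2021~11 April 2021", 59, "0.5205", "11"),
    ("12 April 2020~20 April 2020", 60, "0.4995", "10"),
)

_FIXTURES: dict[str, tuple[tuple[str, int, str, str], ...]] = {"T1": _T1_ROWS, "T2": _T2_ROWS}


def covid_fixture(fixture_id: str) -> InformationSchedule:
    """Packaged COVID-19 case-study schedule.

    ``"T1"`` — 32 four-day cycles (27 Dec 2019 to 2 May 2020); ``"T2"`` — 60
    eight-day cycles extending into 2021.  Values are exact transcriptions;
    the date-range strings are carried as period labels.
    """
    try:
        rows = _FIXTURES[fixture_id]
    except KeyError:
        raise KeyError(f"unknown fixture {fixture_id!r}; expected one of {sorted(_FIXTURES)}") from None
    return InformationSchedule(
        N=tuple(float(n) for _, _, _, n in rows),
        S=tuple(float(s) for _, _, s, _ in rows),
        label=fixture_id,
        period_labels=tuple(date for date, _, _, _ in rows),
    )


# Memory-parameter grids used by the simulation study: a five-combo grid
# varying rho in {0.4, 0.5, 0.6} and k in {0.2, 0.3, 0.4} around the centre
# (0.5, 0.3), and a 2x2 grid crossing high/low memory with high/low
# association for the COVID-19 case study.
_GRIDS: dict[str, tuple[tuple[str, float, float], ...]] = {
    "table3": (
        ("1", 0.5, 0.4),
        ("2", 0.6, 0.3),
        ("3", 0.5, 0.3),
        ("4", 0.4, 0.3),
        ("5", 0.5, 0.2),
    ),
    "table12": (
        ("1", 0.8, 0.4),
        ("2", 0.5, 0.4),
        ("3", 0.8, 0.2),
        ("4", 0.5, 0.2),
    ),
}


def memory_grid(grid_id: str) -> list[MemoryProfile]:
    """Labelled memory-parameter combinations, order-preserving."""
    try:
        rows = _GRIDS[grid_id]
    except KeyError:
        raise KeyError(f"unknown grid {grid_id!r}; expected one of {sorted(_GRIDS)}") from None
    return [MemoryProfile(rho=rho, k=k, label=label) for label, rho, k in rows]


#: Named scenario bundles: name -> (list of (label, schedule), default grid id or None).
def scenario_bundle(name: str) -> tuple[list[tuple[str, InformationSchedule]], str | None]:
    """Resolve a named study scenario to its schedules and default grid.

    Single-profile bundles (the information-release studies run at the
    centre combo rho=0.5, k=0.3) return ``None`` as grid id.
    """
    if name == "table3-constant":
        return [("constant", constant_schedule(10.0, 2.0, DEFAULT_T))], "table3"
    if name == "linear-up":
        return [("linear-up", linear_N_schedule(5.0, 5.0))], None
    if name == "linear-down":
        return [("linear-down", linear_N_schedule(-5.0, 105.0))], None
    if name == "gaussian":
        return [("gaussian", gaussian_N_schedule(1000.0, 10.0, 5.0))], None
    if name == "sinusoid":
        return [("sinusoid", sinusoidal_N_schedule())], None
    if name == "stimulus-up":
        rows = [("1", 0.05, 2.0), ("2", 0.1, 2.0), ("3", 0.2, 2.0), ("4", 0.2, 3.0)]
        return [(lbl, linear_S_schedule(c, d)) for lbl, c, d in rows], None
    if name == "stimulus-down":
        rows = [("1", -0.05, 6.0), ("2", -0.1, 6.0), ("3", -0.2, 6.0), ("4", -0.2, 5.0)]
        return [(lbl, linear_S_schedule(c, d)) for lbl, c, d in rows], None
    if name == "stimulus-gaussian":
        rows = [
            ("1", 80.0, 10.0, 5.0), ("2", 60.0, 10.0, 5.0), ("3", 60.0, 5.0, 5.0),
            ("4", 60.0, 15.0, 5.0), ("5", 80.0, 10.0, 10.0), ("6", 40.0, 10.0, 5.0),
        ]
        return [(lbl, gaussian_S_schedule(C, mu, sigma)) for lbl, C, mu, sigma in rows], None
    if name in _FIXTURES:
        return [(name, covid_fixture(name))], "table12"
    raise KeyError(f"unknown scenario bundle {name!r}; expected one of {sorted(SCENARIO_NAMES)}")


SCENARIO_NAMES: tuple[str, ...] = (
    "table3-constant", "linear-up", "linear-down", "gaussian", "sinusoid",
    "stimulus-up", "stimulus-down", "stimulus-gaussian", "T1", "T2",
)


# --------------------------------------------------------------------------
# Analysis: peaks, lags, sweeps, shape
# --------------------------------------------------------------------------


def peak_period(values: Sequence[float]) -> int:
    """1-based index of the maximum; ties break toward the earliest period."""
    if len(values) == 0:
        raise ValueError("peak_period of an empty sequence")
    return int(np.argmax(np.asarray(values, dtype=float))) + 1


def local_maxima(values: Sequence[float]) -> list[int]:
    """1-based indices of strict interior local maxima.

    A plateau that rises on the left and falls on the right resolves to the
    first index of the plateau.  Endpoints are never reported.
    """
    v = [float(x) for x in values]
    T = len(v)
    peaks: list[int] = []
    i = 1
    while i < T - 1:
        j = i
        while j + 1 < T and v[j + 1] == v[j]:
            j += 1
        if v[i] > v[i - 1] and j + 1 < T and v[j] > v[j + 1]:
            peaks.append(i + 1)
        i = j + 1
    return peaks


def perception_lag(schedule: InformationSchedule, trajectory: PerceptionTrajectory) -> int:
    """Periods by which the perception peak trails the information-count peak.

    ``peak_period(y) - peak_period(N)``; the memory rate governs the size of
    this lag.  For constant schedules the count peak is degenerate (period 1)
    and the value is not meaningful.
    """
    if trajectory.T != schedule.T:
        raise ScheduleError(f"trajectory horizon {trajectory.T} != schedule horizon {schedule.T}")
    return peak_period(trajectory.y) - peak_period(schedule.N)


def parameter_sweep(grid: Sequence[MemoryProfile], schedule: InformationSchedule) -> SweepResult:
    """Simulate every memory profile on a shared schedule.

    Deterministic, order-preserving; steady states are reported only for
    constant schedules (they are undefined otherwise).
    """
    if len(grid) == 0:
        raise ValueError("parameter sweep requires a non-empty grid")
    constant = schedule.is_constant()
    entries = []
    for idx, profile in enumerate(grid, start=1):
        label = profile.label or str(idx)
        try:
            traj = simulate(profile, schedule)
        except Exception as exc:
            raise type(exc)(f"combo {label} (rho={profile.rho}, k={profile.k}): {exc}") from exc
        pk = peak_period(traj.y)
        steady = steady_state_limit(profile, schedule.N[0], schedule.S[0]) if constant else None
        entries.append(
            SweepEntry(
                label=label, profile=profile, trajectory=traj,
                summary=SweepSummary(
                    peak_period=pk, peak_value=traj.y[pk - 1],
                    final_value=traj.y[-1], steady_state=steady,
                ),
            )
        )
    return SweepResult(schedule=schedule, entries=tuple(entries))


#: First differences smaller than this fraction of max|y| count as flat.
FLAT_TOL: float = 1e-9


def shape_diagnostics(trajectory: PerceptionTrajectory) -> ShapeReport:
    """Classify a trajectory's shape from its first-difference sign pattern.

    ``monotone-increasing-saturating`` — no negative differences (the
    "reverse L" of constant-input regimes); ``rise-then-fall`` — a single
    sign change from rise to fall; ``oscillating`` — two or more sign
    changes; ``other`` — anything else (e.g. monotone decline).  For
    constant schedules the report includes the relative distance of ``y_T``
    to the closed-form steady state.
    """
    y = trajectory.y
    if len(y) < 3:
        raise ValueError(f"shape diagnostics requires T >= 3 (got T={len(y)})")
    scale = max(abs(v) for v in y) or 1.0
    signs = []
    for a, b in zip(y, y[1:]):
        d = b - a
        signs.append("0" if abs(d) < FLAT_TOL * scale else ("+" if d > 0 else "-"))
    pattern = "".join(signs)
    nonflat = [s for s in signs if s != "0"]
    changes = sum(1 for a, b in zip(nonflat, nonflat[1:]) if a != b)
    if "-" not in nonflat:
        classification = "monotone-increasing-saturating"
    elif changes == 1 and nonflat[0] == "+":
        classification = "rise-then-fall"
    elif changes >= 2:
        classification = "oscillating"
    else:
        classification = "other"
    gap = None
    if trajectory.schedule.is_constant():
        star = steady_state_limit(trajectory.profile, trajectory.schedule.N[0], trajectory.schedule.S[0])
        if star != 0.0:
            gap = abs(y[-1] - star) / abs(star)
        else:
            gap = abs(y[-1])
    return ShapeReport(classification=classification, sign_pattern=pattern, steady_state_gap=gap)


# --------------------------------------------------------------------------
# I/O & run orchestration
# --------------------------------------------------------------------------

_SCHEDULE_HEADER = ["period", "N", "S"]


def parse_schedule_csv(path: str | Path) -> InformationSchedule:
    """Read a schedule CSV with header ``period,N,S``.

    Periods must run contiguously 1..T in ascending order; counts must be
    positive.  Errors name the offending row (1-based, header = row 1).
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ScheduleError(f"{path}: empty file") from None
        if [h.strip() for h in header] != _SCHEDULE_HEADER:
            raise ScheduleError(f"{path}: malformed header {header!r}; expected {_SCHEDULE_HEADER}")
        N: list[float] = []
        S: list[float] = []
        for rownum, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue
            if len(row) != 3:
                raise ScheduleError(f"{path}: row {rownum}: expected 3 columns, got {len(row)}")
            try:
                period = int(row[0])
                n = float(row[1])
                s = float(row[2])
            except ValueError as exc:
                raise ScheduleError(f"{path}: row {rownum}: {exc}") from None
            expected = len(N) + 1
            if period != expected:
                raise ScheduleError(
                    f"{path}: row {rownum}: non-contiguous period {period} (expected {expected})"
                )
            if n <= 0.0:
                raise ScheduleError(f"{path}: row {rownum}: non-positive N = {row[1]}")
            N.append(n)
            S.append(s)
    if not N:
        raise ScheduleError(f"{path}: no data rows")
    return InformationSchedule(N=tuple(N), S=tuple(S), label=path.stem)


def write_schedule_csv(schedule: InformationSchedule, path: str | Path) -> None:
    """Write a schedule as ``period,N,S`` with shortest round-trip floats."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_SCHEDULE_HEADER)
        for t in range(1, schedule.T + 1):
            writer.writerow([t, repr(schedule.N[t - 1]), repr(schedule.S[t - 1])])


def sweep_frame(result: SweepResult) -> pd.DataFrame:
    """Tidy long-format frame: one row per combo x period."""
    records = []
    for entry in result.entries:
        sched = entry.trajectory.schedule
        for t in range(1, sched.T + 1):
            records.append(
                {
                    "label": entry.label, "rho": entry.profile.rho, "k": entry.profile.k,
                    "period": t, "N": sched.N[t - 1], "S": sched.S[t - 1],
                    "y": entry.trajectory.y[t - 1],
                }
            )
    return pd.DataFrame.from_records(records)


def sweep_summary(result: SweepResult) -> dict:
    """JSON-ready summary: per-combo peaks, lags, finals, steady states."""
    sched = result.schedule
    return {
        "schedule": sched.label,
        "T": sched.T,
        "N_peak_period": peak_period(sched.N),
        "S_peak_period": peak_period(sched.S),
        "combos": [
            {
                "label": e.label,
                "rho": e.profile.rho,
                "k": e.profile.k,
                "peak_period": e.summary.peak_period,
                "peak_value": e.summary.peak_value,
                "final_value": e.summary.final_value,
                "steady_state": e.summary.steady_state,
                "lag_vs_N_peak": e.summary.peak_period - peak_period(sched.N),
            }
            for e in result.entries
        ],
    }


def _write_frame_csv(frame: pd.DataFrame, path: Path) -> None:
    # repr-format floats so a re-parse reproduces the values bit-for-bit
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(frame.columns.tolist())
        for row in frame.itertuples(index=False):
            writer.writerow([repr(v) if isinstance(v, float) else v for v in row])


def _resolve_profiles(profiles: Sequence[tuple[float, float]] | str) -> list[MemoryProfile]:
    if isinstance(profiles, str):
        return memory_grid(profiles)
    out = [MemoryProfile(rho=float(r), k=float(kk), label=str(i)) for i, (r, kk) in enumerate(profiles, start=1)]
    if not out:
        raise ValueError("at least one memory profile is required")
    return out


def run(config: RunConfig) -> dict[str, Path]:
    """Execute one configured run and write its artifacts.

    Resolves the scenario to a schedule, sweeps the requested profiles,
    and writes ``<stem>_trajectories.csv`` (tidy long format) and/or
    ``<stem>_summary.json`` plus an optional ``<stem>.png`` into the output
    directory.  Returns the written paths keyed by artifact kind.  Numeric
    CSV output uses full round-trip precision, so re-running an identical
    configuration reproduces byte-identical files.
    """
    if isinstance(config.scenario, InformationSchedule):
        schedule = config.scenario
    elif isinstance(config.scenario, ScenarioSpec):
        schedule = config.scenario.build()
    else:
        schedule = parse_schedule_csv(config.scenario)
    grid = _resolve_profiles(config.profiles)
    logger.info(
        "run: schedule=%r T=%d profiles=%s", schedule.label, schedule.T,
        [(p.rho, p.k) for p in grid],
    )
    result = parameter_sweep(grid, schedule)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    if "csv" in config.formats:
        csv_path = outdir / f"{config.stem}_trajectories.csv"
        _write_frame_csv(sweep_frame(result), csv_path)
        written["csv"] = csv_path
    if "json" in config.formats:
        json_path = outdir / f"{config.stem}_summary.json"
        json_path.write_text(json.dumps(sweep_summary(result), indent=2) + "\n")
        written["json"] = json_path
    if config.plot:
        written["plot"] = _plot_sweep(result, outdir / f"{config.stem}.png")
    return written


def _plot_sweep(result: SweepResult, path: Path) -> Path:
    """Advisory trajectory plot (one line per combo)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    periods = range(1, result.schedule.T + 1)
    for entry in result.entries:
        ax.plot(
            periods, entry.trajectory.y,
            label=f"{entry.label}: rho={entry.profile.rho:g}, k={entry.profile.k:g}",
        )
    ax.set_xlabel("period")
    ax.set_ylabel("risk perception y")
    ax.set_title(result.schedule.label)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
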