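"""Kinetic models of deuterium label uptake and loss in cell populations.

All models track the fraction of labelled DNA strands ``l(t)`` in one or
more populations at demographic steady state, forced by the deuterium
availability ``D(t)`` (see :mod:`deukin.enrichment`).  Time is in scaled
time units (stu; labelling period = 1), and rates are per stu.

Model families
--------------
IS (implicit source)
    One population with turnover rate ``d`` whose precursors are assumed
    fully labelled: ``dl/dt = d (D(t) - l)``.

ES (explicit source)
    A precursor with turnover rate ``d1`` feeding a population of
    interest (POI) that divides at ``p2`` and is lost at ``d2``.  Each
    differentiating precursor contributes ``k`` cells (``k = 2`` for
    division-linked differentiation).  In fractions:

        dl1/dt = d1 (D - l1)
        dl2/dt = ((d2 - p2)/k) (l1 + (k-1) D) + p2 D - d2 l2

KH (kinetic heterogeneity)
    Two sub-populations with turnover rates ``delta1`` (slow) and
    ``delta2`` (fast), mixed with weight ``beta_slow`` on the slow one.

Phenomenological
    Constant label gain and loss rates: ``dl/dt = p* D - d* l``.  This
    is the two-parameter model usually fitted to labelling data when the
    underlying architecture is unknown.

Chain
    A KH head population feeding an arbitrary chain of ES-type
    populations, each driven by the labelled fraction of its upstream
    neighbour.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .enrichment import EnrichmentSchedule, availability
from .errors import ConfigurationError, ParameterError

__all__ = [
    "ESFractionParams",
    "CellNumberParams",
    "KHParams",
    "PhenomParams",
    "ChainSpec",
    "LabelTimeSeries",
    "simulate_is",
    "simulate_es",
    "es_closed_form",
    "simulate_kh",
    "simulate_phenom",
    "simulate_chain",
    "simulate_cell_numbers",
]

#: relative tolerance below which two rates are treated as equal and the
#: confluent (repeated-eigenvalue) closed-form branch is used
CONFLUENT_RTOL = 1e-6

#: default ODE solver tolerances
ODE_RTOL = 1e-8
ODE_ATOL = 1e-8


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ESFractionParams:
    """Identifiable parameters of the explicit-source model in fractions.

    Working with labelled fractions instead of cell numbers reduces the
    explicit-source model to three rates plus ``k``:

    d1
        Turnover (loss) rate of the precursor population, per stu.
    p2
        Division rate of the POI, per stu.
    d2
        Loss/turnover rate of the POI, per stu.  Steady state requires
        ``d2 > p2``: the shortfall is supplied by the precursor influx.
    k
        Number of cells produced per differentiating precursor (1 or 2).
    """

    d1: float
    p2: float
    d2: float
    k: int = 1

    def __post_init__(self) -> None:
        if not self.d1 > 0:
            raise ParameterError(f"d1 must be positive, got {self.d1}")
        if not self.d2 > 0:
            raise ParameterError(f"d2 must be positive, got {self.d2}")
        if not 0 <= self.p2 < self.d2:
            raise ParameterError(
                f"need 0 <= p2 < d2 for a steady state, got p2={self.p2}, d2={self.d2}"
            )
        if self.k not in (1, 2):
            raise ParameterError(f"k must be 1 or 2, got {self.k}")

    @property
    def division_fraction(self) -> float:
        """alpha2 = p2/d2: fraction of the POI replaced by its own division."""
        return self.p2 / self.d2


@dataclass(frozen=True)
class CellNumberParams:
    """Full cell-number parameterisation of the explicit-source model.

    sigma
        Influx into the precursor pool, cells per stu.
    p1, d1
        Division and loss rates of the precursor, per stu (``d1 > p1``).
    alpha_frac
        Fraction of departing precursors that mature into the POI.
    p2, d2, k
        POI parameters as in :class:`ESFractionParams`.
    """

    sigma: float
    p1: float
    d1: float
    alpha_frac: float
    p2: float
    d2: float
    k: int = 1

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ParameterError("sigma must be positive")
        if not 0 <= self.p1 < self.d1:
            raise ParameterError(
                f"need 0 <= p1 < d1 for a precursor steady state, "
                f"got p1={self.p1}, d1={self.d1}"
            )
        if not 0 < self.alpha_frac <= 1:
            raise ParameterError("alpha_frac must lie in (0, 1]")
        if not 0 <= self.p2 < self.d2:
            raise ParameterError("need 0 <= p2 < d2 for a POI steady state")
        if self.k not in (1, 2):
            raise ParameterError(f"k must be 1 or 2, got {self.k}")

    @property
    def n1_bar(self) -> float:
        """Steady-state precursor pool size sigma/(d1 - p1)."""
        return self.sigma / (self.d1 - self.p1)

    @property
    def n2_bar(self) -> float:
        """Steady-state POI size k*alpha*d1*N1bar/(d2 - p2)."""
        return self.k * self.alpha_frac * self.d1 * self.n1_bar / (self.d2 - self.p2)

    @property
    def fractions(self) -> ESFractionParams:
        """The reduced fraction-scale parameter set (d1, p2, d2, k)."""
        return ESFractionParams(d1=self.d1, p2=self.p2, d2=self.d2, k=self.k)


@dataclass(frozen=True)
class KHParams:
    """Two sub-population kinetic-heterogeneity parameters.

    beta_slow
        Fraction of the pool in the slow sub-population.  Must lie in
        [0, 1] unless ``extended=True``, which admits the wider range of
        the equivalent explicit-source mixing weight (used when mapping
        an ES parameter set onto the KH form).
    delta1, delta2
        Turnover rates of the slow and fast sub-populations
        (``delta1 <= delta2`` in the strict KH interpretation).
    """

    beta_slow: float
    delta1: float
    delta2: float
    extended: bool = False

    def __post_init__(self) -> None:
        if not (self.delta1 > 0 and self.delta2 > 0):
            raise ParameterError("sub-population turnover rates must be positive")
        if not self.extended:
            if not 0 <= self.beta_slow <= 1:
                raise ParameterError(
                    f"beta_slow must lie in [0, 1], got {self.beta_slow} "
                    "(use extended=True for the ES-equivalent mixing weight)"
                )
            if self.delta1 > self.delta2:
                raise ParameterError("delta1 (slow) must not exceed delta2 (fast)")

    @property
    def delta_bar(self) -> float:
        """Average turnover rate beta*delta1 + (1-beta)*delta2."""
        return self.beta_slow * self.delta1 + (1 - self.beta_slow) * self.delta2


@dataclass(frozen=True)
class PhenomParams:
    """Constant label gain rate ``p_star`` and loss rate ``d_star``."""

    p_star: float
    d_star: float

    def __post_init__(self) -> None:
        if self.p_star < 0:
            raise ParameterError("p_star must be non-negative")
        if not self.d_star > 0:
            raise ParameterError("d_star must be positive")

    @property
    def plateau(self) -> float:
        """Asymptotic labelled fraction p*/d* under sustained labelling."""
        return self.p_star / self.d_star


@dataclass(frozen=True)
class ChainSpec:
    """A KH head population feeding a chain of ES-type populations.

    ``downstream`` is an ordered list of ``(p_i, d_i, k_i)`` triples;
    population ``i`` is fed by the labelled fraction of population
    ``i - 1`` in place of a precursor curve.
    """

    head: KHParams
    downstream: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "downstream", tuple(tuple(x) for x in self.downstream))
        for i, (p, d, k) in enumerate(self.downstream):
            if not 0 <= p < d:
                raise ParameterError(
                    f"downstream population {i + 1}: need 0 <= p < d, got p={p}, d={d}"
                )
            if k not in (1, 2):
                raise ParameterError(f"downstream population {i + 1}: k must be 1 or 2")

    def __len__(self) -> int:
        return 1 + len(self.downstream)


# ---------------------------------------------------------------------------
# time-series container
# ---------------------------------------------------------------------------


@dataclass
class LabelTimeSeries:
    """Tidy container for observed or simulated labelled fractions.

    ``data`` has columns ``time`` (stu or days), ``population``,
    ``replicate`` and ``value`` (labelled fraction, or APE for raw
    enrichment data).  ``metadata`` records the schedule, value scale
    and any unit conversion applied on input.
    """

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    REQUIRED = ("time", "population", "replicate", "value")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ConfigurationError(f"time series missing columns: {missing}")
        if len(self.data) == 0:
            raise ConfigurationError("time series is empty")
        if (self.data["time"] < 0).any():
            raise ConfigurationError("time series contains negative times")
        if not np.isfinite(self.data["value"]).all():
            raise ConfigurationError("time series contains non-finite values")

    @classmethod
    def from_arrays(cls, time, value, population="poi", replicate=0, metadata=None):
        df = pd.DataFrame(
            {
                "time": np.asarray(time, dtype=float),
                "population": population,
                "replicate": replicate,
                "value": np.asarray(value, dtype=float),
            }
        )
        return cls(df, metadata=dict(metadata or {}))

    @property
    def populations(self) -> list:
        seen: dict = {}
        for p in self.data["population"]:
            seen.setdefault(p, None)
        return list(seen)

    def series(self, population) -> tuple[np.ndarray, np.ndarray]:
        """Times and values for one population, sorted by time."""
        sub = self.data[self.data["population"] == population].sort_values(
            ["time", "replicate"], kind="stable"
        )
        if len(sub) == 0:
            raise ConfigurationError(f"no records for population {population!r}")
        return sub["time"].to_numpy(), sub["value"].to_numpy()

    def concat(self, other: "LabelTimeSeries") -> "LabelTimeSeries":
        meta = {**self.metadata, **other.metadata}
        return LabelTimeSeries(
            pd.concat([self.data, other.data], ignore_index=True), metadata=meta
        )


def _series(times, values_by_pop: dict, metadata) -> LabelTimeSeries:
    frames = [
        pd.DataFrame(
            {"time": times, "population": pop, "replicate": 0, "value": vals}
        )
        for pop, vals in values_by_pop.items()
    ]
    return LabelTimeSeries(pd.concat(frames, ignore_index=True), metadata=metadata)


# ---------------------------------------------------------------------------
# closed forms (step-pulse schedule)
# ---------------------------------------------------------------------------


def _is_closed(d: float, t: np.ndarray, tau: float) -> np.ndarray:
    """Single-pool labelling: 1 - exp(-d t) up to tau, then washout at d."""
    t = np.asarray(t, dtype=float)
    up = -np.expm1(-d * t)
    l_tau = -np.expm1(-d * tau)
    down = l_tau * np.exp(-d * (t - tau))
    return np.where(t <= tau, up, down)


def _confluent(d1: float, d2: float) -> bool:
    return abs(d1 - d2) < CONFLUENT_RTOL * max(d1, d2)


def es_closed_form(params: ESFractionParams, t, tau: float = 1.0):
    """Analytic (l1, l2) of the explicit-source model under a step pulse.

    During labelling the POI curve is a mixture of the two exponentials
    ``exp(-d1 t)`` and ``exp(-d2 t)``:

        l2(t) = 1 - A exp(-d1 t) - (1 - A) exp(-d2 t),
        A = (d2 - p2) / (k (d2 - d1))

    with the confluent branch ``l2 = 1 - (1 + (d2-p2) t / k) exp(-d2 t)``
    when ``d1 = d2``.  The de-labelling continuation solves the same
    linear system with D = 0 from the state at ``t = tau``; it is
    cross-validated against direct ODE integration in the test suite.
    """
    d1, p2, d2, k = params.d1, params.p2, params.d2, params.k
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ParameterError("closed form defined for t >= 0")

    l1 = _is_closed(d1, t_arr, tau)

    def labelling(tt):
        if _confluent(d1, d2):
            return -np.expm1(-d2 * tt) - ((d2 - p2) / k) * tt * np.exp(-d2 * tt)
        a_coef = (d2 - p2) / (k * (d2 - d1))
        return 1.0 - a_coef * np.exp(-d1 * tt) - (1.0 - a_coef) * np.exp(-d2 * tt)

    l1_tau = float(-np.expm1(-d1 * tau))
    l2_tau = float(labelling(np.asarray([tau]))[0])

    def delabelling(tt):
        s = tt - tau
        if _confluent(d1, d2):
            transfer = ((d2 - p2) / k) * l1_tau * s * np.exp(-d2 * s)
        else:
            transfer = (
                ((d2 - p2) / k)
                * l1_tau
                * (np.exp(-d1 * s) - np.exp(-d2 * s))
                / (d2 - d1)
            )
        return l2_tau * np.exp(-d2 * s) + transfer

    l2 = np.where(t_arr <= tau, labelling(t_arr), delabelling(t_arr))

    if np.isscalar(t) or np.asarray(t).ndim == 0:
        return float(l1[0]), float(l2[0])
    return l1, l2


def _phenom_closed(p_star: float, d_star: float, t: np.ndarray, tau: float):
    t = np.asarray(t, dtype=float)
    up = p_star * (-np.expm1(-d_star * t)) / d_star
    l_tau = p_star * (-np.expm1(-d_star * tau)) / d_star
    down = l_tau * np.exp(-d_star * (t - tau))
    return np.where(t <= tau, up, down)


# ---------------------------------------------------------------------------
# ODE machinery
# ---------------------------------------------------------------------------


def _integrate(rhs, times, schedule: EnrichmentSchedule, y0, rtol=ODE_RTOL, atol=ODE_ATOL):
    """Integrate ``rhs(t, y, D)`` over the requested times.

    The step-pulse discontinuity at ``tau`` is never stepped across: the
    interval is split at ``tau`` and the two segments are solved
    separately, each with a continuous forcing (D = 1 then D = 0 for the
    step shape).  Requested times may be unsorted and contain
    duplicates.
    """
    times = np.asarray(times, dtype=float)
    uniq, inverse = np.unique(times, return_inverse=True)
    tau = schedule.tau
    y0 = np.asarray(y0, dtype=float)
    step = schedule.shape == "step"

    def d_pre(tt):
        return 1.0 if step else availability(float(tt), schedule)

    def d_post(tt):
        return 0.0 if step else availability(float(tt), schedule)

    pre = uniq[uniq <= tau]
    post = uniq[uniq > tau]
    out = np.empty((len(uniq), len(y0)))

    eval_pre = np.union1d(pre, [tau])  # always carry the state to tau
    sol = solve_ivp(
        lambda tt, yy: rhs(tt, yy, d_pre(tt)),
        (0.0, tau),
        y0,
        t_eval=eval_pre,
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"ODE solver failed in labelling phase: {sol.message}")
    if len(pre):
        idx = np.searchsorted(eval_pre, pre)
        out[: len(pre)] = sol.y.T[idx]
    y_tau = sol.y[:, -1]

    if len(post):
        sol2 = solve_ivp(
            lambda tt, yy: rhs(tt, yy, d_post(tt)),
            (tau, float(post[-1])),
            y_tau,
            t_eval=post,
            method="LSODA",
            rtol=rtol,
            atol=atol,
        )
        if not sol2.success:
            raise RuntimeError(
                f"ODE solver failed in de-labelling phase: {sol2.message}"
            )
        out[len(pre):] = sol2.y.T
    return out[inverse]


# ---------------------------------------------------------------------------
# simulators
# ---------------------------------------------------------------------------


def simulate_is(d: float, schedule: EnrichmentSchedule, times) -> LabelTimeSeries:
    """Implicit-source labelling curve: dl/dt = d (D(t) - l)."""
    if not d > 0:
        raise ParameterError(f"turnover rate must be positive, got {d}")
    times = np.asarray(times, dtype=float)
    if schedule.shape == "step":
        vals = _is_closed(d, times, schedule.tau)
    else:
        vals = _integrate(lambda t, y, D: [d * (D - y[0])], times, schedule, [0.0])[:, 0]
    return _series(times, {"poi": vals}, {"schedule": schedule, "model": "is", "d": d})


def simulate_es(
    params: ESFractionParams,
    schedule: EnrichmentSchedule,
    times,
    method: str = "auto",
) -> LabelTimeSeries:
    """Precursor (l1) and POI (l2) labelling curves of the ES model.

    ``method="auto"`` uses the closed form under a step pulse and ODE
    integration otherwise; ``"ode"`` forces numerical integration (the
    source of truth the closed form is validated against).
    """
    times = np.asarray(times, dtype=float)
    use_closed = (method == "closed_form") or (
        method == "auto" and schedule.shape == "step"
    )
    if use_closed:
        if schedule.shape != "step":
            raise ConfigurationError("closed form requires a step schedule")
        l1, l2 = es_closed_form(params, times, tau=schedule.tau)
    else:
        d1, p2, d2, k = params.d1, params.p2, params.d2, params.k

        def rhs(t, y, D):
            l1_, l2_ = y
            return [
                d1 * (D - l1_),
                ((d2 - p2) / k) * (l1_ + (k - 1) * D) + p2 * D - d2 * l2_,
            ]

        sol = _integrate(rhs, times, schedule, [0.0, 0.0])
        l1, l2 = sol[:, 0], sol[:, 1]
    return _series(
        times,
        {"precursor": l1, "poi": l2},
        {"schedule": schedule, "model": "es", "params": params},
    )


def simulate_kh(params: KHParams, schedule: EnrichmentSchedule, times) -> LabelTimeSeries:
    """Two sub-population kinetic-heterogeneity labelling curve.

    Under a step pulse this is the beta-weighted sum of two single-pool
    curves; under a body-water schedule each sub-population integrates
    ``dl_i/dt = delta_i (D(t) - l_i)`` and the weighted sum is returned.
    """
    times = np.asarray(times, dtype=float)
    b, x1, x2 = params.beta_slow, params.delta1, params.delta2
    if schedule.shape == "step":
        vals = b * _is_closed(x1, times, schedule.tau) + (1 - b) * _is_closed(
            x2, times, schedule.tau
        )
    else:
        sol = _integrate(
            lambda t, y, D: [x1 * (D - y[0]), x2 * (D - y[1])],
            times,
            schedule,
            [0.0, 0.0],
        )
        vals = b * sol[:, 0] + (1 - b) * sol[:, 1]
    return _series(times, {"poi": vals}, {"schedule": schedule, "model": "kh", "params": params})


def simulate_phenom(
    params: PhenomParams, schedule: EnrichmentSchedule, times
) -> LabelTimeSeries:
    """Constant-rate phenomenological curve: dl/dt = p* D(t) - d* l."""
    times = np.asarray(times, dtype=float)
    if schedule.shape == "step":
        vals = _phenom_closed(params.p_star, params.d_star, times, schedule.tau)
    else:
        vals = _integrate(
            lambda t, y, D: [params.p_star * D - params.d_star * y[0]],
            times,
            schedule,
            [0.0],
        )[:, 0]
    return _series(
        times, {"poi": vals}, {"schedule": schedule, "model": "phenom", "params": params}
    )


def simulate_chain(spec: ChainSpec, schedule: EnrichmentSchedule, times) -> LabelTimeSeries:
    """Labelling curves of a KH head feeding a chain of ES populations.

    Population j >= 2 obeys
    ``dl_j/dt = ((d_j - p_j)/k_j)(l_{j-1} + (k_j - 1) D) + p_j D - d_j l_j``
    with the upstream labelled fraction in place of a precursor curve.
    Populations are named ``pop1`` (head) through ``popN``.
    """
    if len(spec) < 1:
        raise ConfigurationError("chain must contain at least the head population")
    times = np.asarray(times, dtype=float)
    head = spec.head
    n_down = len(spec.downstream)

    def rhs(t, y, D):
        ls, lf = y[0], y[1]
        dy = [head.delta1 * (D - ls), head.delta2 * (D - lf)]
        upstream = head.beta_slow * ls + (1 - head.beta_slow) * lf
        for j, (p, d, k) in enumerate(spec.downstream):
            lj = y[2 + j]
            dy.append(((d - p) / k) * (upstream + (k - 1) * D) + p * D - d * lj)
            upstream = lj
        return dy

    sol = _integrate(rhs, times, schedule, [0.0] * (2 + n_down))
    head_vals = head.beta_slow * sol[:, 0] + (1 - head.beta_slow) * sol[:, 1]
    out = {"pop1": head_vals}
    for j in range(n_down):
        out[f"pop{j + 2}"] = sol[:, 2 + j]
    return _series(times, out, {"schedule": schedule, "model": "chain", "spec": spec})


def simulate_cell_numbers(
    params: CellNumberParams, schedule: EnrichmentSchedule, times
) -> pd.DataFrame:
    """Cell-number trajectories N1, N2, L1, L2 plus fractions l1, l2.

    Starts from the demographic steady state with no label; N1 and N2
    therefore stay constant and L_i / N_i reproduces the fraction-scale
    model exactly.
    """
    times = np.asarray(times, dtype=float)
    s, p1, d1 = params.sigma, params.p1, params.d1
    a, p2, d2, k = params.alpha_frac, params.p2, params.d2, params.k
    n1, n2 = params.n1_bar, params.n2_bar

    def rhs(t, y, D):
        N1, N2, L1, L2 = y
        return [
            s + (p1 - d1) * N1,
            k * a * d1 * N1 + (p2 - d2) * N2,
            s * D + p1 * D * n1 - d1 * L1,
            a * d1 * L1 + (k - 1) * a * d1 * n1 * D + p2 * D * n2 - d2 * L2,
        ]

    sol = _integrate(rhs, times, schedule, [n1, n2, 0.0, 0.0])
    df = pd.DataFrame(
        {
            "time": times,
            "N1": sol[:, 0],
            "N2": sol[:, 1],
            "L1": sol[:, 2],
            "L2": sol[:, 3],
        }
    )
    df["l1"] = df["L1"] / df["N1"]
    df["l2"] = df["L2"] / df["N2"]
    return df
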