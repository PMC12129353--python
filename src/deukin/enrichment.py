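"""Deuterium availability D(t) used as forcing in every kinetic model.

The availability function gives the probability that a de-novo synthesised
DNA strand incorporates deuterium at time ``t``.  Two shapes are supported:

``step``
    A square pulse: fully available while label is administered
    (``t < tau``) and zero afterwards.  This is the standard description
    for deuterated-glucose experiments, where plasma glucose turns over
    much faster than the cells being tracked.

``body_water``
    A saturating exponential rising towards the plateau ``f`` at water
    turnover rate ``delta``, starting from a baseline ``beta0``, followed
    by exponential washout after ``tau``.  This is the usual description
    for deuterated-water experiments, where body water equilibrates on a
    timescale of days.

Time is measured in scaled time units (stu): the labelling period is 1 by
convention, so the default ``tau`` is 1.  ``normalize=True`` rescales the
body-water curve by its plateau ``f`` so that the availability approaches
1 during long labelling, matching the convention that labelled fractions
saturate at 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DomainError

__all__ = ["EnrichmentSchedule", "availability"]

logger = logging.getLogger(__name__)

_SHAPES = ("step", "body_water")


@dataclass(frozen=True)
class EnrichmentSchedule:
    """Description of deuterium availability over the experiment.

    Parameters
    ----------
    shape:
        ``"step"`` or ``"body_water"``.
    tau:
        End of the labelling period, in the time units of the data
        (1 stu by convention).
    f:
        Asymptotic enrichment fraction of body water (body_water only).
    delta:
        Body-water turnover rate, per unit of the time axis
        (body_water only).
    beta0:
        Baseline enrichment at ``t = 0`` (body_water only).
    normalize:
        Divide the body-water curve by its plateau ``f`` so that the
        availability approaches 1 during labelling.
    time_unit:
        Label recording whether ``tau``/``delta`` are expressed per stu
        or per day; conversion between the two is the caller's
        responsibility and is logged at construction.
    """

    shape: str = "step"
    tau: float = 1.0
    f: float | None = None
    delta: float | None = None
    beta0: float = 0.0
    normalize: bool = True
    time_unit: str = "stu"

    def __post_init__(self) -> None:
        if self.shape not in _SHAPES:
            raise ConfigurationError(f"unknown schedule shape {self.shape!r}")
        if not self.tau > 0:
            raise ConfigurationError(f"tau must be positive, got {self.tau}")
        if self.shape == "body_water":
            if self.f is None or self.f <= 0:
                raise ConfigurationError(
                    "body_water schedule requires an asymptote f > 0"
                )
            if self.delta is None or self.delta <= 0:
                raise ConfigurationError(
                    "body_water schedule requires a turnover rate delta > 0"
                )
            if self.beta0 < 0:
                raise ConfigurationError("beta0 must be non-negative")
            if self.beta0 > self.f:
                raise ConfigurationError(
                    "baseline enrichment beta0 exceeds the asymptote f"
                )
        logger.info(
            "enrichment schedule: shape=%s tau=%g per-%s", self.shape, self.tau,
            self.time_unit,
        )

    def __call__(self, t):
        return availability(t, self)


def availability(t, schedule: EnrichmentSchedule):
    """Evaluate the deuterium availability D(t).

    Accepts scalars or arrays; returns the same shape.  Negative times
    are outside the experiment and raise :class:`DomainError`.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise DomainError("availability is defined for t >= 0 only")

    if schedule.shape == "step":
        out = np.where(t_arr < schedule.tau, 1.0, 0.0)
    else:
        f, delta, beta0 = schedule.f, schedule.delta, schedule.beta0
        up = f - (f - beta0) * np.exp(-delta * t_arr)
        d_tau = f - (f - beta0) * np.exp(-delta * schedule.tau)
        down = d_tau * np.exp(-delta * (t_arr - schedule.tau))
        out = np.where(t_arr <= schedule.tau, up, down)
        if schedule.normalize:
            out = out / f

    if np.isscalar(t) or t_arr.ndim == 0:
        return float(out)
    return out
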