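"""Cell-cycle kinetic parameterization and closed-form derived quantities.

The population is split into six compartments: unlabelled G0/G1, S and G2/M
cells (``G``, ``S``, ``M``) and their EdU-labelled counterparts (``Gp``,
``Sp``, ``Mp``).  Each compartment has a rate of entry into the next phase
(``a_X``, per hour) and a rate of exit from the population — death,
differentiation or migration — (``d_X``, per hour).  Label uptake is
governed by two parameters: ``beta``, the labelling rate of S-phase cells
while label is bioavailable (infinite in the default "instant" mode), and
``alpha``, the proportion of labelled mitoses whose daughters shed the
label.

The standard analysis mode constrains these fourteen parameters to two free
ones, (``a_G``, ``a_M``), through the biological hypotheses used throughout
this package:

* labelling does not perturb kinetics (labelled rates equal unlabelled);
* labelling is instantaneous during a pulse (``beta`` infinite);
* no label shedding over the experiment (``alpha = 0``);
* the population is at steady state, which forces ``d_G = a_G``;
* no exit during S or G2/M (``d_S = d_M = 0``);
* S phase lasts 6.5 h (``a_S = 1/6.5``).

Under those constraints the proliferation rate has the closed form
``p = 200 a_M a_G / (2 a_M + 13 a_M a_G + 2 a_G)`` in percent of cells
dividing per hour, and phase durations are the reciprocals of the
transition rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "S_PHASE_HOURS",
    "CycleRates",
    "LabelingParams",
    "PopulationState",
    "SteadyStateProportions",
    "DerivedKinetics",
    "InvalidParameterError",
    "DegenerateRatesError",
    "apply_hypotheses",
    "steady_state",
    "proliferation_rate",
    "derived_kinetics",
    "rates_for_proliferation",
]

#: Fixed S-phase duration (hours) under the standard hypotheses.
S_PHASE_HOURS = 6.5


class InvalidParameterError(ValueError):
    """A kinetic parameter violates its domain (e.g. non-positive rate)."""


class DegenerateRatesError(ValueError):
    """Rates for which the steady-state distribution is undefined."""


@dataclass(frozen=True)
class CycleRates:
    """Per-hour transition and exit rates of the six compartments.

    ``a_G, a_S, a_M`` are entry rates into the next phase for unlabelled
    G0/G1, S and G2/M cells; ``d_G, d_S, d_M`` the corresponding exit
    (death/differentiation/migration) rates.  ``*_p`` fields are the same
    for labelled cells.
    """

    a_G: float
    a_S: float
    a_M: float
    d_G: float = 0.0
    d_S: float = 0.0
    d_M: float = 0.0
    a_Gp: float | None = None
    a_Sp: float | None = None
    a_Mp: float | None = None
    d_Gp: float | None = None
    d_Sp: float | None = None
    d_Mp: float | None = None

    def __post_init__(self) -> None:
        # None on a primed field means "same as the unprimed rate" (the
        # labelling-neutrality hypothesis); frozen dataclass needs object.__setattr__.
        for name in ("a_Gp", "a_Sp", "a_Mp", "d_Gp", "d_Sp", "d_Mp"):
            if getattr(self, name) is None:
                object.__setattr__(self, name, getattr(self, name[:-1]))
        for name in (
            "a_G", "a_S", "a_M", "d_G", "d_S", "d_M",
            "a_Gp", "a_Sp", "a_Mp", "d_Gp", "d_Sp", "d_Mp",
        ):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise InvalidParameterError(f"{name} must be finite and >= 0, got {v!r}")


@dataclass(frozen=True)
class LabelingParams:
    """Label-uptake parameters.

    ``alpha`` is the proportion (in [0, 1]) of labelled dividing cells whose
    daughters lose the label.  ``beta`` is the per-hour labelling rate of
    S-phase cells during a pulse; ``math.inf`` selects the instant-labelling
    mode (implemented as a discrete transfer, not a stiff rate).
    """

    alpha: float = 0.0
    beta: float = math.inf

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise InvalidParameterError(f"alpha must be in [0, 1], got {self.alpha!r}")
        if not self.beta > 0:
            raise InvalidParameterError(f"beta must be > 0 (or inf), got {self.beta!r}")

    @property
    def instant(self) -> bool:
        return math.isinf(self.beta)


@dataclass(frozen=True)
class PopulationState:
    """Compartment abundances in percent-of-initial-total units."""

    G: float
    S: float
    M: float
    Gp: float = 0.0
    Sp: float = 0.0
    Mp: float = 0.0

    def as_tuple(self) -> tuple[float, float, float, float, float, float]:
        return (self.G, self.S, self.M, self.Gp, self.Sp, self.Mp)

    @property
    def total(self) -> float:
        return sum(self.as_tuple())

    @property
    def labelled(self) -> float:
        return self.Gp + self.Sp + self.Mp


@dataclass(frozen=True)
class SteadyStateProportions:
    """Steady-state phase occupancy (G+G', S+S', M+M'), percent; sums to 100."""

    gg: float
    ss: float
    mm: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.gg, self.ss, self.mm)

    def initial_state(self) -> PopulationState:
        """All-unlabelled population at steady-state occupancy (the fit's t=0)."""
        return PopulationState(G=self.gg, S=self.ss, M=self.mm)


@dataclass(frozen=True)
class DerivedKinetics:
    """Quantities derived from a fitted (a_G, a_M) pair.

    ``p_per_hour``/``p_per_day``: percent of cells dividing per hour/day;
    ``g1_duration_h = 1/a_G``; ``g2m_duration_h = 1/a_M``; ``s_duration_h``
    fixed at 6.5 h; ``intermitotic_days = 100 / p_per_day``.
    """

    p_per_hour: float
    p_per_day: float
    g1_duration_h: float
    g2m_duration_h: float
    s_duration_h: float
    intermitotic_days: float


def apply_hypotheses(a_G: float, a_M: float) -> tuple[CycleRates, LabelingParams]:
    """Expand the two free parameters into the fully constrained rate set.

    Applies the standard constraints: ``a_S = 1/6.5``, ``d_G = a_G`` (steady
    state), ``d_S = d_M = 0``, labelled rates equal unlabelled, ``alpha = 0``
    and instant labelling.

    Parameters
    ----------
    a_G, a_M
        Per-hour rates of entry into S phase (from G0/G1) and into division
        (from G2/M).  Must be strictly positive.
    """
    if not (a_G > 0 and math.isfinite(a_G)):
        raise InvalidParameterError(f"a_G must be > 0 and finite, got {a_G!r}")
    if not (a_M > 0 and math.isfinite(a_M)):
        raise InvalidParameterError(f"a_M must be > 0 and finite, got {a_M!r}")
    rates = CycleRates(
        a_G=a_G,
        a_S=1.0 / S_PHASE_HOURS,
        a_M=a_M,
        d_G=a_G,
        d_S=0.0,
        d_M=0.0,
    )
    return rates, LabelingParams(alpha=0.0, beta=math.inf)


def steady_state(rates: CycleRates) -> SteadyStateProportions:
    """Steady-state phase occupancy of the summed (labelled + unlabelled) system.

    Valid whenever labelled and unlabelled rates coincide and there is no
    exit during G2/M; the three components are::

        (G+G')ss = 200 a_M (a_S + d_S) / D
        (S+S')ss = 200 a_M a_G / D
        (M+M')ss = 100 (a_G + d_G)(a_S + d_S) / D
        D = 2 a_M (a_S + d_S) + 2 a_M a_G + (a_G + d_G)(a_S + d_S)
    """
    asds = rates.a_S + rates.d_S
    denom = 2 * rates.a_M * asds + 2 * rates.a_M * rates.a_G + (rates.a_G + rates.d_G) * asds
    if denom <= 0:
        raise DegenerateRatesError("steady-state denominator is not positive")
    gg = 200 * rates.a_M * asds / denom
    ss = 200 * rates.a_M * rates.a_G / denom
    mm = 100 * (rates.a_G + rates.d_G) * asds / denom
    return SteadyStateProportions(gg=gg, ss=ss, mm=mm)


def proliferation_rate(a_G: float, a_M: float) -> float:
    """Proliferation rate in percent of cells dividing per hour.

    Closed form under the standard hypotheses:
    ``p = 200 a_M a_G / (2 a_M + 13 a_M a_G + 2 a_G)``; algebraically equal
    to ``a_M (M+M')ss``.
    """
    if not (a_G > 0 and a_M > 0):
        raise InvalidParameterError("a_G and a_M must be > 0")
    return 200.0 * a_M * a_G / (2.0 * a_M + 13.0 * a_M * a_G + 2.0 * a_G)


def proliferation_gradient(a_G: float, a_M: float) -> tuple[float, float]:
    """Analytic gradient of :func:`proliferation_rate` (%/h) wrt (a_G, a_M)."""
    denom = 2.0 * a_M + 13.0 * a_M * a_G + 2.0 * a_G
    num = 200.0 * a_M * a_G
    dp_daG = (200.0 * a_M * denom - num * (13.0 * a_M + 2.0)) / denom**2
    dp_daM = (200.0 * a_G * denom - num * (13.0 * a_G + 2.0)) / denom**2
    return dp_daG, dp_daM


def derived_kinetics(a_G: float, a_M: float) -> DerivedKinetics:
    """All derived quantities for a fitted (a_G, a_M) pair.

    Rates are kept in per-hour units internally; the per-day rate is
    ``24 x p_per_hour`` and the inter-mitotic time ``100 / p_per_day`` days.
    """
    p_h = proliferation_rate(a_G, a_M)
    p_d = 24.0 * p_h
    return DerivedKinetics(
        p_per_hour=p_h,
        p_per_day=p_d,
        g1_duration_h=1.0 / a_G,
        g2m_duration_h=1.0 / a_M,
        s_duration_h=S_PHASE_HOURS,
        intermitotic_days=100.0 / p_d,
    )


def rates_for_proliferation(p_per_day: float, g2m_duration_h: float) -> tuple[float, float]:
    """Invert the proliferation-rate formula: (a_G, a_M) for a target rate.

    Given a target proliferation rate (percent per day) and a G2/M duration
    (hours, so ``a_M = 1/g2m_duration_h``), solve
    ``p = 200 a_M a_G / (2 a_M + 13 a_M a_G + 2 a_G)`` for ``a_G``.

    Raises :class:`InvalidParameterError` if the target rate is unreachable
    for that ``a_M`` (the formula saturates at ``200 a_M / (13 a_M + 2)``
    %/h as ``a_G`` grows).
    """
    if p_per_day <= 0 or g2m_duration_h <= 0:
        raise InvalidParameterError("target rate and G2/M duration must be > 0")
    a_M = 1.0 / g2m_duration_h
    p_h = p_per_day / 24.0
    denom = 200.0 * a_M - p_h * (13.0 * a_M + 2.0)
    if denom <= 0:
        raise InvalidParameterError(
            f"proliferation {p_per_day} %/day unreachable with G2/M = {g2m_duration_h} h"
        )
    a_G = 2.0 * a_M * p_h / denom
    return a_G, a_M
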