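"""Estimation of (a_G, a_M) from gated dot-plot triplets.

A sample's data are three gated percentages at sacrifice — unlabelled
G0/G1, unlabelled G2/M, and EdU-labelled cells.  Under the standard
hypotheses the model has two free parameters, the per-hour rates of entry
into S phase (``a_G``) and into division (``a_M``).  The estimator follows
the original procedure: simulate the labelling protocol from the
steady-state initial condition over a two-dimensional log-spaced grid of
(a_G, a_M), take the pair minimising the Euclidean distance between the
simulated and observed triplets, then (optionally) polish the grid optimum
with Nelder-Mead in log-parameter space.

Confidence intervals use the numerical Hessian of a multinomially weighted
least-squares objective at the optimum (Pearson weighting: for proportion
residuals that sum to zero, ``n * diag(1/p)`` is the generalised inverse of
the multinomial covariance).  Wald 95% intervals are reported for the
parameters and, via the delta method, for the proliferation rate.

:class:`DotPlotModel` / :class:`DotPlotResults` provide the model-object
interface; :func:`fit_sample` and :func:`fit_table` are the functional
equivalents for single samples and sample tables.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar
from scipy.stats import norm as _norm

from .kinetics import (
    DerivedKinetics,
    apply_hypotheses,
    derived_kinetics,
    proliferation_gradient,
    steady_state,
)
from .protocol import Protocol, default_study_protocol
from .simulate import (
    DotPlotSummary,
    SimConfig,
    _endpoint_batch_hypothesis,
    endpoint_summary,
    simulate,
)

__all__ = [
    "FitConfig",
    "FitResult",
    "RateRegression",
    "DotPlotModel",
    "DotPlotResults",
    "objective",
    "fit_sample",
    "confidence_intervals",
    "fit_table",
    "edu_to_rate",
]

logger = logging.getLogger(__name__)

#: Printed calibration of the %EdU+ -> proliferation-rate shortcut
#: (fraction/day per %EdU+ on the 0-100 scale, and its intercept).
EDU_RATE_SLOPE = 0.0119
EDU_RATE_INTERCEPT = -0.000884


@dataclass(frozen=True)
class FitConfig:
    """Search-box and refinement settings for the grid fit.

    ``grid_min``/``grid_max`` bound both rates (per hour); ``grid_n``
    log-spaced points per axis; ``refine`` enables the Nelder-Mead polish;
    ``distance_warn`` flags fits whose final Euclidean distance exceeds the
    quality bound expected of a well-specified sample (0.05 percentage
    points by default).
    """

    grid_min: float = 1e-4
    grid_max: float = 1.0
    grid_n: int = 60
    refine: bool = True
    distance_warn: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.grid_min < self.grid_max:
            raise ValueError("need 0 < grid_min < grid_max")
        if self.grid_n < 2:
            raise ValueError("grid_n must be >= 2")


@dataclass(frozen=True)
class FitResult:
    """Point estimates, fit quality, derived kinetics and (optional) CIs."""

    a_G_hat: float
    a_M_hat: float
    distance: float
    kinetics: DerivedKinetics
    boundary_flag: bool = False
    distance_flag: bool = False
    non_identifiable: bool = False
    ci_a_G: tuple[float, float] | None = None
    ci_a_M: tuple[float, float] | None = None
    ci_p: tuple[float, float] | None = None  # %/day
    se_p: float | None = None  # %/day
    cov: np.ndarray | None = None
    n_events: int | None = None


@dataclass(frozen=True)
class RateRegression:
    """OLS calibration of proliferation rate (fraction/day) on %EdU+ cells."""

    slope: float
    intercept: float
    r2: float


def _prepare_target(target: DotPlotSummary) -> DotPlotSummary:
    """Renormalise a gated triplet whose components miss 100 by > 0.5."""
    total = target.total
    if abs(total - 100.0) > 0.5:
        if total <= 0:
            raise ValueError("target triplet has non-positive total")
        logger.warning("target triplet sums to %.3f; renormalising to 100", total)
        f = 100.0 / total
        return DotPlotSummary(target.pct_G * f, target.pct_M * f, target.pct_labelled * f)
    return target


def _simulated_triplet(
    a_G: float, a_M: float, protocol: Protocol, sim_config: SimConfig
) -> np.ndarray:
    """Forward-simulate a sample under the hypotheses; return (%G, %M, %EdU+)."""
    rates, labeling = apply_hypotheses(a_G, a_M)
    initial = steady_state(rates).initial_state()
    traj = simulate(rates, labeling, protocol, initial, sim_config)
    return endpoint_summary(traj).as_array()


def objective(
    a_G: float,
    a_M: float,
    target: DotPlotSummary,
    protocol: Protocol | None = None,
    sim_config: SimConfig | None = None,
) -> float:
    """Euclidean distance (percent units) between simulated and observed triplets."""
    if protocol is None:
        protocol = default_study_protocol()
    if sim_config is None:
        sim_config = SimConfig()
    sim = _simulated_triplet(a_G, a_M, protocol, sim_config)
    return float(np.linalg.norm(sim - target.as_array()))


@lru_cache(maxsize=8)
def _grid_cache(
    grid_min: float, grid_max: float, grid_n: int,
    windows: tuple, dt_h: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Grid axes and their endpoint triplets, shared across fits of one design."""
    axis = np.logspace(math.log10(grid_min), math.log10(grid_max), grid_n)
    aG = np.repeat(axis, grid_n)   # a_G outer, a_M inner: argmin ties resolve
    aM = np.tile(axis, grid_n)     # to the lexicographically smallest pair
    triplets = _endpoint_batch_hypothesis(aG, aM, Protocol(windows), dt_h)
    return aG, aM, triplets


def _refine(
    a_G0: float, a_M0: float, target_arr: np.ndarray,
    protocol: Protocol, sim_config: SimConfig, fit_config: FitConfig,
) -> tuple[float, float, float]:
    lo, hi = math.log(fit_config.grid_min), math.log(fit_config.grid_max)

    def f(x: np.ndarray) -> float:
        if x[0] < lo or x[0] > hi or x[1] < lo or x[1] > hi:
            return 1e12
        sim = _simulated_triplet(math.exp(x[0]), math.exp(x[1]), protocol, sim_config)
        d = sim - target_arr
        return float(d @ d)

    res = minimize(
        f,
        np.log([a_G0, a_M0]),
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-18, "maxfev": 600},
    )
    a_G, a_M = math.exp(res.x[0]), math.exp(res.x[1])
    return a_G, a_M, math.sqrt(max(res.fun, 0.0))


def fit_sample(
    target: DotPlotSummary,
    protocol: Protocol | None = None,
    fit_config: FitConfig | None = None,
    sim_config: SimConfig | None = None,
) -> FitResult:
    """Grid search plus optional Nelder-Mead polish for one sample.

    Samples with no labelled cells are not identifiable in ``a_G``: the fit
    reports ``a_G`` at the lower box edge (an upper bound on the true rate)
    with ``boundary_flag`` set, rather than failing.  A fit whose final
    distance exceeds ``distance_warn`` is flagged, not rejected.
    """
    if protocol is None:
        protocol = default_study_protocol()
    if fit_config is None:
        fit_config = FitConfig()
    if sim_config is None:
        sim_config = SimConfig()
    target = _prepare_target(target)
    target_arr = target.as_array()

    aG_flat, aM_flat, triplets = _grid_cache(
        fit_config.grid_min, fit_config.grid_max, fit_config.grid_n,
        protocol.windows, sim_config.dt_h,
    )

    boundary = target.pct_labelled <= 0.0
    if boundary:
        # a_G -> 0 drives %EdU+ -> 0: pin a_G at the box floor (upper bound)
        a_G_hat = fit_config.grid_min
        mask = aG_flat == aG_flat.min()
        d = np.linalg.norm(triplets[mask] - target_arr, axis=1)
        a_M_hat = float(aM_flat[mask][int(np.argmin(d))])
        if fit_config.refine:
            lo, hi = math.log(fit_config.grid_min), math.log(fit_config.grid_max)
            res = minimize_scalar(
                lambda x: float(
                    np.sum((_simulated_triplet(a_G_hat, math.exp(x), protocol, sim_config)
                            - target_arr) ** 2)
                ),
                bounds=(lo, hi), method="bounded",
                options={"xatol": 1e-8},
            )
            a_M_hat = math.exp(res.x)
        distance = objective(a_G_hat, a_M_hat, target, protocol, sim_config)
    else:
        d = np.linalg.norm(triplets - target_arr, axis=1)
        best = int(np.argmin(d))
        a_G_hat, a_M_hat, distance = float(aG_flat[best]), float(aM_flat[best]), float(d[best])
        if fit_config.refine:
            a_G_hat, a_M_hat, distance = _refine(
                a_G_hat, a_M_hat, target_arr, protocol, sim_config, fit_config
            )
        edge = 1e-6
        if (
            a_G_hat <= fit_config.grid_min * (1 + edge)
            or a_G_hat >= fit_config.grid_max * (1 - edge)
            or a_M_hat <= fit_config.grid_min * (1 + edge)
            or a_M_hat >= fit_config.grid_max * (1 - edge)
        ):
            boundary = True

    distance_flag = distance > fit_config.distance_warn
    if distance_flag:
        logger.warning("fit distance %.4f exceeds %.4f", distance, fit_config.distance_warn)
    return FitResult(
        a_G_hat=a_G_hat,
        a_M_hat=a_M_hat,
        distance=distance,
        kinetics=derived_kinetics(a_G_hat, a_M_hat),
        boundary_flag=boundary,
        distance_flag=distance_flag,
    )


def _hessian_2d(f, x: np.ndarray, rel_step: float = 1e-3) -> np.ndarray:
    """Central-difference Hessian of a smooth scalar function of two variables."""
    h = np.maximum(rel_step * np.abs(x), 1e-8)
    H = np.empty((2, 2))
    f0 = f(x)
    for i in range(2):
        ei = np.zeros(2)
        ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h[i] ** 2
    e0 = np.array([h[0], 0.0])
    e1 = np.array([0.0, h[1]])
    H[0, 1] = H[1, 0] = (
        f(x + e0 + e1) - f(x + e0 - e1) - f(x - e0 + e1) + f(x - e0 - e1)
    ) / (4.0 * h[0] * h[1])
    return H


def confidence_intervals(
    fit: FitResult,
    target: DotPlotSummary,
    n_events: int,
    protocol: Protocol | None = None,
    fit_config: FitConfig | None = None,
    sim_config: SimConfig | None = None,
    level: float = 0.95,
) -> FitResult:
    """Wald confidence intervals from the Hessian of the weighted objective.

    The objective is the multinomially weighted least squares
    ``Q(theta) = n * sum_i (obs_i - mu_i(theta))^2 / mu_i(theta-hat)`` on
    the proportion scale, whose curvature at the optimum is the Fisher
    information of the gated triplet viewed as a multinomial draw of
    ``n_events`` cells.  The covariance is the inverse Hessian of ``Q/2``;
    intervals for the proliferation rate (reported in %/day) follow by the
    delta method with the analytic gradient of the closed-form rate.

    A singular or non-positive-definite Hessian marks the fit
    non-identifiable; the parameter intervals then span the search box.
    """
    if protocol is None:
        protocol = default_study_protocol()
    if fit_config is None:
        fit_config = FitConfig()
    if sim_config is None:
        sim_config = SimConfig()
    target = _prepare_target(target)
    obs = target.as_array() / 100.0

    theta_hat = np.array([fit.a_G_hat, fit.a_M_hat])
    mu_hat = _simulated_triplet(theta_hat[0], theta_hat[1], protocol, sim_config) / 100.0
    w = np.maximum(mu_hat, 1e-9)  # Pearson weights, fixed at the optimum

    def half_q(theta: np.ndarray) -> float:
        mu = _simulated_triplet(theta[0], theta[1], protocol, sim_config) / 100.0
        r = obs - mu
        return 0.5 * n_events * float(np.sum(r * r / w))

    H = _hessian_2d(half_q, theta_hat)
    z = _norm.ppf(0.5 + level / 2.0)
    try:
        eigvals = np.linalg.eigvalsh(H)
        if eigvals.min() <= 0:
            raise np.linalg.LinAlgError("Hessian not positive definite")
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        box = (fit_config.grid_min, fit_config.grid_max)
        return replace(
            fit, non_identifiable=True, ci_a_G=box, ci_a_M=box,
            ci_p=(0.0, derived_kinetics(box[1], box[1]).p_per_day),
            se_p=None, cov=None, n_events=n_events,
        )

    se = np.sqrt(np.diag(cov))
    gH, gM = proliferation_gradient(theta_hat[0], theta_hat[1])
    grad_p_day = 24.0 * np.array([gH, gM])
    se_p = float(np.sqrt(grad_p_day @ cov @ grad_p_day))
    p_day = fit.kinetics.p_per_day
    return replace(
        fit,
        ci_a_G=(theta_hat[0] - z * se[0], theta_hat[0] + z * se[0]),
        ci_a_M=(theta_hat[1] - z * se[1], theta_hat[1] + z * se[1]),
        ci_p=(p_day - z * se_p, p_day + z * se_p),
        se_p=se_p,
        cov=cov,
        n_events=n_events,
    )


def edu_to_rate(pct_edu: float) -> float:
    """Proliferation rate (fraction/day) from %EdU+ via the printed calibration.

    ``rate = -0.000884 + 0.0119 x`` with ``x`` the percentage of EdU+ cells
    on the 0-100 scale, valid for the default 16.5-h pulse-chase-pulse
    protocol.  Values outside [0, 100] extrapolate with a warning.
    """
    if not 0.0 <= pct_edu <= 100.0:
        warnings.warn(
            f"%EdU+ = {pct_edu} outside [0, 100]; extrapolating the calibration line",
            stacklevel=2,
        )
    return EDU_RATE_INTERCEPT + EDU_RATE_SLOPE * pct_edu


class DotPlotModel:
    """Model object for one gated sample.

    Parameters
    ----------
    target
        The gated triplet (:class:`~edupulse.simulate.DotPlotSummary` or a
        (pct_G, pct_M, pct_labelled) sequence in percent).
    protocol
        Labelling protocol; defaults to the 0/1/16-h injections design.
    n_events
        Number of gated live cells in the sample; enables confidence
        intervals.
    """

    def __init__(
        self,
        target,
        protocol: Protocol | None = None,
        n_events: int | None = None,
        fit_config: FitConfig | None = None,
        sim_config: SimConfig | None = None,
    ) -> None:
        if not isinstance(target, DotPlotSummary):
            g, m, lab = (float(v) for v in target)
            target = DotPlotSummary(g, m, lab)
        self.target = target
        self.protocol = protocol if protocol is not None else default_study_protocol()
        self.n_events = n_events
        self.fit_config = fit_config if fit_config is not None else FitConfig()
        self.sim_config = sim_config if sim_config is not None else SimConfig()

    @classmethod
    def from_row(cls, row: pd.Series, protocol: Protocol | None = None, **kwargs
                 ) -> "DotPlotModel":
        """Build from a sample-table row (pct_g_unlabelled, pct_m_unlabelled,
        pct_labelled, n_events columns)."""
        return cls(
            (row["pct_g_unlabelled"], row["pct_m_unlabelled"], row["pct_labelled"]),
            protocol=protocol,
            n_events=int(row["n_events"]) if "n_events" in row else None,
            **kwargs,
        )

    def loss(self, a_G: float, a_M: float) -> float:
        """Euclidean distance of the simulated triplet from this sample's data."""
        return objective(a_G, a_M, self.target, self.protocol, self.sim_config)

    def fit(self, compute_ci: bool | None = None) -> "DotPlotResults":
        """Run the grid + polish estimator; CIs when an event count is known."""
        res = fit_sample(self.target, self.protocol, self.fit_config, self.sim_config)
        if compute_ci is None:
            compute_ci = self.n_events is not None
        if compute_ci:
            if self.n_events is None:
                raise ValueError("n_events is required for confidence intervals")
            res = confidence_intervals(
                res, self.target, self.n_events, self.protocol,
                self.fit_config, self.sim_config,
            )
        return DotPlotResults(self, res)


class DotPlotResults:
    """Estimates, uncertainty and diagnostics of a :class:`DotPlotModel` fit."""

    def __init__(self, model: DotPlotModel, result: FitResult) -> None:
        self.model = model
        self._result = result

    # -- estimates ---------------------------------------------------------
    @property
    def params(self) -> np.ndarray:
        """(a_G, a_M) in per-hour units."""
        return np.array([self._result.a_G_hat, self._result.a_M_hat])

    @property
    def a_G(self) -> float:
        return self._result.a_G_hat

    @property
    def a_M(self) -> float:
        return self._result.a_M_hat

    @property
    def kinetics(self) -> DerivedKinetics:
        return self._result.kinetics

    @property
    def distance(self) -> float:
        return self._result.distance

    @property
    def boundary_flag(self) -> bool:
        return self._result.boundary_flag

    @property
    def result(self) -> FitResult:
        return self._result

    @property
    def bse(self) -> np.ndarray | None:
        cov = self._result.cov
        return None if cov is None else np.sqrt(np.diag(cov))

    def conf_int(self) -> pd.DataFrame | None:
        r = self._result
        if r.ci_a_G is None:
            return None
        return pd.DataFrame(
            [r.ci_a_G, r.ci_a_M, r.ci_p],
            index=["a_G (/h)", "a_M (/h)", "p (%/day)"],
            columns=["lower", "upper"],
        )

    def predict(self) -> DotPlotSummary:
        """Simulated triplet at the fitted parameters."""
        sim = _simulated_triplet(
            self.a_G, self.a_M, self.model.protocol, self.model.sim_config
        )
        return DotPlotSummary(*sim)

    def summary(self) -> str:
        r = self._result
        k = r.kinetics
        lines = [
            "EdU pulse-chase dot-plot fit",
            "=" * 46,
            f"target (%G, %M, %EdU+)   : ({self.model.target.pct_G:.2f}, "
            f"{self.model.target.pct_M:.2f}, {self.model.target.pct_labelled:.2f})",
            f"a_G (entry into S, /h)   : {r.a_G_hat:.6g}",
            f"a_M (entry into div, /h) : {r.a_M_hat:.6g}",
            f"Euclidean distance (%)   : {r.distance:.3e}",
            f"proliferation rate       : {k.p_per_day:.3f} %/day "
            f"({k.p_per_hour:.4f} %/h)",
            f"G0/G1 duration           : {k.g1_duration_h:.2f} h",
            f"S duration (fixed)       : {k.s_duration_h:.2f} h",
            f"G2/M duration            : {k.g2m_duration_h:.2f} h",
            f"inter-mitotic time       : {k.intermitotic_days:.2f} days",
        ]
        if r.ci_p is not None:
            lines.append(
                f"95% CI p (%/day)         : ({r.ci_p[0]:.3f}, {r.ci_p[1]:.3f})"
                + (f", SE = {r.se_p:.3f}" if r.se_p is not None else "")
            )
        flags = [
            name for name, on in [
                ("boundary", r.boundary_flag),
                (f"distance > {self.model.fit_config.distance_warn}", r.distance_flag),
                ("non-identifiable", r.non_identifiable),
            ] if on
        ]
        lines.append("flags                    : " + (", ".join(flags) if flags else "none"))
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<DotPlotResults a_G={self.a_G:.4g}/h a_M={self.a_M:.4g}/h "
            f"p={self.kinetics.p_per_day:.2f}%/day>"
        )


def fit_table(
    table: pd.DataFrame,
    protocol: Protocol | None = None,
    fit_config: FitConfig | None = None,
    sim_config: SimConfig | None = None,
    compute_ci: bool = True,
) -> pd.DataFrame:
    """Fit every row of a sample table; append estimate columns.

    Input columns: ``sample_id, strain, age_months, organ, population,
    n_events, pct_g_unlabelled, pct_m_unlabelled, pct_labelled`` (metadata
    columns are passed through untouched; only the three percentages and
    ``n_events`` are used).
    """
    rows = []
    for _, row in table.iterrows():
        model = DotPlotModel.from_row(
            row, protocol=protocol, fit_config=fit_config, sim_config=sim_config
        )
        res = model.fit(compute_ci=compute_ci and model.n_events is not None)
        r = res.result
        k = r.kinetics
        logger.info(
            "fit %s: a_G=%.5g a_M=%.5g dist=%.3e p=%.2f%%/day flags=%s%s",
            row.get("sample_id", "?"), r.a_G_hat, r.a_M_hat, r.distance, k.p_per_day,
            "B" if r.boundary_flag else "-", "D" if r.distance_flag else "-",
        )
        out = dict(row)
        out.update(
            a_g_per_h=r.a_G_hat,
            a_m_per_h=r.a_M_hat,
            distance=r.distance,
            p_pct_per_day=k.p_per_day,
            p_ci_low=r.ci_p[0] if r.ci_p else np.nan,
            p_ci_high=r.ci_p[1] if r.ci_p else np.nan,
            g1_h=k.g1_duration_h,
            g2m_h=k.g2m_duration_h,
            s_h=k.s_duration_h,
            intermitotic_days=k.intermitotic_days,
            boundary_flag=r.boundary_flag,
        )
        rows.append(out)
    return pd.DataFrame(rows)
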