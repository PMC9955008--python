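"""Adjustment for censoring of CoDMI imputations.

CoDMI assumes every COVID-death would have ended in a death of disease
(delta_j = 1). To relax this, the imputed data set is status-reversed and
re-fitted: the reverse Kaplan-Meier curve estimates the *censoring* time
distribution and yields alternative virtual lifetimes tau_j^(R). Each
imputation then keeps the direct estimate when the probability alpha(theta_j)
that an event at theta_j is a death (rather than a censoring) is at least
0.5, and takes the reverse estimate otherwise. Expert overrides take
precedence.

alpha(t) is estimated on the standard observations only, from direct and
reverse hazard rates fitted on a time grid: empirical per-cell hazards
(events / person-time) are smoothed by a parametric hazard family fitted by
exposure-weighted least squares on the log-hazard scale, and
alpha = h / (h + h_reverse) per cell.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .km import KaplanMeierEstimator
from .sample import SurvivalSample, order_sample, reverse_sample

__all__ = [
    "HazardGrid",
    "reverse_codmi_lifetimes",
    "AdjustedImputation",
    "reverse_km_lifetimes",
    "fit_grid_hazard",
    "alpha_curve",
    "adjust_for_censoring",
    "CensoringAdjuster",
]

logger = logging.getLogger(__name__)

FAMILIES = ("weibull", "gompertz", "exponential")


def reverse_km_lifetimes(w_hat, thetas) -> np.ndarray:
    """Reverse-KM virtual lifetimes tau^(R) from an imputed sample.

    All status indicators of ``w_hat`` are flipped (times unchanged), the
    KM estimator is fitted with completion, and tau_j^(R) = theta_j +
    e_theta_j is computed on the reverse death-mass distribution.
    """
    rev = reverse_sample(w_hat)
    km = KaplanMeierEstimator(complete=True).fit(rev)
    thetas = np.asarray(thetas, dtype=float)
    out = np.empty(len(thetas))
    for j, th in enumerate(thetas):
        try:
            out[j] = th + km.life_expectancy(th)
        except ValueError as exc:
            raise ValueError(f"reverse distribution, j={j} (theta={th}): {exc}") from exc
    return out


def reverse_codmi_lifetimes(
    z, thetas, tau_init, tolerance: float = 1.0, max_iter: int = 100
):
    """Self-consistent reverse virtual lifetimes for fully censored endpoints.

    When every imputation is classified as a censoring (alpha(theta_j) = 0
    for all j), the imputed records belong to the censoring-time
    distribution, and a single reverse-KM pass from the death-based CoDMI
    output is not self-consistent: the imputed records sit at death-based
    positions inside the reverse fit. This routine iterates the expectation
    step on the reverse side -- fit KM with completion on the status-reversed
    extended data (standard statuses flipped, imputed records non-events)
    and update tau_j = theta_j + e_theta_j from its death mass -- until the
    max change drops below ``tolerance``.

    Returns ``(tau, converged)``.
    """
    z = order_sample(z)
    thetas = np.asarray(thetas, dtype=float)
    tau = np.asarray(tau_init, dtype=float).copy()
    if len(thetas) == 0:
        return tau, True
    e_prev = tau - thetas
    zeros = np.zeros(len(thetas), dtype=np.int64)
    for _ in range(max_iter):
        wt = np.concatenate([z.times, tau])
        wd = np.concatenate([1 - z.status, zeros])
        km = KaplanMeierEstimator(complete=True).fit(SurvivalSample(wt, wd))
        e_new = np.array([km.life_expectancy(th) for th in thetas])
        tau = thetas + e_new
        if np.max(np.abs(e_new - e_prev)) < tolerance:
            return tau, True
        e_prev = e_new
    logger.warning("reverse self-consistent adjustment did not converge")
    return tau, False


@dataclass
class HazardGrid:
    """Direct and reverse hazards fitted on a time grid over [0, t_max]."""

    edges: np.ndarray
    h_direct: np.ndarray
    h_reverse: np.ndarray
    alpha: np.ndarray
    family: str
    events_direct: np.ndarray = None
    events_reverse: np.ndarray = None
    exposure: np.ndarray = None

    @property
    def n_cells(self) -> int:
        return len(self.edges) - 1

    def cell_of(self, t):
        """Index of the grid cell containing time t (clipped to the grid)."""
        t = np.asarray(t, dtype=float)
        return np.clip(np.searchsorted(self.edges, t, side="right") - 1, 0, self.n_cells - 1)

    def alpha_at(self, t):
        """Piecewise-constant alpha evaluated at time(s) t."""
        a = self.alpha[self.cell_of(t)]
        return a if np.ndim(t) else float(a)


def _cell_events_exposure(times, status, edges):
    """Events and person-time at risk per grid cell."""
    G = len(edges) - 1
    lo, hi = edges[:-1], edges[1:]
    t = times[:, None]
    events = (((t > lo) & (t <= hi)) * status[:, None]).sum(axis=0).astype(float)
    exposure = np.clip(np.minimum(t, hi) - lo, 0.0, None).sum(axis=0)
    return events, exposure


def _fit_family(mids, empirical, weights, family):
    """Weighted least squares on log-hazard; returns fitted hazard at mids.

    weibull:      log h = a + b log t   (h = exp(a) * t^b)
    gompertz:     log h = a + b t
    exponential:  log h = a
    Cells with zero empirical hazard or zero weight are excluded from the
    fit; the fitted curve still covers them.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown hazard family {family!r}; choose from {FAMILIES}")
    mask = (empirical > 0) & (weights > 0)
    if not mask.any():
        warnings.warn("all-zero empirical hazards; returning zero hazard curve")
        return np.zeros_like(mids)
    x = {"weibull": np.log(mids), "gompertz": mids, "exponential": np.zeros_like(mids)}[family]
    y = np.log(empirical[mask])
    w = np.sqrt(weights[mask])
    if family == "exponential" or mask.sum() < 2:
        a = float(np.average(y, weights=weights[mask]))
        return np.exp(a + 0.0 * mids)
    X = np.column_stack([np.ones(mask.sum()), x[mask]])
    beta, *_ = np.linalg.lstsq(X * w[:, None], y * w, rcond=None)
    return np.exp(beta[0] + beta[1] * x)


def fit_grid_hazard(sample, n_cells: int = 9, family: str = "weibull"):
    """Fit a parametric hazard on an equal-width grid over [0, t_max].

    Returns ``(edges, fitted, empirical, events, exposure)`` where
    ``fitted`` holds the family hazard evaluated at cell midpoints.
    """
    if n_cells < 2:
        raise ValueError("n_cells must be at least 2")
    s = order_sample(sample)
    if len(s) == 0 or s.times.max() <= 0:
        raise ValueError("sample must span positive time")
    edges = np.linspace(0.0, s.times.max(), n_cells + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    events, exposure = _cell_events_exposure(s.times, s.status, edges)
    with np.errstate(invalid="ignore"):
        empirical = np.where(exposure > 0, events / np.where(exposure > 0, exposure, 1.0), 0.0)
    fitted = _fit_family(mids, empirical, exposure, family)
    return edges, fitted, empirical, events, exposure


def alpha_curve(z, n_cells: int = 9, family: str = "weibull") -> HazardGrid:
    """Estimate the non-censoring probability curve alpha(t) from z.

    Fits the chosen hazard family to the direct data and to its status
    reverse on the same grid; alpha = h / (h + h_reverse) per cell, with
    alpha = 0.5 where both hazards vanish.
    """
    z = order_sample(z)
    edges, h_dir, _, ev_d, expo = fit_grid_hazard(z, n_cells, family)
    _, h_rev, _, ev_r, _ = fit_grid_hazard(reverse_sample(z), n_cells, family)
    denom = h_dir + h_rev
    both_zero = denom <= 0
    if both_zero.any():
        logger.warning(
            "alpha undefined (both hazards zero) in %d cell(s); using 0.5", both_zero.sum()
        )
    alpha = np.where(both_zero, 0.5, h_dir / np.where(both_zero, 1.0, denom))
    return HazardGrid(
        edges=edges,
        h_direct=h_dir,
        h_reverse=h_rev,
        alpha=alpha,
        family=family,
        events_direct=ev_d,
        events_reverse=ev_r,
        exposure=expo,
    )


@dataclass
class AdjustedImputation:
    """Per-imputation choice between direct and reverse virtual lifetimes."""

    tau_star: np.ndarray
    delta: np.ndarray
    alpha_at_theta: np.ndarray
    source: list

    def __len__(self):
        return len(self.tau_star)


def adjust_for_censoring(
    tau_direct, tau_reverse, alpha_at_theta, overrides=None
) -> AdjustedImputation:
    """Select direct or reverse lifetime per imputation.

    alpha >= 0.5 keeps the direct CoDMI estimate with delta = 1; alpha < 0.5
    takes the reverse-KM estimate with delta = 0. ``overrides`` is an
    optional mapping j -> delta (0 or 1) applied with precedence
    (source='override').
    """
    tau_d = np.asarray(tau_direct, dtype=float)
    tau_r = np.asarray(tau_reverse, dtype=float)
    alpha = np.asarray(alpha_at_theta, dtype=float)
    if not (len(tau_d) == len(tau_r) == len(alpha)):
        raise ValueError("tau_direct, tau_reverse and alpha_at_theta must have equal length")
    m = len(tau_d)
    delta = (alpha >= 0.5).astype(np.int64)
    source = ["direct" if d else "reverse" for d in delta]
    if overrides:
        for j, dj in overrides.items():
            j = int(j)
            if not 0 <= j < m:
                raise IndexError(f"override index {j} out of range for m={m}")
            if dj not in (0, 1):
                raise ValueError("override delta must be 0 or 1")
            delta[j] = dj
            source[j] = "override"
    tau_star = np.where(delta == 1, tau_d, tau_r)
    return AdjustedImputation(tau_star=tau_star, delta=delta, alpha_at_theta=alpha, source=source)


class CensoringAdjuster(BaseEstimator):
    """Estimator wrapper: learn alpha(t) from standard data, adjust imputations.

    Parameters
    ----------
    n_cells : int, default=9
        Number of equal-width grid cells over [0, t_max].
    family : {'weibull', 'gompertz', 'exponential'}, default='weibull'
        Parametric hazard family used to smooth the cell hazards.

    Attributes
    ----------
    grid_ : HazardGrid
    """

    def __init__(self, n_cells: int = 9, family: str = "weibull"):
        self.n_cells = n_cells
        self.family = family

    def fit(self, X, y=None):
        """Fit the alpha curve on the standard (non-imputed) observations."""
        self.grid_ = alpha_curve(order_sample(X), self.n_cells, self.family)
        return self

    def alpha(self, t):
        if not hasattr(self, "grid_"):
            raise AttributeError("this CensoringAdjuster instance is not fitted yet")
        return self.grid_.alpha_at(t)

    def adjust(self, w_hat, thetas, tau_direct, overrides=None) -> AdjustedImputation:
        """Apply the selection rule to a CoDMI output sample."""
        thetas = np.asarray(thetas, dtype=float)
        tau_reverse = reverse_km_lifetimes(w_hat, thetas)
        return adjust_for_censoring(tau_direct, tau_reverse, self.alpha(thetas), overrides)
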