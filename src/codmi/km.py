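"""Kaplan-Meier product-limit estimation with distribution completion.

The estimator here works *per record*: the at-risk count decrements by one
for every record, so tied times contribute one hazard factor each. The
resulting survival values coincide with the usual distinct-time product
(``(1 - 1/R)(1 - 1/(R-1))... = (R - d)/R``), but the per-record accounting
is what the downstream variance correction for imputed records requires.

Distribution completion: when the largest observation is censored the KM
curve ends at ``S(t_max) > 0`` and mean lifetimes are undefined. Completing
the distribution forces ``S(t_max) = 0`` by treating the single largest
record as a death, which places the residual mass ``Q_fin`` on ``t_max``.
The input sample is never mutated; the fit records that completion happened.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .sample import SurvivalSample, order_sample

__all__ = [
    "KaplanMeierEstimator",
    "fit_km",
    "life_expectancy",
    "greenwood_sd",
]


class KaplanMeierEstimator(BaseEstimator):
    """Product-limit estimator of the survival function S(t) = P(T >= t).

    Parameters
    ----------
    complete : bool, default=True
        If the largest observed time is censored, treat that single record
        as a death so that the fitted distribution integrates to 1. Required
        for life-expectancy computations.

    Attributes
    ----------
    times_ : ndarray of shape (n,)
        Ordered observation times (deaths before censorings at ties).
    status_ : ndarray of shape (n,)
        Status indicators after the (possible) completion flip.
    at_risk_ : ndarray of shape (n,)
        Number at risk immediately before each record; decrements by 1 per
        record.
    hazards_ : ndarray of shape (n,)
        Per-record hazard d_i / R_i.
    survival_ : ndarray of shape (n,)
        S immediately after each record (the running product).
    death_mass_ : ndarray of shape (n,)
        Probability mass q_i dropped at each record (0 at censorings).
    t_max_ : float
        Largest observed time.
    t_max_d_ : float
        Largest uncensored time in the *input* data (before completion).
    completed_ : bool
        Whether the completion flip was applied.
    q_fin_ : float
        Residual mass relocated to ``t_max_`` by completion (0 otherwise).
    """

    def __init__(self, complete: bool = True):
        self.complete = complete

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y=None):
        """Fit the product-limit estimator.

        ``X`` is an (n, 2) array of (time, status) records or a
        ``SurvivalSample``; ``y`` is ignored (sklearn API compatibility).
        """
        sample = order_sample(X)
        if len(sample) == 0:
            raise ValueError("cannot fit a Kaplan-Meier estimator on an empty sample")
        t = sample.times
        d = sample.status.copy()

        deaths = t[d == 1]
        self.t_max_ = float(t[-1])
        self.t_max_d_ = float(deaths[-1]) if deaths.size else np.nan

        self.completed_ = False
        self.q_fin_ = 0.0
        if self.complete and d[-1] == 0:
            d[-1] = 1
            self.completed_ = True

        n = len(t)
        R = np.arange(n, 0, -1, dtype=float)
        h = d / R
        S = np.cumprod(1.0 - h)
        S_prev = np.concatenate(([1.0], S[:-1]))
        q = S_prev - S

        self.n_ = n
        self.times_ = t
        self.status_ = d
        self.input_status_ = sample.status
        self.at_risk_ = R
        self.hazards_ = h
        self.survival_ = S
        self.death_mass_ = q
        if self.completed_:
            self.q_fin_ = float(q[-1])
        # suffix sums for fast truncated means
        self._suffix_q = np.concatenate([np.cumsum(q[::-1])[::-1], [0.0]])
        self._suffix_tq = np.concatenate([np.cumsum((t * q)[::-1])[::-1], [0.0]])
        return self

    def _check_fitted(self):
        if not hasattr(self, "times_"):
            raise AttributeError("this KaplanMeierEstimator instance is not fitted yet")

    # -- evaluation --------------------------------------------------------

    def survival_function(self, t, side: str = "left"):
        """Evaluate S at times ``t``.

        ``side='left'`` (default) gives the left-continuous value
        P(T >= t): at an event time the pre-jump value is returned.
        ``side='right'`` gives P(T > t), the value immediately after ``t``.
        """
        self._check_fitted()
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times_, t, side="left" if side == "left" else "right")
        S_ext = np.concatenate(([1.0], self.survival_))
        return S_ext[idx] if t.ndim else float(S_ext[idx])

    def predict(self, t):
        """Alias for ``survival_function(t, side='left')``."""
        return self.survival_function(t)

    def life_expectancy(self, theta: float) -> float:
        """Mean residual lifetime beyond ``theta`` on the truncated distribution.

        e_theta = sum_{t_i > theta} (t_i - theta) q_i / sum_{t_i > theta} q_i,
        with strict truncation. Requires a completed distribution (total
        death mass 1) and positive mass strictly beyond ``theta``.
        """
        self._check_fitted()
        total = self.death_mass_.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                "life expectancy requires a completed distribution "
                f"(total death mass {total:.6f} != 1); fit with complete=True"
            )
        idx = np.searchsorted(self.times_, theta, side="right")
        denom = self._suffix_q[idx]
        if denom <= 0.0:
            raise ValueError(f"no death mass strictly beyond theta={theta!r}")
        num = self._suffix_tq[idx] - theta * denom
        return float(num / denom)

    def greenwood_sd(self, t: float) -> float:
        """Classical Greenwood standard deviation of S at time ``t``.

        s.d. = S(t) * sqrt(sum_{t_i <= t} h_i / ((1 - h_i) R_i)), with the
        summand set to 0 where h_i = 1.
        """
        self._check_fitted()
        if t < 0:
            raise ValueError("t must be non-negative")
        idx = np.searchsorted(self.times_, t, side="right")
        h = self.hazards_[:idx]
        R = self.at_risk_[:idx]
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(h < 1.0, h / ((1.0 - h) * R), 0.0)
        S = self.survival_function(t, side="right")
        return float(S * np.sqrt(terms.sum()))

    def confidence_interval(self, t: float, level: float = 0.95):
        """Greenwood-based CI on the log scale, clamped to [0, 1]."""
        S = self.survival_function(t, side="right")
        sd = self.greenwood_sd(t)
        return log_scale_ci(S, sd, level)

    def summary(self):
        """Distinct-time table: time, at risk, events, censored, survival."""
        import pandas as pd

        self._check_fitted()
        ut, inv = np.unique(self.times_, return_inverse=True)
        events = np.bincount(inv, weights=self.status_)
        cens = np.bincount(inv, weights=1 - self.status_)
        at_risk = [self.at_risk_[np.searchsorted(self.times_, u, side="left")] for u in ut]
        surv = [self.survival_function(u, side="right") for u in ut]
        return pd.DataFrame(
            {
                "time": ut,
                "at_risk": np.asarray(at_risk, dtype=int),
                "events": events.astype(int),
                "censored": cens.astype(int),
                "survival": surv,
            }
        )


def log_scale_ci(S: float, sd: float, level: float = 0.95):
    """CI for S from bounds on log S: exp(log S +/- z * sd / S), in [0, 1]."""
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if S == 0.0:
        return (0.0, 0.0)
    if not 0.0 < S <= 1.0:
        raise ValueError("S must lie in (0, 1]")
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * sd / S
    lo = float(np.clip(np.exp(np.log(S) - half), 0.0, 1.0))
    hi = float(np.clip(np.exp(np.log(S) + half), 0.0, 1.0))
    return (lo, hi)


# -- thin functional wrappers ---------------------------------------------


def fit_km(sample, complete: bool = True) -> KaplanMeierEstimator:
    """Fit a :class:`KaplanMeierEstimator` on a sample."""
    return KaplanMeierEstimator(complete=complete).fit(sample)


def life_expectancy(fit: KaplanMeierEstimator, theta: float) -> float:
    return fit.life_expectancy(theta)


def greenwood_sd(fit: KaplanMeierEstimator, t: float) -> float:
    return fit.greenwood_sd(t)
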