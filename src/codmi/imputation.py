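"""CoDMI: Covid-Death Mean-Imputation by EM iteration.

Each COVID-death observation theta_j is a lifetime observed only up to the
intervening event; CoDMI replaces it by the virtual lifetime
tau_j = theta_j + e_theta_j, where e_theta_j is the mean residual lifetime
under the Kaplan-Meier distribution fitted to the standard data *plus the
imputed records themselves*. Iterating estimation (KM fit with completion)
and expectation (truncated-mean imputation) to a fixed point is an EM-style
scheme; the algorithm is deterministic.

Convergence: stop when max_j |e^(k+1)_j - e^(k)_j| < tolerance. The first
comparison is made against the expectancies implied by the initializer
(zero for at-theta initialization). One iteration = one estimation +
expectation sweep; initialization is not counted.

Cyclicity: the iteration can enter a repeating cycle instead of converging.
With cycle detection on, iterates (rounded for hashing) are remembered; on
recurrence the iterate with the smallest successive change inside the cycle
is returned, accepted when that change is below tolerance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .km import KaplanMeierEstimator
from .sample import SurvivalSample, order_sample

__all__ = ["CoDMIImputer", "CodmiResult", "run_codmi", "initialize", "em_step"]

logger = logging.getLogger(__name__)

CONVERGED = "converged"
CYCLE_ACCEPTED = "cycle_accepted"
FAILED = "failed"


@dataclass
class CodmiResult:
    """Outcome of a CoDMI run.

    tau_hat / e_hat are the imputed virtual lifetimes and residual life
    expectancies per COVID observation; ``imputed_sample`` is the completed
    data set w = z union {(tau_j, 1)}.
    """

    theta: np.ndarray
    tau_hat: np.ndarray
    e_hat: np.ndarray
    iterations: int
    status: str
    trajectory: list = field(repr=False)
    imputed_sample: SurvivalSample = None

    @property
    def converged(self) -> bool:
        return self.status in (CONVERGED, CYCLE_ACCEPTED)


def _expectancies(times, status, thetas):
    """Life expectancies beyond each theta under the completed KM fit."""
    km = KaplanMeierEstimator(complete=True).fit(
        SurvivalSample(times, status)
    )
    out = np.empty(len(thetas))
    for j, th in enumerate(thetas):
        try:
            out[j] = km.life_expectancy(th)
        except ValueError as exc:
            raise ValueError(
                f"COVID observation j={j} (theta={th}): {exc}"
            ) from exc
    return out


def initialize(z, covid_times, mode: str = "expectancy") -> np.ndarray:
    """Initial virtual lifetimes tau^(0).

    ``mode='at_theta'``: tau_j = theta_j. ``mode='expectancy'``
    (or 'theta_plus_expectancy'): tau_j = theta_j + e_theta_j computed from
    the standard data z alone (KM with completion).
    """
    z = order_sample(z)
    thetas = np.asarray(covid_times, dtype=float)
    if thetas.size and thetas.min() <= 0:
        raise ValueError("COVID-death times must be strictly positive")
    if thetas.size == 0:
        return thetas.copy()
    if mode == "at_theta":
        return thetas.copy()
    if mode in ("expectancy", "theta_plus_expectancy"):
        return thetas + _expectancies(z.times, z.status, thetas)
    raise ValueError(f"unknown init mode {mode!r}")


def em_step(z, covid_times, tau_current) -> np.ndarray:
    """One estimation + expectation sweep: returns tau^(k+1).

    Builds w = z union {(tau_j, 1)}, fits KM with completion, and returns
    theta_j + e_theta_j from the fitted death-mass distribution.
    """
    z = order_sample(z)
    thetas = np.asarray(covid_times, dtype=float)
    tau = np.asarray(tau_current, dtype=float)
    if thetas.size == 0:
        return thetas.copy()
    wt = np.concatenate([z.times, tau])
    wd = np.concatenate([z.status, np.ones(len(tau), dtype=np.int64)])
    return thetas + _expectancies(wt, wd, thetas)


class CoDMIImputer(BaseEstimator):
    """EM mean-imputer for COVID-death times in right-censored survival data.

    Parameters
    ----------
    tolerance : float, default=0.1
        Convergence tolerance epsilon (days) on the max change of the
        imputed life expectancies between sweeps.
    max_iter : int, default=100
        Maximum number of estimation+expectation sweeps.
    init : {'expectancy', 'at_theta'}, default='expectancy'
        Initialization of the virtual lifetimes.
    cycle_detection : bool, default=True
        Detect repeating iterates and accept the best point of the cycle
        when its successive change is within tolerance.
    round_decimals : int, default=6
        Rounding used when hashing iterates for cycle detection.

    Attributes (after fit)
    ----------------------
    theta_, tau_hat_, e_hat_ : ndarray of shape (m,)
    n_iter_ : int                 number of expectation sweeps performed
    status_ : str                 'converged' | 'cycle_accepted' | 'failed'
    trajectory_ : list of ndarray per-sweep e-vectors
    imputed_times_, imputed_status_ : the ordered w data set
    is_imputed_ : bool mask over the ordered w records
    result_ : CodmiResult
    """

    def __init__(
        self,
        tolerance: float = 0.1,
        max_iter: int = 100,
        init: str = "expectancy",
        cycle_detection: bool = True,
        round_decimals: int = 6,
    ):
        self.tolerance = tolerance
        self.max_iter = max_iter
        self.init = init
        self.cycle_detection = cycle_detection
        self.round_decimals = round_decimals

    def fit(self, X, covid_times=(), y=None):
        """Run CoDMI on standard data ``X`` with the given COVID-death times."""
        if not self.tolerance > 0:
            raise ValueError("tolerance must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be at least 1")
        z = order_sample(X)
        thetas = np.asarray(covid_times, dtype=float)
        result = run_codmi(
            z,
            thetas,
            tolerance=self.tolerance,
            max_iter=self.max_iter,
            init=self.init,
            cycle_detection=self.cycle_detection,
            round_decimals=self.round_decimals,
        )
        self.theta_ = result.theta
        self.tau_hat_ = result.tau_hat
        self.e_hat_ = result.e_hat
        self.n_iter_ = result.iterations
        self.status_ = result.status
        self.trajectory_ = result.trajectory
        self.result_ = result
        w = result.imputed_sample
        self.imputed_times_ = w.times
        self.imputed_status_ = w.status
        order = np.lexsort((1 - w.status, w.times))
        flags = np.concatenate(
            [np.zeros(len(z), dtype=bool), np.ones(len(thetas), dtype=bool)]
        )
        self.is_imputed_ = flags[order]
        # expose w in ordered form
        self.imputed_times_ = w.times[order]
        self.imputed_status_ = w.status[order]
        return self

    def transform(self, X=None):
        """Return the imputed data set w as an (n+m, 2) array."""
        if not hasattr(self, "tau_hat_"):
            raise AttributeError("this CoDMIImputer instance is not fitted yet")
        return np.column_stack([self.imputed_times_, self.imputed_status_.astype(float)])

    def fit_transform(self, X, covid_times=(), y=None):
        return self.fit(X, covid_times).transform()


def _best_cycle_iterate(trajectory, start: int):
    """Index (within trajectory) of the cycle iterate with minimal successive
    change, and that change. Earliest occurrence wins ties.

    ``trajectory`` includes the initial implied e-vector at position 0; the
    cycle spans positions start..len-1 where the last entry repeats the one
    at ``start``.
    """
    best_idx, best_change = None, np.inf
    for k in range(max(start, 1), len(trajectory)):
        change = float(np.max(np.abs(trajectory[k] - trajectory[k - 1])))
        if change < best_change:
            best_idx, best_change = k, change
    return best_idx, best_change


def run_codmi(
    z,
    covid_times,
    tolerance: float = 0.1,
    max_iter: int = 100,
    init: str = "expectancy",
    cycle_detection: bool = True,
    round_decimals: int = 6,
) -> CodmiResult:
    """Functional CoDMI driver; see :class:`CoDMIImputer` for semantics."""
    z = order_sample(z)
    thetas = np.asarray(covid_times, dtype=float)
    m = len(thetas)

    if m == 0:
        return CodmiResult(
            theta=thetas,
            tau_hat=thetas.copy(),
            e_hat=thetas.copy(),
            iterations=0,
            status=CONVERGED,
            trajectory=[],
            imputed_sample=z,
        )

    tau = initialize(z, thetas, init)
    e_prev = tau - thetas
    trajectory = [e_prev.copy()]
    # the hashing quantum must resolve changes at the tolerance scale,
    # otherwise slow asymptotic convergence masquerades as a 1-cycle
    decimals = max(round_decimals, int(np.ceil(-np.log10(tolerance))) + 2)
    seen = {tuple(np.round(e_prev, decimals)): 0}

    status = FAILED
    n_iter = 0
    e_final, tau_final = e_prev, tau
    for k in range(1, max_iter + 1):
        tau_new = em_step(z, thetas, tau)
        e_new = tau_new - thetas
        n_iter = k
        trajectory.append(e_new.copy())
        change = float(np.max(np.abs(e_new - e_prev)))
        if change < tolerance:
            status = CONVERGED
            e_final, tau_final = e_new, tau_new
            break
        if cycle_detection:
            key = tuple(np.round(e_new, decimals))
            if key in seen:
                idx, best_change = _best_cycle_iterate(trajectory, seen[key])
                e_final = trajectory[idx]
                tau_final = thetas + e_final
                status = CYCLE_ACCEPTED if best_change < tolerance else FAILED
                logger.warning(
                    "CoDMI cycle detected at sweep %d (period %d); minimal "
                    "successive change %.6g -> %s",
                    k, k - seen[key], best_change, status,
                )
                break
            seen[key] = len(trajectory) - 1
        e_prev, tau = e_new, tau_new
    else:
        e_final, tau_final = e_prev, tau
        logger.warning("CoDMI failed to converge within %d iterations", max_iter)

    wt = np.concatenate([z.times, tau_final])
    wd = np.concatenate([z.status, np.ones(m, dtype=np.int64)])
    logger.info(
        "CoDMI finished: status=%s iterations=%d tolerance=%g", status, n_iter, tolerance
    )
    return CodmiResult(
        theta=thetas,
        tau_hat=tau_final,
        e_hat=e_final,
        iterations=n_iter,
        status=status,
        trajectory=trajectory[1:],
        imputed_sample=SurvivalSample(wt, wd),
    )
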