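"""Right-censored survival samples.

A sample is a set of records ``(t_i, d_i)`` where ``t_i >= 0`` is the
observed time (days) and ``d_i`` is the status indicator: 1 for a death of
the disease under study (DoD), 0 for a censoring (Cen).

The ordering convention used throughout the package: records are sorted by
non-decreasing time and, at tied times, deaths precede censorings (a
censored subject at ``t`` is still at risk for a death occurring at ``t``).
Ties among records of the same status keep input order (stable sort).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SurvivalSample", "order_sample", "reverse_sample"]


def _as_time_status(times, status=None):
    """Coerce input into validated (times, status) float/int arrays.

    Accepts an ``(n, 2)`` array, a pair of 1-d arrays, or a sequence of
    ``(time, status)`` pairs.
    """
    if status is None:
        arr = np.asarray(times, dtype=float)
        if arr.size == 0:
            return np.empty(0), np.empty(0, dtype=np.int64)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError(
                f"expected an (n, 2) array of (time, status) records, got shape {arr.shape}"
            )
        t, d = arr[:, 0], arr[:, 1]
    else:
        t = np.asarray(times, dtype=float)
        d = np.asarray(status, dtype=float)
        if t.shape != d.shape or t.ndim != 1:
            raise ValueError("times and status must be 1-d arrays of equal length")
    if np.any(t < 0) or np.any(~np.isfinite(t)):
        raise ValueError("survival times must be finite and non-negative")
    di = d.astype(np.int64)
    if np.any(di != d) or np.any((di != 0) & (di != 1)):
        raise ValueError("status indicators must be 0 (censoring) or 1 (death)")
    return t, di


@dataclass(frozen=True)
class SurvivalSample:
    """An ordered collection of right-censored survival records.

    Parameters
    ----------
    times : ndarray of shape (n,)
        Observed times, non-negative.
    status : ndarray of shape (n,)
        1 = death of disease, 0 = censoring.

    The constructor validates but does not reorder; use :meth:`ordered`
    (or :func:`order_sample`) to apply the tie convention.
    """

    times: np.ndarray
    status: np.ndarray
    tie_convention: str = field(default="deaths-before-censorings", compare=False)

    def __post_init__(self):
        t, d = _as_time_status(self.times, self.status)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "status", d)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def n_deaths(self) -> int:
        return int(self.status.sum())

    @property
    def n_censored(self) -> int:
        return int(len(self) - self.status.sum())

    def ordered(self) -> "SurvivalSample":
        """Sorted copy: time ascending, deaths before censorings at ties."""
        idx = np.lexsort((1 - self.status, self.times))
        return SurvivalSample(self.times[idx], self.status[idx])

    def reversed(self) -> "SurvivalSample":
        """Status-reversed copy (d -> 1 - d); times unchanged."""
        return SurvivalSample(self.times, 1 - self.status)

    def to_array(self) -> np.ndarray:
        return np.column_stack([self.times, self.status.astype(float)])

    @classmethod
    def from_records(cls, records) -> "SurvivalSample":
        t, d = _as_time_status(records)
        return cls(t, d)


def order_sample(records) -> SurvivalSample:
    """Order records by increasing time, deaths first within ties.

    ``records`` may be a SurvivalSample, an (n, 2) array, or a sequence of
    ``(time, status)`` pairs. Negative times raise ``ValueError``.
    """
    if isinstance(records, SurvivalSample):
        return records.ordered()
    return SurvivalSample.from_records(records).ordered()


def reverse_sample(sample) -> SurvivalSample:
    """Flip every status indicator, keeping times fixed (an involution)."""
    if not isinstance(sample, SurvivalSample):
        sample = SurvivalSample.from_records(sample)
    return sample.reversed()
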