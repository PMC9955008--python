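"""Embedded NCOG head/neck cancer survival data and CSV input/output.

The two arms of the North California Oncology Group study (survival in days
from study entry; a trailing ``+`` in the published tables marks censoring)
are shipped verbatim as package fixtures, together with the evenly spaced
artificial COVID-death time points used in the worked examples.

Arm A (chemotherapy): 51 records, 42 deaths, 9 censorings, t_max = 1417
(uncensored). Arm B (chemotherapy + radiation): 45 records, 31 deaths,
14 censorings, t_max = 2297 (censored), last death at 1776.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sample import SurvivalSample

__all__ = [
    "DatasetBundle",
    "load_fixture",
    "read_survival_csv",
    "write_survival_csv",
    "export_step_function",
]

logger = logging.getLogger(__name__)

# NCOG arm A, chemotherapy. "+" entries resolved into status 0.
_ARM_A = [
    (7, 1), (34, 1), (42, 1), (63, 1), (64, 1), (74, 0), (83, 1), (84, 1), (91, 1),
    (108, 1), (112, 1), (129, 1), (133, 1), (133, 1), (139, 1), (140, 1), (140, 1), (146, 1),
    (149, 1), (154, 1), (157, 1), (160, 1), (160, 1), (165, 1), (173, 1), (176, 1), (185, 0),
    (218, 1), (225, 1), (241, 1), (248, 1), (273, 1), (277, 1), (279, 0), (297, 1), (319, 0),
    (405, 1), (417, 1), (420, 1), (440, 1), (523, 1), (523, 0), (583, 1), (594, 1), (1101, 1),
    (1116, 0), (1146, 1), (1226, 0), (1349, 0), (1412, 0), (1417, 1),
]

# NCOG arm B, chemotherapy + radiation.
_ARM_B = [
    (37, 1), (84, 1), (92, 1), (94, 1), (110, 1), (112, 1), (119, 1), (127, 1), (130, 1),
    (133, 1), (140, 1), (146, 1), (155, 1), (159, 1), (169, 0), (173, 1), (179, 1), (194, 1),
    (195, 1), (209, 1), (249, 1), (281, 1), (319, 1), (339, 1), (432, 1), (469, 1), (519, 1),
    (528, 0), (547, 0), (613, 0), (633, 1), (725, 1), (759, 0), (817, 1), (1092, 0), (1245, 0),
    (1331, 0), (1557, 1), (1642, 0), (1771, 0), (1776, 1), (1897, 0), (2023, 0), (2146, 0),
    (2297, 0),
]

# Worked-example COVID-death time points (roughly 10% of n, evenly spaced).
_COVID_TIMES = {"arm_a": (250.0, 500.0, 750.0, 1000.0, 1250.0),
                "arm_b": (400.0, 800.0, 1200.0, 1600.0, 2000.0)}


@dataclass(frozen=True)
class DatasetBundle:
    """Standard observations plus the COVID-death times attached to them."""

    standard: SurvivalSample
    covid_times: tuple
    label: str


def load_fixture(name: str) -> DatasetBundle:
    """Load an embedded NCOG arm by name ('arm_a' or 'arm_b')."""
    tables = {"arm_a": _ARM_A, "arm_b": _ARM_B}
    if name not in tables:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(tables)}")
    sample = SurvivalSample.from_records(tables[name]).ordered()
    return DatasetBundle(standard=sample, covid_times=_COVID_TIMES[name], label=name)


def read_survival_csv(path) -> SurvivalSample:
    """Read (time, status) records from CSV with a ``time,status`` header.

    An optional ``is_imputed`` column is tolerated and ignored. Malformed
    rows raise with their line number; an empty body yields an empty sample
    with a warning.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"time", "status"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}, got {list(df.columns)}")
    if len(df) == 0:
        logger.warning("%s: no data rows, returning empty sample", path)
        return SurvivalSample(np.empty(0), np.empty(0, dtype=np.int64))
    times = pd.to_numeric(df["time"], errors="coerce")
    status = pd.to_numeric(df["status"], errors="coerce")
    for col, vals in (("time", times), ("status", status)):
        bad = np.flatnonzero(vals.isna().to_numpy())
        if bad.size:
            raise ValueError(f"{path}, line {bad[0] + 2}: malformed {col} value {df[col].iloc[bad[0]]!r}")
    st = status.to_numpy()
    bad = np.flatnonzero((st != 0) & (st != 1))
    if bad.size:
        raise ValueError(f"{path}, line {bad[0] + 2}: status must be 0 or 1, got {st[bad[0]]!r}")
    return SurvivalSample(times.to_numpy(dtype=float), st.astype(np.int64))


def write_survival_csv(sample: SurvivalSample, path, is_imputed=None) -> None:
    """Write records as CSV at full precision (round-trip exact)."""
    cols = {"time": sample.times, "status": sample.status}
    if is_imputed is not None:
        cols["is_imputed"] = np.asarray(is_imputed, dtype=int)
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def export_step_function(km, path) -> None:
    """Write the fitted survival step function as (t, survival) CSV rows.

    Starts at (0, 1) and records the post-jump value at each distinct time.
    """
    ut = np.unique(km.times_)
    rows = {"t": np.concatenate([[0.0], ut]),
            "survival": np.concatenate([[1.0], [km.survival_function(u, side="right") for u in ut]])}
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")
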