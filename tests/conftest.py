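import numpy as np
import pytest

from codmi import SurvivalSample, load_fixture


@pytest.fixture(scope="session")
def arm_a():
    return load_fixture("arm_a")


@pytest.fixture(scope="session")
def arm_b():
    return load_fixture("arm_b")


@pytest.fixture
def toy_mixed():
    """Four records (1,1),(2,0),(3,1),(4,0): one death, censor, death, censor."""
    return SurvivalSample(np.array([1.0, 2.0, 3.0, 4.0]), np.array([1, 0, 1, 0]))


def brute_force_product_limit(records, complete=True):
    """Independent product-limit oracle: explicit loop, per-record at-risk.

    Returns (times, status, masses, survival_after_each_record) for records
    ordered by (time, deaths-first).
    """
    recs = sorted(
        [(float(t), int(d)) for t, d in records], key=lambda r: (r[0], -r[1])
    )
    if complete and recs and recs[-1][1] == 0:
        recs[-1] = (recs[-1][0], 1)
    n = len(recs)
    S = 1.0
    out_t, out_d, out_q, out_S = [], [], [], []
    for i, (t, d) in enumerate(recs):
        at_risk = n - i
        drop = S * d / at_risk
        S = S - drop
        out_t.append(t)
        out_d.append(d)
        out_q.append(drop)
        out_S.append(S)
    return (
        np.array(out_t),
        np.array(out_d),
        np.array(out_q),
        np.array(out_S),
    )


@pytest.fixture
def km_oracle():
    return brute_force_product_limit
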