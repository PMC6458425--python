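import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_instruments(beta_exp, se_exp, beta_out, se_out) -> pd.DataFrame:
    """Build a harmonized-instrument table from plain arrays."""
    return pd.DataFrame(
        {
            "snp": [f"rs{i}" for i in range(len(beta_exp))],
            "beta_exp": np.asarray(beta_exp, float),
            "se_exp": np.asarray(se_exp, float),
            "beta_out": np.asarray(beta_out, float),
            "se_out": np.asarray(se_out, float),
        }
    )


@pytest.fixture
def instruments_factory():
    return make_instruments


@pytest.fixture
def random_instruments():
    """Seeded generator of random small instrument sets (positive beta_exp)."""

    def gen(rng: np.random.Generator, k: int) -> pd.DataFrame:
        return make_instruments(
            beta_exp=rng.uniform(0.02, 0.3, k),
            se_exp=rng.uniform(0.005, 0.05, k),
            beta_out=rng.normal(0, 0.05, k),
            se_out=rng.uniform(0.005, 0.05, k),
        )

    return gen


# ---------------------------------------------------------------- oracles
def wls_zero_intercept_oracle(bx, by, w):
    """Zero-intercept weighted least squares by the normal equations."""
    bx, by, w = (np.asarray(a, float) for a in (bx, by, w))
    return float(np.sum(w * bx * by) / np.sum(w * bx**2))


def wls_intercept_oracle(bx, by, w):
    """Weighted least squares with intercept: solve the 2×2 normal equations."""
    bx, by, w = (np.asarray(a, float) for a in (bx, by, w))
    A = np.array([[np.sum(w), np.sum(w * bx)], [np.sum(w * bx), np.sum(w * bx**2)]])
    rhs = np.array([np.sum(w * by), np.sum(w * bx * by)])
    intercept, slope = np.linalg.solve(A, rhs)
    return float(slope), float(intercept)


def weighted_median_oracle(ratios, weights):
    """Cumulative-weight interpolation at 0.5, written as an explicit loop."""
    pairs = sorted(zip(ratios, weights), key=lambda p: p[0])
    total = sum(w for _, w in pairs)
    cum = 0.0
    mids = []
    for r, w in pairs:
        mids.append((r, (cum + w / 2) / total))
        cum += w
    if mids[0][1] >= 0.5:
        return mids[0][0]
    for (r0, c0), (r1, c1) in zip(mids, mids[1:]):
        if c0 < 0.5 <= c1:
            return r0 + (r1 - r0) * (0.5 - c0) / (c1 - c0)
    return mids[-1][0]
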