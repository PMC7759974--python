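"""Shared fixtures: small synthetic records and the two session-scoped
cohorts used by the end-to-end checks (computing their feature matrices is
the expensive part, so they are built once per session)."""

from __future__ import annotations

import numpy as np
import pytest

from gaitmse.classify import cohort_features
from gaitmse.simulate import GaitClassParams, make_cohort, simulate_gait_record


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def short_record():
    """One 80-s record at 300 Hz (11 ten-second windows after trimming)."""
    params = GaitClassParams(label="HC", period_cv=0.05)
    return simulate_gait_record(params, duration_s=80.0, fs=300.0, seed=5, subject_id="HC01")


@pytest.fixture(scope="session")
def small_cohort():
    """Two well-separated classes, 3 subjects each, 70-s records: enough
    windows for 5-fold CV while staying cheap."""
    spec = [
        (GaitClassParams(label="LOW", period_cv=0.02), 3),
        (GaitClassParams(label="HIGH", period_cv=0.25), 3),
    ]
    records, manifest = make_cohort(spec, duration_s=70.0, fs=300.0, seed=11)
    return records, manifest


@pytest.fixture(scope="session")
def small_cohort_features(small_cohort):
    records, _ = small_cohort
    return cohort_features(records, tw_s=10.0)


@pytest.fixture(scope="session")
def recovery_cohort_features():
    """The stride-variability recovery cohort: two classes differing only
    in stride-period CV (0.02 vs 0.20), 8 subjects each, 5-min records at
    300 Hz, featurized at the 10-s window length."""
    spec = [
        (GaitClassParams(label="LOW", period_cv=0.02), 8),
        (GaitClassParams(label="HIGH", period_cv=0.20), 8),
    ]
    records, _ = make_cohort(spec, duration_s=300.0, fs=300.0, seed=42)
    return cohort_features(records, tw_s=10.0)


@pytest.fixture(scope="session")
def null_cohort_features():
    """Null-calibration cohort: both classes share identical generator
    parameters, so no window feature carries class information."""
    params = dict(period_cv=0.06)
    spec = [
        (GaitClassParams(label="A", **params), 10),
        (GaitClassParams(label="B", **params), 10),
    ]
    records, _ = make_cohort(spec, duration_s=150.0, fs=300.0, seed=1042)
    return cohort_features(records, tw_s=10.0)


def sampen_bruteforce(x, m: int, r_abs: float) -> float:
    """Naive O(N²) sample-entropy oracle: explicit double loop over the
    first N−m templates, Chebyshev distance, self-matches excluded."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    n_t = n - m
    b = a = 0
    for i in range(n_t):
        for j in range(n_t):
            if i == j:
                continue
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r_abs:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r_abs:
                    a += 1
    if b == 0 or a == 0:
        return float("nan")
    return float(-np.log(a / b))
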