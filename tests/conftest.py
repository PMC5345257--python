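"""Shared fixtures: random tables and an independent likelihood oracle."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import brentq, minimize_scalar
from scipy.special import expit, xlogy

from grm_assoc import GenotypeCounts


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_tables(rng, n_tables, low=1, high=400):
    """All-positive random 2x3 tables."""
    out = []
    for _ in range(n_tables):
        cases = tuple(int(v) for v in rng.integers(low, high, size=3))
        controls = tuple(int(v) for v in rng.integers(low, high, size=3))
        out.append(GenotypeCounts(cases, controls))
    return out


def brute_force_loglik(counts: GenotypeCounts, codes) -> tuple[float, float, float]:
    """Independent maximisation of the one-slope grouped binomial likelihood.

    Profiles the intercept out exactly (1-d root of the intercept score via
    bracketed root-finding) and maximises over the slope by bounded scalar
    search; shares no code with the package's Newton-Raphson fitter.
    Returns (beta, alpha, max log-likelihood).
    """
    y, n = counts.as_arrays()
    x = np.asarray(codes, dtype=float)

    def profiled(beta):
        def intercept_score(a):
            return float((y - n * expit(a + beta * x)).sum())

        a = brentq(intercept_score, -50.0, 50.0, xtol=1e-13)
        eta = a + beta * x
        ll = float((y * eta - n * np.logaddexp(0.0, eta)).sum())
        return ll, a

    res = minimize_scalar(
        lambda b: -profiled(b)[0], bounds=(-15.0, 15.0), method="bounded",
        options={"xatol": 1e-12},
    )
    ll, a = profiled(res.x)
    return float(res.x), a, ll


def g_statistic(counts: GenotypeCounts) -> float:
    """Closed-form 2x3 G-statistic 2*sum O*ln(O/E), the grm oracle."""
    obs = np.array([counts.case_counts, counts.control_counts], dtype=float)
    expected = obs.sum(axis=1, keepdims=True) * obs.sum(axis=0) / obs.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = xlogy(obs, obs / expected)
    return float(2.0 * np.nansum(terms))
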