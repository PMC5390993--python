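"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest


def grid_search_sse(t, y, family, a_bounds=None, n_a=200, n_k=200, n_b=20):
    """Exhaustive grid-search least squares over the bounded parameter box.

    Independent oracle: evaluates the decline curves directly (its own
    formulas, not the package's) on a dense grid and returns
    ``(best_params, best_sse)``.  The curve is linear in A for every
    family, so the A axis is vectorised while k (and the Weibull shape
    b) are looped.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if a_bounds is None:
        a_bounds = (0.0, 2.0 * max(float(np.max(y)), 1e-12))
    A = np.linspace(a_bounds[0], a_bounds[1], n_a)
    k_lo, k_hi = -5.0, 5.0
    if family == "harmonic" and t.max() > 0:
        k_lo = max(k_lo, (1e-6 - 1.0) / float(t.max()))
    ks = np.linspace(k_lo, k_hi, n_k)
    bs = np.linspace(1e-4, 5.0, n_b) if family == "weibull" else [None]

    best_sse, best_params = np.inf, None
    for b in bs:
        for k in ks:
            if family == "linear":
                pred = A[:, None] - k * t[None, :]
            else:
                if family == "exponential":
                    g = np.exp(np.minimum(-k * t, 150.0))
                elif family == "harmonic":
                    g = 1.0 / (1.0 + k * t)
                else:  # weibull, odd extension for negative k*t
                    u = k * t
                    g = np.exp(np.clip(-np.sign(u) * np.abs(u) ** b, -150.0, 150.0))
                pred = A[:, None] * g[None, :]
            sse = ((y[None, :] - pred) ** 2).sum(axis=1)
            i = int(np.argmin(sse))
            if sse[i] < best_sse:
                best_sse = float(sse[i])
                best_params = (float(A[i]), float(k)) if b is None else (
                    float(A[i]), float(k), float(b)
                )
    return best_params, best_sse


@pytest.fixture(scope="session")
def grid_oracle():
    return grid_search_sse


@pytest.fixture(scope="session")
def small_cohort():
    """A 150-subject synthetic cohort shared across tests."""
    from alscourse.synthetic import CohortConfig, generate_cohort

    return generate_cohort(CohortConfig(n_subjects=150, seed=42))
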