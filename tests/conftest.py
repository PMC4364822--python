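"""Shared fixtures and independent oracles for the test suite."""

import math

import numpy as np
import pytest

import pitmark as pm
from pitmark import models
from pitmark.design import CohortTable


@pytest.fixture(scope="session")
def study():
    """The eight-occasion study design (calendar + cohorts)."""
    return pm.powell_river_design()


@pytest.fixture(scope="session")
def reconstruction():
    """The canonical reconstructed study dataset (session cached)."""
    return pm.reconstruct_study_dataset()


def monthly_calendar(n_occasions: int, start="2009-06-01"):
    """A small all-summer calendar with dt = 1 month everywhere."""
    import datetime as dt

    d0 = dt.date.fromisoformat(start)
    dates = []
    y, m = d0.year, d0.month
    for _ in range(n_occasions):
        dates.append(dt.date(y, m, 15))
        m += 1
        if m == 13:
            y, m = y + 1, 1
    return pm.build_calendar(dates, list(range(n_occasions)))


@pytest.fixture
def cal4():
    return monthly_calendar(4)


def make_set(calendar, rows, release=None):
    """Build a CaptureHistorySet from a list of history strings."""
    release = release or [0] * len(rows)
    codes = np.vstack(
        [
            pm.parse_history(r, release[i], calendar.n_occasions)
            for i, r in enumerate(rows)
        ]
    )
    ids = tuple(f"t{i}" for i in range(len(rows)))
    return pm.CaptureHistorySet(codes, np.asarray(release), ids, calendar)


def brute_force_marginal(hset, params, spec):
    """Independent oracle: sum exp(complete-data log-likelihood) over every
    latent alive path consistent with monotone survival.

    Non-monotone alive sequences carry zero transition probability
    (resurrection), so enumerating the monotone paths -- equivalently the
    death occasions -- is the exact latent sum.
    """
    total = 0.0
    k = hset.n_occasions
    for i in range(hset.n_individuals):
        row = hset.subset([i])
        rel = int(row.release[0])
        row_p = 0.0
        for tau in range(rel + 1, k + 1):
            try:
                lat = models.LatentStateMatrix.from_death_times(
                    row, np.array([tau]), spec
                )
            except ValueError:
                continue
            ll = pm.complete_data_loglik(row, lat, params, spec)
            if np.isfinite(ll):
                row_p += math.exp(ll)
        if row_p == 0.0:
            return -np.inf
        total += math.log(row_p)
    return total


def grid_posterior_means(hset, spec, n_grid=250):
    """2-D grid-quadrature posterior means of (S, Pc_l) for model4-style
    specs under Uniform(0,1) priors, built on the enumerated marginal."""
    grid = np.linspace(0.5 / n_grid, 1 - 0.5 / n_grid, n_grid)
    ll = np.empty((n_grid, n_grid))
    for a, s in enumerate(grid):
        for b, p in enumerate(grid):
            ll[a, b] = pm.marginal_loglik_enumerate(
                hset, pm.ParamState([s], [p]), spec
            )
    w = np.exp(ll - ll.max())
    w /= w.sum()
    s_mean = float((w.sum(axis=1) * grid).sum())
    p_mean = float((w.sum(axis=0) * grid).sum())
    return s_mean, p_mean


def small_noisy_instance(seed=3):
    """4 individuals x 5 occasions with deliberately rough rates so the
    posterior is informative but far from degenerate."""
    cal5 = monthly_calendar(5)
    cohorts = CohortTable([0, 1], [2, 2])
    truth = pm.SimTruth(
        pm.ParamState([0.85], [0.7]), cal5, cohorts, pm.preset("model4"), seed=seed
    )
    return pm.simulate_histories(truth)
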