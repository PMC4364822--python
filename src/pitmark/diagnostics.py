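"""Convergence diagnostics and posterior summaries.

Multi-chain potential scale reduction (Gelman-Rubin), sample
autocorrelation, effective sample size from the summed autocorrelation
sequence, and the tidy posterior summary table (mean, SD, 2.5/50/97.5%
quantiles, R-hat, ESS per parameter).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .mcmc import PosteriorDraws


class DiagnosticError(ValueError):
    """Diagnostic undefined for the supplied draws."""


def gelman_rubin(chains: np.ndarray) -> float:
    """Potential scale reduction factor R-hat from >= 2 chains.

    ``chains`` is (n_chains, n_draws).  R-hat compares the pooled variance
    estimate ((n-1)/n W + B/n) with the mean within-chain variance W; it
    approaches 1 from above as chains mix.  Chains that are identical (or
    all constant) give 1.0 by convention.
    """
    x = np.asarray(chains, float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise DiagnosticError("Gelman-Rubin needs at least two chains")
    m, n = x.shape
    if n < 2:
        raise DiagnosticError("Gelman-Rubin needs at least two draws per chain")
    w = x.var(axis=1, ddof=1).mean()
    b_over_n = x.mean(axis=1).var(ddof=1)
    if w == 0.0:
        return 1.0 if b_over_n == 0.0 else np.inf
    var_plus = (n - 1) / n * w + b_over_n
    return float(np.sqrt(var_plus / w))


def autocorrelation(draws: np.ndarray, max_lag: int) -> np.ndarray:
    """Sample autocorrelation at lags 0..max_lag of a single chain."""
    x = np.asarray(draws, float).reshape(-1)
    n = x.size
    if n < 2:
        raise DiagnosticError("autocorrelation needs at least two draws")
    x = x - x.mean()
    denom = float(x @ x)
    if denom == 0.0:
        raise DiagnosticError("autocorrelation undefined for a constant chain")
    max_lag = min(max_lag, n - 1)
    full = np.correlate(x, x, mode="full")[n - 1 : n + max_lag]
    return full / denom


def effective_sample_size(draws: np.ndarray) -> float:
    """ESS = N / (1 + 2 sum of autocorrelations), capped at N.

    Accepts a single chain or an (n_chains, n_draws) array (chains are
    analysed separately and their ESS summed).  The autocorrelation sum is
    truncated by Geyer's initial-positive-sequence rule.
    """
    x = np.asarray(draws, float)
    if x.ndim == 2:
        return float(sum(effective_sample_size(row) for row in x))
    n = x.size
    try:
        rho = autocorrelation(x, max_lag=min(n - 1, 1000))
    except DiagnosticError:
        return float(n)  # constant chain carries no autocorrelation signal
    acc = 0.0
    for t in range(1, rho.size - 1, 2):
        pair = rho[t] + rho[t + 1]
        if pair <= 0:
            break
        acc += pair
    ess = n / (1 + 2 * acc)
    return float(min(ess, n))


def summarize_posterior(draws: PosteriorDraws) -> pd.DataFrame:
    """Pooled posterior summary per parameter.

    Columns: parameter, season (summer/winter/pooled, read from the draw
    name), mean, sd, q2.5, median, q97.5, rhat, ess.
    """
    rows = []
    for name, arr in draws.draws.items():
        pooled = arr.reshape(-1)
        if name.endswith("_summer"):
            base, season = name[: -len("_summer")], "summer"
        elif name.endswith("_winter"):
            base, season = name[: -len("_winter")], "winter"
        else:
            base, season = name, "pooled"
        rhat = gelman_rubin(arr) if arr.shape[0] >= 2 else np.nan
        rows.append(
            {
                "parameter": base,
                "season": season,
                "mean": pooled.mean(),
                "sd": pooled.std(ddof=1),
                "q2.5": np.quantile(pooled, 0.025),
                "median": np.quantile(pooled, 0.5),
                "q97.5": np.quantile(pooled, 0.975),
                "rhat": rhat,
                "ess": effective_sample_size(arr),
            }
        )
    return pd.DataFrame(rows)


def max_rhat(draws: PosteriorDraws) -> float:
    """Largest R-hat over all recorded scalar parameters."""
    return float(max(gelman_rubin(arr) for arr in draws.draws.values()))
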