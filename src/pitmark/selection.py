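"""Deviance, DIC and the model-comparison rules.

DIC = D-bar + p_D with p_D = D-bar - D-hat, where D-bar is the posterior
mean deviance and D-hat the deviance at the posterior-mean parameters.
The deviance focus is the observation layer conditional on the latent
alive/dead states (the convention of MCMC samplers that treat O_l and O_d
as the stochastic observed nodes); the state-transition terms of the fully
latent nodes can be included instead via ``focus="complete_data"``, which
shifts every model's deviance by a data-dependent amount, so the focus
must be held fixed within a comparison.

Models sharing the dead-recovery likelihood (the dead-inclusive variants)
are ranked together; variants that drop the dead layer condition on
different data and are ranked only against each other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import models
from .histories import CaptureHistorySet
from .mcmc import PosteriorDraws
from .models import LatentStateMatrix, ModelSpec, ParamState

OBSERVATION = "observation"
COMPLETE_DATA = "complete_data"

WELL_SUPPORTED = "well-supported"
LESS_SUPPORTED = "less-supported"
EXCLUDED = "excluded"


class ComparabilityError(ValueError):
    """Attempt to rank models with different data likelihoods together."""


def deviance(
    hset: CaptureHistorySet,
    latent: LatentStateMatrix,
    params: ParamState,
    spec: ModelSpec,
    focus: str = OBSERVATION,
) -> float:
    """-2 x log-likelihood at the given latent states and parameters."""
    if focus == OBSERVATION:
        ll = models.observation_loglik(hset, latent, params, spec)
    elif focus == COMPLETE_DATA:
        ll = models.complete_data_loglik(hset, latent, params, spec)
    else:
        raise ValueError(f"unknown deviance focus {focus!r}")
    return float(-2.0 * ll) if np.isfinite(ll) else np.inf


@dataclass(frozen=True)
class DicResult:
    """Deviance summaries of one fitted model."""

    model_name: str
    dbar: float
    dhat: float
    includes_dead: bool

    @property
    def p_d(self) -> float:
        """Effective number of parameters, D-bar - D-hat."""
        return self.dbar - self.dhat

    @property
    def dic(self) -> float:
        return self.dbar + self.p_d


def dic(
    draws: PosteriorDraws, hset: CaptureHistorySet, spec: ModelSpec | None = None
) -> DicResult:
    """DIC from a sampler run.

    D-bar is the mean of the recorded deviance trace; D-hat plugs the
    posterior-mean parameters and the per-cell posterior modal latent
    states into the same deviance.
    """
    spec = spec or draws.spec
    if draws.deviance.size == 0:
        raise ValueError("empty deviance trace")
    dbar = float(draws.deviance.mean())
    params_hat = draws.posterior_mean_params()
    latent_hat = draws.modal_latent(hset)
    dhat = deviance(hset, latent_hat, params_hat, spec)
    return DicResult(
        model_name=spec.name or "model",
        dbar=dbar,
        dhat=dhat,
        includes_dead=spec.include_dead_submodel,
    )


def _support(delta: float) -> str:
    if delta <= 5.0:
        return WELL_SUPPORTED
    if delta <= 10.0:
        return LESS_SUPPORTED
    return EXCLUDED


def compare_models(results) -> pd.DataFrame:
    """Rank models by DIC and apply the 5/10-unit support rules.

    Delta <= 5 units of the best model: well supported; 5 < Delta <= 10:
    substantially less supported; Delta > 10: excluded.  All models in one
    ranking must share the same data likelihood (all dead-inclusive or all
    dead-exclusive); mixing raises :class:`ComparabilityError`.
    """
    results = list(results)
    if not results:
        raise ValueError("no models to compare")
    kinds = {r.includes_dead for r in results}
    if len(kinds) > 1:
        raise ComparabilityError(
            "dead-inclusive and dead-exclusive models condition on different "
            "data and cannot be ranked in one block"
        )
    ordered = sorted(results, key=lambda r: r.dic)
    best = ordered[0].dic
    return pd.DataFrame(
        {
            "model": [r.model_name for r in ordered],
            "dbar": [r.dbar for r in ordered],
            "p_d": [r.p_d for r in ordered],
            "dic": [r.dic for r in ordered],
            "delta_dic": [r.dic - best for r in ordered],
            "support": [_support(r.dic - best) for r in ordered],
        }
    )


def compare_in_blocks(results) -> dict[str, pd.DataFrame]:
    """Split results into the dead-inclusive and dead-exclusive comparison
    blocks and rank each separately."""
    blocks = {}
    with_dead = [r for r in results if r.includes_dead]
    without = [r for r in results if not r.includes_dead]
    if with_dead:
        blocks["dead_inclusive"] = compare_models(with_dead)
    if without:
        blocks["dead_exclusive"] = compare_models(without)
    return blocks
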