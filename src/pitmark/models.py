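"""Model variants, parameters, latent states, priors and likelihoods.

The state-space model couples a monotone alive/dead state process with two
Bernoulli observation layers.  For individual i and occasion k after its
release (release itself is conditioned on and contributes no terms):

* state:        L_k | L_{k-1} ~ Bernoulli(L_{k-1} * S_j^{dt_k}) with S_j
  the monthly survival rate for the season j of the interval and dt_k the
  interval length in months;
* live layer:   O_l,k ~ Bernoulli(L_k * Pc_l,j) -- detection of a live
  individual via its PIT tag;
* dead layer:   O_d,k ~ Bernoulli(D_k * Pc_d,j) -- recovery of a dead
  individual's shell, present only in the dead-inclusive variants.

D_k indicates that the shell is available for recovery: under the default
``until_recovered`` persistence a shell stays detectable at every occasion
from death until its first recovery (code 2), after which the individual
is censored; under ``single_occasion`` it is detectable only at the first
occasion after death.

Eight named variants cover the 2 x 2 x 2 design of (seasonal structure) x
(dead submodel) x (individual random effects): model1 is fully seasonal
with the dead layer, model2 keeps seasonality only in Pc_d, model3 drops
seasonality entirely, model4 additionally drops the dead layer; the "-1"
variants add truncated-normal individual effects with Uniform(0,1)
hypermeans and Uniform(0, prior_sd_upper) SDs shared across seasons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

from .histories import DEAD_RECOVERY, NOT_SEEN, POST, SEEN, CaptureHistorySet

UNTIL_RECOVERED = "until_recovered"
SINGLE_OCCASION = "single_occasion"


class SizeError(ValueError):
    """Instance too large for exact latent enumeration."""


@dataclass(frozen=True)
class ModelSpec:
    """Which parameters are seasonal / hierarchical, and the dead submodel."""

    seasonal_S: bool = False
    seasonal_Pcl: bool = False
    seasonal_Pcd: bool = False
    include_dead_submodel: bool = True
    hierarchical: bool = False
    shell_persistence: str = UNTIL_RECOVERED
    prior_sd_upper: float = 0.5
    name: str = ""

    def __post_init__(self):
        if self.shell_persistence not in (UNTIL_RECOVERED, SINGLE_OCCASION):
            raise ValueError(f"unknown shell persistence {self.shell_persistence!r}")
        if not self.include_dead_submodel and (self.seasonal_Pcd):
            raise ValueError("seasonal Pc_d requires the dead submodel")
        if self.prior_sd_upper <= 0:
            raise ValueError("prior_sd_upper must be positive")

    @property
    def n_seasons_S(self) -> int:
        return 2 if self.seasonal_S else 1

    @property
    def n_seasons_Pcl(self) -> int:
        return 2 if self.seasonal_Pcl else 1

    @property
    def n_seasons_Pcd(self) -> int:
        return 2 if self.seasonal_Pcd else 0 if not self.include_dead_submodel else 1

    def season_index_S(self, season_labels: np.ndarray) -> np.ndarray:
        """Map 1/2 season labels to parameter indices for S."""
        labels = np.asarray(season_labels, int)
        return labels - 1 if self.seasonal_S else np.zeros_like(labels)

    def season_index_Pcl(self, season_labels: np.ndarray) -> np.ndarray:
        labels = np.asarray(season_labels, int)
        return labels - 1 if self.seasonal_Pcl else np.zeros_like(labels)

    def season_index_Pcd(self, season_labels: np.ndarray) -> np.ndarray:
        labels = np.asarray(season_labels, int)
        return labels - 1 if self.seasonal_Pcd else np.zeros_like(labels)


_PRESETS = {
    "model1": ModelSpec(True, True, True, True, False, name="model1"),
    "model1-1": ModelSpec(True, True, True, True, True, name="model1-1"),
    "model2": ModelSpec(False, False, True, True, False, name="model2"),
    "model2-1": ModelSpec(False, False, True, True, True, name="model2-1"),
    "model3": ModelSpec(False, False, False, True, False, name="model3"),
    "model3-1": ModelSpec(False, False, False, True, True, name="model3-1"),
    "model4": ModelSpec(False, False, False, False, False, name="model4"),
    "model4-1": ModelSpec(False, False, False, False, True, name="model4-1"),
}


def preset(name: str) -> ModelSpec:
    """Named model variant ("model1", "model1-1", ..., "model4-1")."""
    try:
        return _PRESETS[name.lower()]
    except KeyError:
        raise KeyError(
            f"unknown model preset {name!r}; choose from {sorted(_PRESETS)}"
        ) from None


def preset_names() -> tuple[str, ...]:
    return tuple(_PRESETS)


@dataclass
class ParamState:
    """Values of S, Pc_l, Pc_d (per season or pooled) and, for hierarchical
    specs, the per-individual values plus hypermeans and shared SDs.

    For non-hierarchical specs ``s``/``pcl``/``pcd`` hold the population
    parameters; for hierarchical specs they hold the hypermeans and the
    ``*_i`` arrays (n individuals x seasons) hold the individual values
    drawn from truncated normals on [0, 1].
    """

    s: np.ndarray
    pcl: np.ndarray
    pcd: np.ndarray | None = None
    s_i: np.ndarray | None = None
    pcl_i: np.ndarray | None = None
    pcd_i: np.ndarray | None = None
    sigma_s: float | None = None
    sigma_pcl: float | None = None
    sigma_pcd: float | None = None

    def __post_init__(self):
        self.s = np.atleast_1d(np.asarray(self.s, float))
        self.pcl = np.atleast_1d(np.asarray(self.pcl, float))
        if self.pcd is not None:
            self.pcd = np.atleast_1d(np.asarray(self.pcd, float))
        for name in ("s_i", "pcl_i", "pcd_i"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, float))

    @classmethod
    def initial(cls, spec: ModelSpec, n_individuals: int | None = None, rng=None) -> "ParamState":
        """A valid starting state (mildly dispersed when ``rng`` is given)."""
        rng = np.random.default_rng(rng)
        s = rng.uniform(0.85, 0.99, spec.n_seasons_S)
        pcl = rng.uniform(0.6, 0.95, spec.n_seasons_Pcl)
        pcd = rng.uniform(0.2, 0.8, spec.n_seasons_Pcd) if spec.include_dead_submodel else None
        st = cls(s, pcl, pcd)
        if spec.hierarchical:
            if n_individuals is None:
                raise ValueError("hierarchical state needs the number of individuals")
            st.sigma_s = float(rng.uniform(0.005, 0.05))
            st.sigma_pcl = float(rng.uniform(0.005, 0.05))
            st.s_i = np.clip(
                s[None, :] + st.sigma_s * rng.standard_normal((n_individuals, s.size)),
                1e-4, 1 - 1e-4,
            )
            st.pcl_i = np.clip(
                pcl[None, :] + st.sigma_pcl * rng.standard_normal((n_individuals, pcl.size)),
                1e-4, 1 - 1e-4,
            )
            if spec.include_dead_submodel:
                st.sigma_pcd = float(rng.uniform(0.01, 0.1))
                st.pcd_i = np.clip(
                    pcd[None, :] + st.sigma_pcd * rng.standard_normal((n_individuals, pcd.size)),
                    1e-4, 1 - 1e-4,
                )
        return st

    def copy(self) -> "ParamState":
        return ParamState(
            self.s.copy(),
            self.pcl.copy(),
            None if self.pcd is None else self.pcd.copy(),
            None if self.s_i is None else self.s_i.copy(),
            None if self.pcl_i is None else self.pcl_i.copy(),
            None if self.pcd_i is None else self.pcd_i.copy(),
            self.sigma_s,
            self.sigma_pcl,
            self.sigma_pcd,
        )

    # -- per-cell parameter values (hierarchical-aware) --------------------

    def s_cells(self, spec: ModelSpec, n: int, interval_season: np.ndarray) -> np.ndarray:
        """(n, K) monthly survival applying to the interval ending at k (k>=1)."""
        k = interval_season.size + 1
        idx = spec.season_index_S(interval_season)
        src = self.s_i if (spec.hierarchical and self.s_i is not None) else None
        out = np.empty((n, k))
        out[:, 0] = np.nan
        out[:, 1:] = src[:, idx] if src is not None else self.s[idx][None, :]
        return out

    def pcl_cells(self, spec: ModelSpec, n: int, occasion_season: np.ndarray) -> np.ndarray:
        idx = spec.season_index_Pcl(occasion_season)
        src = self.pcl_i if (spec.hierarchical and self.pcl_i is not None) else None
        return src[:, idx] if src is not None else np.broadcast_to(self.pcl[idx], (n, idx.size))

    def pcd_cells(self, spec: ModelSpec, n: int, occasion_season: np.ndarray) -> np.ndarray | None:
        if not spec.include_dead_submodel:
            return None
        idx = spec.season_index_Pcd(occasion_season)
        src = self.pcd_i if (spec.hierarchical and self.pcd_i is not None) else None
        return src[:, idx] if src is not None else np.broadcast_to(self.pcd[idx], (n, idx.size))


def interval_survival(s_monthly: float, dt_months: float) -> float:
    """Per-interval survival probability S^dt.

    >>> interval_survival(0.999, 2.0)
    0.998001
    """
    if not 0.0 <= s_monthly <= 1.0:
        raise ValueError("monthly survival must lie in [0, 1]")
    if dt_months <= 0:
        raise ValueError("interval length must be positive")
    return float(s_monthly**dt_months)


def truncnorm_logpdf(x, mu, sigma, lower=0.0, upper=1.0):
    """Log density of a Normal(mu, sigma) truncated to [lower, upper]."""
    x = np.asarray(x, float)
    sigma = np.asarray(sigma, float)
    z = ndtr((upper - mu) / sigma) - ndtr((lower - mu) / sigma)
    out = (
        -0.5 * ((x - mu) / sigma) ** 2
        - np.log(sigma)
        - 0.5 * math.log(2 * math.pi)
        - np.log(z)
    )
    return np.where((x >= lower) & (x <= upper), out, -np.inf)


def prior_logdensity(params: ParamState, spec: ModelSpec) -> float:
    """Joint log prior density; -inf outside the support.

    Uniform(0,1) on population probabilities and hypermeans contributes 0
    inside the unit box; individual effects contribute truncated-normal
    terms; SDs carry Uniform(0, prior_sd_upper) priors.
    """
    tops = [params.s, params.pcl] + ([params.pcd] if spec.include_dead_submodel else [])
    for arr in tops:
        if arr is None or np.any(arr < 0) or np.any(arr > 1):
            return -np.inf
    total = 0.0
    if spec.hierarchical:
        u = spec.prior_sd_upper
        triples = [
            (params.s_i, params.s, params.sigma_s),
            (params.pcl_i, params.pcl, params.sigma_pcl),
        ]
        if spec.include_dead_submodel:
            triples.append((params.pcd_i, params.pcd, params.sigma_pcd))
        for xi, mu, sigma in triples:
            if sigma is None or not 0 < sigma <= u:
                return -np.inf
            total -= math.log(u)
            if xi is not None:
                lp = truncnorm_logpdf(xi, mu[None, :], sigma)
                if np.any(np.isneginf(lp)):
                    return -np.inf
                total += float(lp.sum())
    return total


@dataclass(frozen=True)
class LatentStateMatrix:
    """Augmented alive (L) and shell-available (D) indicators.

    ``death_occasion[i]`` is the first occasion at which individual i is
    dead; the value K means the individual is alive at the final occasion.
    L and D are derived from it: L is 1 from release through death-1, D is
    1 while the shell is available under the spec's persistence mode, and
    both are 0 on censored (POST) cells.
    """

    L: np.ndarray
    D: np.ndarray
    death_occasion: np.ndarray

    @classmethod
    def from_death_times(
        cls, hset: CaptureHistorySet, death_occasion: np.ndarray, spec: ModelSpec
    ) -> "LatentStateMatrix":
        tau = np.asarray(death_occasion, int)
        n, k = hset.codes.shape
        rel = hset.release
        rec = hset.recovery_occasion()
        last = hset.last_seen_alive()
        if np.any(tau <= last) or np.any(tau <= rel) or np.any(tau > k):
            raise ValueError("death occasion conflicts with observed live detections")
        if np.any((rec >= 0) & (tau > rec)):
            raise ValueError("death occasion after the observed dead recovery")
        karr = np.arange(k)
        alive = (karr[None, :] >= rel[:, None]) & (karr[None, :] < tau[:, None])
        end = np.where(rec >= 0, rec, k - 1)
        if spec.shell_persistence == SINGLE_OCCASION:
            dead = (karr[None, :] == tau[:, None]) & (karr[None, :] <= end[:, None])
        else:
            dead = (karr[None, :] >= tau[:, None]) & (karr[None, :] <= end[:, None])
        return cls(alive.astype(np.int8), dead.astype(np.int8), tau)

    def __post_init__(self):
        if np.any((self.L == 1) & (self.D == 1)):
            raise ValueError("an individual cannot be alive and shell-available at once")


def init_latent_states(
    hset: CaptureHistorySet, spec: ModelSpec, seed=None
) -> LatentStateMatrix:
    """A latent matrix consistent with every observation.

    Individuals are alive through their last live detection; a recovered
    individual dies in the interval directly before its recovery;
    unconstrained tails are filled alive.  The result is deterministic (the
    seed is accepted for interface symmetry with the samplers).
    """
    k = hset.n_occasions
    rec = hset.recovery_occasion()
    tau = np.where(rec >= 0, rec, k)
    return LatentStateMatrix.from_death_times(hset, tau, spec)


def death_time_support(hset: CaptureHistorySet, spec: ModelSpec) -> np.ndarray:
    """(n, K) boolean: column t-1 <-> death occasion t in {1..K} allowed."""
    n, k = hset.codes.shape
    rel, last, rec = hset.release, hset.last_seen_alive(), hset.recovery_occasion()
    t = np.arange(1, k + 1)[None, :]
    ok = (t > rel[:, None]) & (t > last[:, None])
    has_rec = rec[:, None] >= 0
    ok &= ~has_rec | (t <= rec[:, None])
    if spec.shell_persistence == SINGLE_OCCASION:
        ok &= ~has_rec | (t == rec[:, None])
    return ok


def _obs_cell_terms(codes, alive, dead, pcl_c, pcd_c, include_dead):
    """Per-cell observation log-probabilities given latent indicators.

    Returns -inf cells for impossible observations (live detection of a
    dead individual, recovery without an available shell).
    """
    with np.errstate(divide="ignore"):
        lp = np.log(pcl_c)
        lq = np.log1p(-pcl_c)
        if include_dead:
            dp = np.log(pcd_c)
            dq = np.log1p(-pcd_c)
    active = (codes == SEEN) | (codes == NOT_SEEN) | (codes == DEAD_RECOVERY)
    out = np.zeros(codes.shape)
    seen = codes == SEEN
    out[seen & (alive == 1)] = np.broadcast_to(lp, codes.shape)[seen & (alive == 1)]
    out[seen & (alive == 0)] = -np.inf
    miss = codes == NOT_SEEN
    out[miss & (alive == 1)] = np.broadcast_to(lq, codes.shape)[miss & (alive == 1)]
    recov = codes == DEAD_RECOVERY
    if include_dead:
        out[miss & (alive == 0) & (dead == 1)] = np.broadcast_to(dq, codes.shape)[
            miss & (alive == 0) & (dead == 1)
        ]
        out[recov & (dead == 1)] = np.broadcast_to(dp, codes.shape)[recov & (dead == 1)]
        out[recov & (dead == 0)] = -np.inf
    else:
        # dead layer excluded: a code-2 cell still requires the individual
        # to be dead, but carries no detection term
        out[recov & (alive == 1)] = -np.inf
    out[~active] = 0.0
    return out


def observation_loglik(
    hset: CaptureHistorySet, latent: LatentStateMatrix, params: ParamState, spec: ModelSpec
) -> float:
    """Log-likelihood of the observation layers given latent states.

    This is the stochastic-observed-node likelihood used for the deviance:
    only the O_l and (if present) O_d Bernoulli terms, summed over
    post-release, non-censored cells.
    """
    n, k = hset.codes.shape
    karr = np.arange(k)
    post_rel = karr[None, :] > hset.release[:, None]
    pcl_c = params.pcl_cells(spec, n, hset.calendar.occasion_season)
    pcd_c = params.pcd_cells(spec, n, hset.calendar.occasion_season)
    terms = _obs_cell_terms(
        hset.codes, latent.L, latent.D, pcl_c, pcd_c, spec.include_dead_submodel
    )
    vals = np.where(post_rel, terms, 0.0)
    if np.any(np.isneginf(vals)):
        return -np.inf
    return float(vals.sum())


def transition_loglik(
    hset: CaptureHistorySet, latent: LatentStateMatrix, params: ParamState, spec: ModelSpec
) -> float:
    """Log-likelihood of the alive/dead state process given parameters."""
    n, k = hset.codes.shape
    cal = hset.calendar
    s_c = params.s_cells(spec, n, cal.interval_season)  # column k = interval ending at k
    dt = np.concatenate([[np.nan], cal.delta_t])
    rel = hset.release
    rec = hset.recovery_occasion()
    total = 0.0
    karr = np.arange(k)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_surv = s_c ** dt[None, :]
        log_surv = np.log(p_surv)
        log_die = np.log1p(-p_surv)
    # a transition into occasion k exists when k > release, the individual
    # was alive at k-1 and the cell is not censored
    prev_alive = np.zeros_like(latent.L)
    prev_alive[:, 1:] = latent.L[:, :-1]
    active = (karr[None, :] > rel[:, None]) & (prev_alive == 1) & (hset.codes != POST)
    term = np.where(latent.L == 1, log_surv, log_die)
    vals = np.where(active, term, 0.0)
    # resurrection (alive after dead) has probability zero
    resurrect = (
        (karr[None, :] > rel[:, None]) & (prev_alive == 0) & (latent.L == 1)
    )
    if np.any(resurrect) or np.any(np.isneginf(vals)):
        return -np.inf
    return float(np.nansum(vals))


def complete_data_loglik(
    hset: CaptureHistorySet, latent: LatentStateMatrix, params: ParamState, spec: ModelSpec
) -> float:
    """Joint log-likelihood of latent states and observations.

    Sum of the Bernoulli state-transition terms and both observation
    layers over post-release, non-censored occasions; the release occasion
    contributes nothing.  Returns -inf when the latent matrix contradicts
    an observation, so samplers can reject invalid proposals uniformly.
    """
    lt = transition_loglik(hset, latent, params, spec)
    if np.isneginf(lt):
        return -np.inf
    lo = observation_loglik(hset, latent, params, spec)
    return float(lt + lo)


def _value(arr_pop, arr_ind, spec_flag, i, idx):
    if spec_flag and arr_ind is not None:
        return float(arr_ind[i, idx])
    return float(arr_pop[idx])


def marginal_loglik_enumerate(
    hset: CaptureHistorySet,
    params: ParamState,
    spec: ModelSpec,
    max_cells: int = 1 << 20,
) -> float:
    """Exact observed-data log-likelihood by enumerating death occasions.

    The monotone alive path of a row is determined by its death occasion
    t in {release+1, ..., K} (t = K means alive throughout), so the
    marginal of each row is a sum over at most K death times, each a
    closed-form product of transition and observation probabilities.  This
    is written directly from the model definition and is independent of
    :func:`complete_data_loglik`, which it equals after summation over
    consistent latent matrices.
    """
    n, k = hset.codes.shape
    if n * (2**k) > max_cells:
        raise SizeError(f"instance of size {n} x 2^{k} too large to enumerate")
    cal = hset.calendar
    dt = cal.delta_t
    s_idx = spec.season_index_S(cal.interval_season)
    l_idx = spec.season_index_Pcl(cal.occasion_season)
    d_idx = spec.season_index_Pcd(cal.occasion_season)
    rec = hset.recovery_occasion()
    last = hset.last_seen_alive()
    total = 0.0
    for i in range(n):
        rel = int(hset.release[i])
        r = int(rec[i])
        end = r if r >= 0 else k - 1
        row_p = 0.0
        for t in range(rel + 1, k + 1):
            if t <= last[i]:
                continue
            if r >= 0:
                if t > r:
                    continue
                if spec.shell_persistence == SINGLE_OCCASION and t != r:
                    continue
            p = 1.0
            # state transitions into occasions rel+1 .. min(t, K-1)
            for m in range(rel + 1, min(t, k - 1) + 1):
                s = _value(params.s, params.s_i, spec.hierarchical, i, s_idx[m - 1])
                ps = s ** dt[m - 1]
                p *= ps if m < t else 1.0 - ps
            # live observations while alive
            for m in range(rel + 1, t):
                pl = _value(params.pcl, params.pcl_i, spec.hierarchical, i, l_idx[m])
                c = hset.codes[i, m]
                if c == SEEN:
                    p *= pl
                elif c == NOT_SEEN:
                    p *= 1.0 - pl
                elif c == DEAD_RECOVERY:
                    p = 0.0
            # dead observations while the shell is available
            if spec.include_dead_submodel and t <= k - 1:
                if spec.shell_persistence == SINGLE_OCCASION:
                    span = [t] if t <= end else []
                else:
                    span = range(t, end + 1)
                for m in span:
                    pdm = _value(params.pcd, params.pcd_i, spec.hierarchical, i, d_idx[m])
                    c = hset.codes[i, m]
                    if c == DEAD_RECOVERY:
                        p *= pdm
                    elif c == NOT_SEEN:
                        p *= 1.0 - pdm
                    elif c == SEEN:
                        p = 0.0
            row_p += p
        if row_p <= 0.0:
            return -np.inf
        total += math.log(row_p)
    return total
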