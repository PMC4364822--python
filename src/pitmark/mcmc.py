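"""Data-augmentation MCMC for the joint live/dead mark-recapture models.

Sampler composition per sweep:

* latent alive/dead trajectories -- exact Gibbs.  Because the alive path of
  a row is monotone, its free part is fully described by the death
  occasion, so each row's full conditional is a small categorical
  distribution enumerated in closed form (vectorised across individuals).
* detection probabilities (non-hierarchical) -- conjugate Beta Gibbs: with
  Uniform(0,1) priors the full conditional is Beta(1 + successes,
  1 + failures) over the at-risk cells of the season.
* monthly survival -- random-walk Metropolis on the logit scale (the
  S^dt term with non-integer dt has no conjugate update).
* hierarchical blocks -- per-individual logit random walks against
  (truncated-normal prior x row likelihood), plus random-walk updates of
  the hypermeans and of the shared SDs.

Proposal scales adapt toward a 20-50% acceptance rate during burn-in and
are frozen afterwards so the post-burn-in kernel satisfies detailed
balance.  Chain c uses the deterministic seed ``config.seed + c``; runs
are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

from . import models
from .histories import DEAD_RECOVERY, NOT_SEEN, SEEN, CaptureHistorySet
from .models import (
    LatentStateMatrix,
    ModelSpec,
    ParamState,
    SINGLE_OCCASION,
    truncnorm_logpdf,
)


class InitializationError(RuntimeError):
    """The likelihood is non-finite at the sampler's starting state."""


@dataclass(frozen=True)
class McmcConfig:
    n_chains: int = 3
    n_iter: int = 20_000
    burn_in: int = 5_000
    thin: int = 1
    seed: int = 0
    proposal_sd: float = 0.5
    adapt: bool = True
    target_accept: float = 0.35
    adapt_window: int = 50

    def __post_init__(self):
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


class _Data:
    """Precomputed index structures for one capture-history set."""

    def __init__(self, hset: CaptureHistorySet, spec: ModelSpec):
        self.hset = hset
        self.spec = spec
        cal = hset.calendar
        self.n, self.K = hset.codes.shape
        self.codes = hset.codes
        self.rel = hset.release
        self.last = hset.last_seen_alive()
        self.rec = hset.recovery_occasion()
        self.end = np.where(self.rec >= 0, self.rec, self.K - 1)
        self.karr = np.arange(self.K)
        self.dt = np.concatenate([[np.nan], cal.delta_t])  # dt[k]: interval ending at k
        self.sidx = np.concatenate([[0], spec.season_index_S(cal.interval_season)])
        self.lidx = spec.season_index_Pcl(cal.occasion_season)
        self.didx = (
            spec.season_index_Pcd(cal.occasion_season)
            if spec.include_dead_submodel
            else None
        )
        self.is0 = self.codes == NOT_SEEN
        self.is1 = self.codes == SEEN
        self.is2 = self.codes == DEAD_RECOVERY
        self.post_rel = self.karr[None, :] > self.rel[:, None]
        self.allowed = models.death_time_support(hset, spec)
        if not self.allowed.any(axis=1).all():
            raise InitializationError("a history admits no consistent latent path")

    # latent masks -----------------------------------------------------

    def alive_cells(self, tau: np.ndarray) -> np.ndarray:
        """(n, K) post-release occasions at which the individual is alive."""
        return self.post_rel & (self.karr[None, :] < tau[:, None])

    def dead_cells(self, tau: np.ndarray) -> np.ndarray:
        k = self.karr[None, :]
        if self.spec.shell_persistence == SINGLE_OCCASION:
            base = k == tau[:, None]
        else:
            base = k >= tau[:, None]
        return base & (k <= self.end[:, None])


def _draw_death_times(data: _Data, params: ParamState, rng) -> np.ndarray:
    """Exact Gibbs draw of every row's death occasion (Gumbel-max trick)."""
    n, K = data.n, data.K
    spec = data.spec
    cal = data.hset.calendar
    s_c = params.s_cells(spec, n, cal.interval_season)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_surv = s_c ** data.dt[None, :]
        ls = np.log(p_surv)
        ld = np.log1p(-p_surv)
    ls[:, 0] = 0.0
    ld[:, 0] = 0.0
    csp = np.cumsum(ls, axis=1)  # col j = sum of survive-terms for intervals 1..j

    pcl_c = params.pcl_cells(spec, n, cal.occasion_season)
    with np.errstate(divide="ignore"):
        lp, lq = np.log(pcl_c), np.log1p(-pcl_c)
    a = np.zeros((n, K))
    live_active = data.post_rel & (data.is0 | data.is1)
    a[live_active & data.is1] = lp[live_active & data.is1]
    a[live_active & data.is0] = lq[live_active & data.is0]
    papad = np.zeros((n, K + 1))
    papad[:, 1:] = np.cumsum(a, axis=1)

    tcols = np.arange(1, K + 1)
    rows = np.arange(n)
    trans = csp[:, tcols - 1] - csp[rows, data.rel][:, None]
    ldpad = np.concatenate([ld, np.zeros((n, 1))], axis=1)
    w = trans + ldpad[:, tcols] + papad[:, tcols]

    if spec.include_dead_submodel:
        pcd_c = params.pcd_cells(spec, n, cal.occasion_season)
        with np.errstate(divide="ignore"):
            dp, dq = np.log(pcd_c), np.log1p(-pcd_c)
        b = np.zeros((n, K))
        dead_active = data.post_rel & (data.karr[None, :] <= data.end[:, None])
        b[dead_active & data.is2] = dp[dead_active & data.is2]
        b[dead_active & data.is0] = dq[dead_active & data.is0]
        bpad = np.concatenate([b, np.zeros((n, 1))], axis=1)
        if spec.shell_persistence == SINGLE_OCCASION:
            w = w + bpad[:, tcols]
        else:
            sbpad = np.zeros((n, K + 1))
            sbpad[:, :K] = np.cumsum(b[:, ::-1], axis=1)[:, ::-1]
            w = w + sbpad[:, tcols]

    w = np.where(data.allowed, w, -np.inf)
    g = rng.gumbel(size=(n, K))
    return 1 + np.argmax(w + g, axis=1)


def _interval_counts(data: _Data, tau: np.ndarray):
    """Per-interval survive counts and death counts from death occasions."""
    alive = data.alive_cells(tau)
    n_surv = alive.sum(axis=0)  # alive at k <=> survived the interval into k
    n_die = np.bincount(tau[tau <= data.K - 1], minlength=data.K)
    return n_surv, n_die


def _survival_logpost(s, exposure, die_dt, die_cnt):
    """Full-conditional log density of a pooled/seasonal monthly survival."""
    if not 0.0 < s < 1.0:
        return -np.inf
    out = exposure * math.log(s)
    for dt, c in zip(die_dt, die_cnt):
        out += c * math.log1p(-(s**dt))
    return out


class _Walker:
    """One adaptive logit-scale random-walk block."""

    def __init__(self, sd: float):
        self.sd = sd
        self.accepted = 0
        self.proposed = 0
        self.batch = 0

    def rate(self) -> float:
        return self.accepted / max(self.proposed, 1)

    def adapt(self, target: float):
        self.batch += 1
        rate = self.rate()
        self.sd = float(
            np.clip(self.sd * math.exp((rate - target) / math.sqrt(self.batch)), 1e-3, 20.0)
        )
        self.accepted = 0
        self.proposed = 0


def _metropolis_scalar(value, logpost, walker: _Walker, rng) -> float:
    """One logit-scale random-walk step for a (0,1)-valued parameter."""
    x = logit(value)
    xp = x + walker.sd * rng.standard_normal()
    vp = float(expit(xp))
    # logit proposal Jacobian: target_x(x) = target_v(v) + log v(1-v)
    delta = (
        logpost(vp)
        - logpost(value)
        + math.log(vp * (1 - vp))
        - math.log(value * (1 - value))
    )
    walker.proposed += 1
    if math.log(rng.uniform()) < delta:
        walker.accepted += 1
        return vp
    return value


def _metropolis_vector(values, loglik, lp_prior, walker: _Walker, rng):
    """Independent logit random-walk steps for a vector of (0,1) values."""
    x = logit(values)
    xp = x + walker.sd * rng.standard_normal(values.shape)
    vp = expit(xp)
    vp = np.clip(vp, 1e-12, 1 - 1e-12)
    delta = (
        loglik(vp)
        - loglik(values)
        + lp_prior(vp)
        - lp_prior(values)
        + np.log(vp * (1 - vp))
        - np.log(values * (1 - values))
    )
    acc = np.log(rng.uniform(size=values.shape)) < delta
    walker.proposed += values.size
    walker.accepted += int(acc.sum())
    return np.where(acc, vp, values)


@dataclass
class PosteriorDraws:
    """Retained MCMC output of :func:`run_chains`."""

    draws: dict[str, np.ndarray]  # name -> (n_chains, n_retained)
    deviance: np.ndarray  # (n_chains, n_retained)
    spec: ModelSpec
    config: McmcConfig
    n_individuals: int
    alive_freq: np.ndarray  # (n, K) posterior frequency of the alive state
    indiv_means: dict[str, np.ndarray] | None = None
    acceptance: dict[str, list[float]] = field(default_factory=dict)

    @property
    def param_names(self) -> list[str]:
        return list(self.draws)

    def stacked(self, name: str) -> np.ndarray:
        """All chains pooled into one vector."""
        return self.draws[name].reshape(-1)

    def posterior_mean(self, name: str) -> float:
        return float(self.stacked(name).mean())

    def posterior_mean_params(self) -> ParamState:
        """Plug-in ParamState built from posterior means."""
        spec = self.spec

        def grab(base):
            seasonal = {
                "S": spec.seasonal_S,
                "Pc_l": spec.seasonal_Pcl,
                "Pc_d": spec.seasonal_Pcd,
            }[base]
            prefix = f"mu_{base}" if spec.hierarchical else base
            if seasonal:
                return np.array(
                    [self.posterior_mean(f"{prefix}_summer"), self.posterior_mean(f"{prefix}_winter")]
                )
            return np.array([self.posterior_mean(prefix)])

        s = grab("S")
        pcl = grab("Pc_l")
        pcd = grab("Pc_d") if spec.include_dead_submodel else None
        st = ParamState(s, pcl, pcd)
        if spec.hierarchical:
            st.sigma_s = self.posterior_mean("sigma_S")
            st.sigma_pcl = self.posterior_mean("sigma_Pc_l")
            st.s_i = self.indiv_means["s_i"]
            st.pcl_i = self.indiv_means["pcl_i"]
            if spec.include_dead_submodel:
                st.sigma_pcd = self.posterior_mean("sigma_Pc_d")
                st.pcd_i = self.indiv_means["pcd_i"]
        return st

    def modal_death_times(self, hset: CaptureHistorySet) -> np.ndarray:
        """Per-cell posterior modal alive state, expressed as death occasions.

        The alive frequencies are monotone along each row, so the per-cell
        mode is itself a monotone path; it is clipped into the support
        allowed by the observations.
        """
        n, k = self.alive_freq.shape
        karr = np.arange(k)
        rel = hset.release
        mask = (karr[None, :] > rel[:, None]) & (self.alive_freq < 0.5)
        tau = np.where(mask.any(axis=1), np.argmax(mask, axis=1), k)
        tau = np.maximum(tau, hset.last_seen_alive() + 1)
        rec = hset.recovery_occasion()
        tau = np.where(rec >= 0, np.minimum(tau, rec), tau)
        if self.spec.shell_persistence == SINGLE_OCCASION:
            tau = np.where(rec >= 0, rec, tau)
        return tau

    def modal_latent(self, hset: CaptureHistorySet) -> LatentStateMatrix:
        return LatentStateMatrix.from_death_times(
            hset, self.modal_death_times(hset), self.spec
        )

    def to_frame(self):
        """Tidy draws table (chain, iteration, one column per parameter)."""
        import pandas as pd

        chains, ret = self.deviance.shape
        rows = {
            "chain": np.repeat(np.arange(chains), ret),
            "iteration": np.tile(np.arange(ret), chains),
        }
        for name, arr in self.draws.items():
            rows[name] = arr.reshape(-1)
        rows["deviance"] = self.deviance.reshape(-1)
        return pd.DataFrame(rows)


def _param_layout(spec: ModelSpec) -> list[tuple[str, str, int]]:
    """(draw name, family, season column) for every scalar parameter."""
    names = []

    def add(base, seasonal, family, n_cols):
        prefix = f"mu_{base}" if spec.hierarchical else base
        if seasonal:
            names.append((f"{prefix}_summer", family, 0))
            names.append((f"{prefix}_winter", family, 1))
        else:
            names.append((prefix, family, 0))

    add("S", spec.seasonal_S, "s", spec.n_seasons_S)
    add("Pc_l", spec.seasonal_Pcl, "pcl", spec.n_seasons_Pcl)
    if spec.include_dead_submodel:
        add("Pc_d", spec.seasonal_Pcd, "pcd", spec.n_seasons_Pcd)
    if spec.hierarchical:
        names.append(("sigma_S", "sigma_s", 0))
        names.append(("sigma_Pc_l", "sigma_pcl", 0))
        if spec.include_dead_submodel:
            names.append(("sigma_Pc_d", "sigma_pcd", 0))
    return names


def _scalar_value(params: ParamState, family: str, col: int) -> float:
    if family == "s":
        return float(params.s[col])
    if family == "pcl":
        return float(params.pcl[col])
    if family == "pcd":
        return float(params.pcd[col])
    if family == "sigma_s":
        return float(params.sigma_s)
    if family == "sigma_pcl":
        return float(params.sigma_pcl)
    if family == "sigma_pcd":
        return float(params.sigma_pcd)
    raise KeyError(family)


def _observation_deviance(data: _Data, params: ParamState, tau: np.ndarray) -> float:
    """-2 x observation-layer log-likelihood at the current state."""
    spec = data.spec
    cal = data.hset.calendar
    alive = data.alive_cells(tau)
    pcl_c = params.pcl_cells(spec, data.n, cal.occasion_season)
    with np.errstate(divide="ignore"):
        total = (
            np.where(data.is1 & alive, np.log(pcl_c), 0.0).sum()
            + np.where(data.is0 & alive, np.log1p(-pcl_c), 0.0).sum()
        )
        if spec.include_dead_submodel:
            dead = data.dead_cells(tau)
            pcd_c = params.pcd_cells(spec, data.n, cal.occasion_season)
            total += (
                np.where(data.is2 & dead, np.log(pcd_c), 0.0).sum()
                + np.where(data.is0 & dead, np.log1p(-pcd_c), 0.0).sum()
            )
    return float(-2.0 * total)


def _update_nonhier(data: _Data, params: ParamState, tau, walkers, rng):
    spec = data.spec
    alive = data.alive_cells(tau)
    for jj in range(spec.n_seasons_Pcl):
        mask = alive & (data.lidx[None, :] == jj)
        m = int(mask.sum())
        y = int((mask & data.is1).sum())
        params.pcl[jj] = rng.beta(1 + y, 1 + m - y)
    if spec.include_dead_submodel:
        dead = data.dead_cells(tau)
        for jj in range(spec.n_seasons_Pcd):
            mask = dead & (data.didx[None, :] == jj)
            m = int(mask.sum())
            y = int((mask & data.is2).sum())
            params.pcd[jj] = rng.beta(1 + y, 1 + m - y)
    n_surv, n_die = _interval_counts(data, tau)
    for jj in range(spec.n_seasons_S):
        ks = np.flatnonzero((data.sidx == jj) & (np.arange(data.K) >= 1))
        exposure = float((data.dt[ks] * n_surv[ks]).sum())
        die_ks = ks[n_die[ks] > 0]
        die_dt, die_cnt = data.dt[die_ks], n_die[die_ks]
        params.s[jj] = _metropolis_scalar(
            float(params.s[jj]),
            lambda s: _survival_logpost(s, exposure, die_dt, die_cnt),
            walkers[f"S[{jj}]"],
            rng,
        )


def _update_hier(data: _Data, params: ParamState, tau, walkers, rng):
    spec = data.spec
    n, K = data.n, data.K
    alive = data.alive_cells(tau)
    dead = data.dead_cells(tau) if spec.include_dead_submodel else None
    u = spec.prior_sd_upper
    with np.errstate(divide="ignore", invalid="ignore"):
        # individual live-detection probabilities
        for jj in range(spec.n_seasons_Pcl):
            mask = alive & (data.lidx[None, :] == jj)
            m_i = mask.sum(axis=1)
            y_i = (mask & data.is1).sum(axis=1)
            mu, sig = float(params.pcl[jj]), params.sigma_pcl
            params.pcl_i[:, jj] = _metropolis_vector(
                params.pcl_i[:, jj],
                lambda v: y_i * np.log(v) + (m_i - y_i) * np.log1p(-v),
                lambda v: truncnorm_logpdf(v, mu, sig),
                walkers[f"pcl_i[{jj}]"],
                rng,
            )
        # individual dead-detection probabilities
        if spec.include_dead_submodel:
            for jj in range(spec.n_seasons_Pcd):
                mask = dead & (data.didx[None, :] == jj)
                m_i = mask.sum(axis=1)
                y_i = (mask & data.is2).sum(axis=1)
                mu, sig = float(params.pcd[jj]), params.sigma_pcd
                params.pcd_i[:, jj] = _metropolis_vector(
                    params.pcd_i[:, jj],
                    lambda v: y_i * np.log(v) + (m_i - y_i) * np.log1p(-v),
                    lambda v: truncnorm_logpdf(v, mu, sig),
                    walkers[f"pcd_i[{jj}]"],
                    rng,
                )
        # individual monthly survival
        died = tau <= K - 1
        dt_die = np.where(died, data.dt[np.minimum(tau, K - 1)], 1.0)
        js_die = np.where(died, data.sidx[np.minimum(tau, K - 1)], -1)
        for jj in range(spec.n_seasons_S):
            season_cells = alive & (data.sidx[None, :] == jj) & (data.karr[None, :] >= 1)
            e_i = (season_cells * np.where(np.isnan(data.dt), 0.0, data.dt)[None, :]).sum(axis=1)
            die_here = js_die == jj
            mu, sig = float(params.s[jj]), params.sigma_s

            def loglik(v, e_i=e_i, die_here=die_here, dt_die=dt_die):
                out = e_i * np.log(v)
                return out + np.where(die_here, np.log1p(-(v**dt_die)), 0.0)

            params.s_i[:, jj] = _metropolis_vector(
                params.s_i[:, jj],
                loglik,
                lambda v: truncnorm_logpdf(v, mu, sig),
                walkers[f"s_i[{jj}]"],
                rng,
            )
    # hypermeans and shared SDs
    families = [("s", params.s_i, params.s, "sigma_s"), ("pcl", params.pcl_i, params.pcl, "sigma_pcl")]
    if spec.include_dead_submodel:
        families.append(("pcd", params.pcd_i, params.pcd, "sigma_pcd"))
    for fam, xi, mu_arr, signame in families:
        sig = getattr(params, signame)
        for jj in range(mu_arr.size):
            col = xi[:, jj]
            mu_arr[jj] = _metropolis_scalar(
                float(mu_arr[jj]),
                lambda m: float(truncnorm_logpdf(col, m, sig).sum()),
                walkers[f"mu_{fam}[{jj}]"],
                rng,
            )
        # SD shared across seasons, Uniform(0, prior_sd_upper) prior
        sig = getattr(params, signame)
        w = walkers[f"sigma_{fam}"]
        z = logit(sig / u) + w.sd * rng.standard_normal()
        sig_p = float(expit(z) * u)

        def sd_target(s):
            return float(truncnorm_logpdf(xi, mu_arr[None, :], s).sum())

        delta = (
            sd_target(sig_p)
            - sd_target(sig)
            + math.log(sig_p * (u - sig_p))
            - math.log(sig * (u - sig))
        )
        w.proposed += 1
        if math.log(rng.uniform()) < delta:
            w.accepted += 1
            setattr(params, signame, sig_p)


def _make_walkers(spec: ModelSpec, sd: float) -> dict[str, _Walker]:
    walkers = {}
    for jj in range(spec.n_seasons_S):
        walkers[f"S[{jj}]"] = _Walker(sd)
    if spec.hierarchical:
        for jj in range(spec.n_seasons_S):
            walkers[f"s_i[{jj}]"] = _Walker(sd)
            walkers[f"mu_s[{jj}]"] = _Walker(sd)
        for jj in range(spec.n_seasons_Pcl):
            walkers[f"pcl_i[{jj}]"] = _Walker(sd)
            walkers[f"mu_pcl[{jj}]"] = _Walker(sd)
        walkers["sigma_s"] = _Walker(sd)
        walkers["sigma_pcl"] = _Walker(sd)
        if spec.include_dead_submodel:
            for jj in range(spec.n_seasons_Pcd):
                walkers[f"pcd_i[{jj}]"] = _Walker(sd)
                walkers[f"mu_pcd[{jj}]"] = _Walker(sd)
            walkers["sigma_pcd"] = _Walker(sd)
    return walkers


def run_chains(
    hset: CaptureHistorySet, spec: ModelSpec, config: McmcConfig
) -> PosteriorDraws:
    """Run the full data-augmentation sampler.

    One sweep = latent Gibbs update + every parameter block; burn-in
    draws are discarded and the rest thinned.  The deviance (-2 x
    observation-layer log-likelihood) is recorded for every retained draw,
    and the per-cell alive frequencies are accumulated for the DIC latent
    plug-in.
    """
    data = _Data(hset, spec)
    layout = _param_layout(spec)
    n_ret = config.n_retained
    draws = {name: np.empty((config.n_chains, n_ret)) for name, _, _ in layout}
    deviance = np.empty((config.n_chains, n_ret))
    alive_counts = np.zeros((data.n, data.K))
    indiv_sums = (
        {
            "s_i": np.zeros((data.n, spec.n_seasons_S)),
            "pcl_i": np.zeros((data.n, spec.n_seasons_Pcl)),
            **(
                {"pcd_i": np.zeros((data.n, spec.n_seasons_Pcd))}
                if spec.include_dead_submodel
                else {}
            ),
        }
        if spec.hierarchical
        else None
    )
    acceptance: dict[str, list[float]] = {}

    for chain in range(config.n_chains):
        rng = np.random.default_rng(config.seed + chain)
        params = ParamState.initial(spec, data.n, rng)
        latent0 = models.init_latent_states(hset, spec)
        tau = latent0.death_occasion.copy()
        if not np.isfinite(
            models.complete_data_loglik(hset, latent0, params, spec)
        ):
            raise InitializationError("non-finite likelihood at initialization")
        walkers = _make_walkers(spec, config.proposal_sd)
        kept = 0
        for it in range(config.n_iter):
            tau = _draw_death_times(data, params, rng)
            if spec.hierarchical:
                _update_hier(data, params, tau, walkers, rng)
            else:
                _update_nonhier(data, params, tau, walkers, rng)
            if config.adapt and it < config.burn_in and (it + 1) % config.adapt_window == 0:
                for w in walkers.values():
                    w.adapt(config.target_accept)
            if it >= config.burn_in and (it - config.burn_in) % config.thin == config.thin - 1:
                for name, fam, col in layout:
                    draws[name][chain, kept] = _scalar_value(params, fam, col)
                deviance[chain, kept] = _observation_deviance(data, params, tau)
                alive_counts += data.alive_cells(tau)
                if indiv_sums is not None:
                    indiv_sums["s_i"] += params.s_i
                    indiv_sums["pcl_i"] += params.pcl_i
                    if spec.include_dead_submodel:
                        indiv_sums["pcd_i"] += params.pcd_i
                kept += 1
        for name, w in walkers.items():
            acceptance.setdefault(name, []).append(w.rate())

    total_kept = config.n_chains * n_ret
    indiv_means = (
        {k: v / total_kept for k, v in indiv_sums.items()} if indiv_sums else None
    )
    return PosteriorDraws(
        draws=draws,
        deviance=deviance,
        spec=spec,
        config=config,
        n_individuals=data.n,
        alive_freq=alive_counts / total_kept,
        indiv_means=indiv_means,
        acceptance=acceptance,
    )


# -- single-step updates exposed for testing and composition --------------


def update_latent_states(
    latent: LatentStateMatrix,
    hset: CaptureHistorySet,
    params: ParamState,
    spec: ModelSpec,
    rng,
) -> LatentStateMatrix:
    """Resample every row's unobserved trajectory from its full conditional."""
    data = _Data(hset, spec)
    tau = _draw_death_times(data, params, rng)
    return LatentStateMatrix.from_death_times(hset, tau, spec)


def update_detection(
    latent: LatentStateMatrix,
    hset: CaptureHistorySet,
    spec: ModelSpec,
    season: int | None,
    which: str,
    rng,
) -> float:
    """Conjugate Beta draw for a detection probability.

    Trials are post-release occasions with L = 1 (``which="live"``) or
    D = 1 (``which="dead"``) in the given season (1 = summer, 2 = winter,
    None = pooled); successes are the matching detections.
    """
    if which not in ("live", "dead"):
        raise ValueError("which must be 'live' or 'dead'")
    k = hset.n_occasions
    karr = np.arange(k)
    post_rel = karr[None, :] > hset.release[:, None]
    in_season = (
        np.ones(k, bool)
        if season is None
        else hset.calendar.occasion_season == season
    )
    if which == "live":
        at_risk = (latent.L == 1) & post_rel & in_season[None, :]
        succ = (hset.codes == SEEN) & at_risk
    else:
        at_risk = (latent.D == 1) & post_rel & in_season[None, :]
        succ = (hset.codes == DEAD_RECOVERY) & at_risk
    m, y = int(at_risk.sum()), int(succ.sum())
    return float(rng.beta(1 + y, 1 + m - y))


def update_survival(
    latent: LatentStateMatrix,
    hset: CaptureHistorySet,
    spec: ModelSpec,
    season: int | None,
    current: float,
    proposal_sd: float,
    rng,
    n_steps: int = 1,
) -> float:
    """Metropolis random-walk draw(s) of a monthly survival rate.

    The full conditional is the product of Bernoulli transition terms of
    the intervals in the given season (interval-season label; None =
    pooled) at the current latent states, with a Uniform(0,1) prior.
    """
    cal = hset.calendar
    k = hset.n_occasions
    tau = latent.death_occasion
    karr = np.arange(k)
    alive = (karr[None, :] > hset.release[:, None]) & (karr[None, :] < tau[:, None])
    n_surv = alive.sum(axis=0)
    n_die = np.bincount(tau[tau <= k - 1], minlength=k)
    dt = np.concatenate([[np.nan], cal.delta_t])
    labels = np.concatenate([[0], cal.interval_season])
    ks = np.flatnonzero(
        (np.arange(k) >= 1) & (np.ones(k, bool) if season is None else labels == season)
    )
    exposure = float((dt[ks] * n_surv[ks]).sum())
    die_ks = ks[n_die[ks] > 0]
    die_dt, die_cnt = dt[die_ks], n_die[die_ks]
    walker = _Walker(proposal_sd)
    value = float(current)
    for _ in range(n_steps):
        value = _metropolis_scalar(
            value,
            lambda s: _survival_logpost(s, exposure, die_dt, die_cnt),
            walker,
            rng,
        )
    return value


def update_hierarchical(
    latent: LatentStateMatrix,
    hset: CaptureHistorySet,
    params: ParamState,
    spec: ModelSpec,
    rng,
    proposal_sd: float = 0.5,
) -> ParamState:
    """One sweep over individual effects, hypermeans and shared SDs."""
    if not spec.hierarchical:
        raise ValueError("update_hierarchical requires a hierarchical spec")
    data = _Data(hset, spec)
    out = params.copy()
    walkers = _make_walkers(spec, proposal_sd)
    _update_hier(data, out, latent.death_occasion, walkers, rng)
    return out
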