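"""Hierarchical Bayesian estimation of plot-level demographic effects.

Each inventory plot carries a six-dimensional latent effect vector

    v = (E_G earlier, E_M^small earlier, E_M^large earlier,
         E_G recent,  E_M^small recent,  E_M^large recent)

describing how much that plot's tree growth and mortality deviated from the
background demographic model in each census period.  Mortality effects act
additively on the logit of the annual background mortality rate,

    M' = logit^-1(logit(M) + E_M),

which for small rates is close to a multiplicative effect ``M' ~ exp(E_M)*M``
— so across plots ``exp(E_M)`` is approximately log-normal.  Growth effects
are multiplicative: ``G' = exp(E_G) * G`` (the stored component is the log
multiplier, keeping the whole vector real-valued and Gaussian).

Within a forest region the vectors are exchangeable draws from a
multivariate normal, ``v ~ MVN(mu, Sigma)``; tree observations are Bernoulli
(death over the census interval, annual rate compounded) and Normal
(diameter increment, residual sd ``sigma*sqrt(interval)``).  ``(mu, Sigma)``
and ``sigma`` get weakly-informative conjugate priors and everything is
estimated jointly by MCMC: vectorized per-plot Metropolis moves for the
effect components interleaved with conjugate hierarchical inverse-Wishart
(Huang–Wand) and Inverse-Gamma updates.  Plots with no trees in some size
class or period
still receive posteriors for the corresponding components, informed through
the estimated covariance (Gaussian conditioning).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from .demography import DemographyParams, vector_rates

__all__ = [
    "COMPONENTS",
    "PlotEffectVector",
    "RegionEffectDistribution",
    "FitConfig",
    "PosteriorSummary",
    "apply_mortality_effect",
    "approx_mortality_effect",
    "apply_growth_effect",
    "derive_blocks",
    "log_likelihood",
    "fit_region",
]

#: Fixed component ordering of the plot-effect vector.
COMPONENTS = (
    "growth_earlier",
    "mort_small_earlier",
    "mort_large_earlier",
    "growth_recent",
    "mort_small_recent",
    "mort_large_recent",
)

GROWTH_IDX = {"earlier": 0, "recent": 3}
MORT_IDX = {
    ("small", "earlier"): 1,
    ("large", "earlier"): 2,
    ("small", "recent"): 4,
    ("large", "recent"): 5,
}


@dataclass(frozen=True)
class PlotEffectVector:
    """One plot's six effects, in the :data:`COMPONENTS` order."""

    v: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.v, dtype=float)
        if arr.shape != (6,):
            raise ValueError("plot effect vector must have 6 components")
        if not np.all(np.isfinite(arr)):
            raise ValueError("plot effects must be finite")
        object.__setattr__(self, "v", arr)

    def __getitem__(self, name: str) -> float:
        return float(self.v[COMPONENTS.index(name)])


def _check_spd(mat: np.ndarray, name: str) -> None:
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    if np.linalg.eigvalsh(mat).min() <= 0:
        raise ValueError(f"{name} must be positive definite")


@dataclass(frozen=True)
class RegionEffectDistribution:
    """Region-level MVN over plot-effect vectors: mean ``mu`` and 6x6 ``sigma_mat``.

    ``sigma_growth`` is the growth residual sd carried with the fit.  The
    within-period (``c0``) and cross-period (``c1``) 3x3 blocks used by the
    effect simulator derive from ``sigma_mat`` via :func:`derive_blocks`.
    """

    mu: np.ndarray
    sigma_mat: np.ndarray
    sigma_growth: float = 0.15

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=float)
        sig = np.asarray(self.sigma_mat, dtype=float)
        if mu.shape != (6,) or sig.shape != (6, 6):
            raise ValueError("mu must be length 6 and sigma_mat 6x6")
        _check_spd(sig, "sigma_mat")
        if self.sigma_growth <= 0:
            raise ValueError("sigma_growth must be > 0")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma_mat", sig)

    @property
    def c0(self) -> np.ndarray:
        return derive_blocks(self)[0]

    @property
    def c1(self) -> np.ndarray:
        return derive_blocks(self)[1]

    def correlation(self) -> np.ndarray:
        sd = np.sqrt(np.diag(self.sigma_mat))
        return self.sigma_mat / np.outer(sd, sd)


def derive_blocks(dist: "RegionEffectDistribution | np.ndarray"):
    """Split a 6x6 effect covariance into within- and cross-period 3x3 blocks.

    ``c0`` is the (symmetrized) average of the earlier and recent diagonal
    blocks; ``c1`` is the symmetrized earlier-by-recent block.  ``c0`` must be
    positive definite.
    """
    sigma = dist.sigma_mat if isinstance(dist, RegionEffectDistribution) else np.asarray(dist)
    if sigma.shape != (6, 6):
        raise ValueError("expected a 6x6 covariance")
    d_e = sigma[:3, :3]
    d_r = sigma[3:, 3:]
    c0 = 0.5 * (d_e + d_r)
    c0 = 0.5 * (c0 + c0.T)
    b = sigma[:3, 3:]
    c1 = 0.5 * (b + b.T)
    if np.linalg.eigvalsh(c0).min() <= 0:
        raise ValueError("within-period covariance block c0 is not positive definite")
    return c0, c1


# ---------------------------------------------------------------------------
# effect application


def apply_mortality_effect(m, e_m):
    """Exact logit-offset mortality effect: ``logit^-1(logit(m) + e_m)``."""
    m = np.asarray(m, dtype=float)
    if np.any((m <= 0) | (m >= 1)):
        raise ValueError("annual mortality must lie strictly in (0, 1)")
    return expit(logit(m) + np.asarray(e_m, dtype=float))


def approx_mortality_effect(m, e_m):
    """Multiplicative approximation ``exp(e_m)*m`` (clipped at 1).

    Accurate for small rates, where odds ~ probability.
    """
    m = np.asarray(m, dtype=float)
    if np.any((m <= 0) | (m >= 1)):
        raise ValueError("annual mortality must lie strictly in (0, 1)")
    return np.minimum(np.exp(np.asarray(e_m, dtype=float)) * m, 1.0)


def apply_growth_effect(g, e_g):
    """Multiplicative growth effect ``exp(e_g)*g`` (``e_g`` is the log multiplier)."""
    g = np.asarray(g, dtype=float)
    if np.any(g < 0):
        raise ValueError("growth must be >= 0")
    return np.exp(np.asarray(e_g, dtype=float)) * g


# ---------------------------------------------------------------------------
# likelihood machinery


class _Design:
    """Flattened per-tree arrays for one set of inventory tables."""

    def __init__(self, trees: pd.DataFrame, plots: pd.DataFrame, params: DemographyParams):
        plot_meta = plots.drop_duplicates("plot_id").set_index("plot_id")
        self.plot_ids = np.asarray(plot_meta.index)
        self.n_plots = len(self.plot_ids)
        pos = {pid: i for i, pid in enumerate(self.plot_ids)}

        t = trees.reset_index(drop=True).copy()
        missing = set(t["plot_id"]) - set(pos)
        if missing:
            raise ValueError(f"tree rows reference unknown plot ids: {sorted(missing)[:5]}")
        t["_pos"] = t["plot_id"].map(pos).to_numpy()
        t["_mat"] = plot_meta["mat"].reindex(t["plot_id"]).to_numpy()
        t["_map"] = plot_meta["map"].reindex(t["plot_id"]).to_numpy()
        # census interval is a plot x period attribute
        iv = plots.set_index(["plot_id", "period"])["interval_yr"]
        t["_dt"] = iv.reindex(pd.MultiIndex.from_frame(t[["plot_id", "period"]])).to_numpy()
        if t["_dt"].isna().any():
            raise ValueError("tree rows reference plot/period pairs missing from the plot table")

        g_bg = np.empty(len(t))
        m_bg = np.empty(len(t))
        for pft, grp in t.groupby("pft", sort=False):
            idx = grp.index.to_numpy()
            g, m = vector_rates(
                grp["dbh_t0"].to_numpy(),
                grp["shading_cai"].to_numpy(),
                grp["_mat"].to_numpy(),
                grp["_map"].to_numpy(),
                str(pft),
                params,
            )
            g_bg[idx] = g
            m_bg[idx] = m

        comp_m = np.array(
            [MORT_IDX[(s, p)] for s, p in zip(t["size_class"], t["period"])], dtype=int
        )
        self.mort_pos = t["_pos"].to_numpy(int)
        self.mort_comp = comp_m
        self.mort_died = (t["status_t1"].to_numpy() == "dead").astype(float)
        self.mort_dt = t["_dt"].to_numpy(float)
        self.mort_logit_m = logit(m_bg)

        grow = t[t["dbh_t1"].notna() & (t["status_t1"] == "live")]
        gidx = grow.index.to_numpy()
        self.grow_pos = grow["_pos"].to_numpy(int)
        self.grow_comp = np.array([GROWTH_IDX[p] for p in grow["period"]], dtype=int)
        self.grow_y = (grow["dbh_t1"] - grow["dbh_t0"]).to_numpy(float)
        self.grow_gdt = g_bg[gidx] * grow["_dt"].to_numpy(float)
        self.grow_dt = grow["_dt"].to_numpy(float)

    # per-tree log-likelihood pieces -------------------------------------
    def mort_loglik(self, e: np.ndarray, sel: np.ndarray) -> np.ndarray:
        """Bernoulli log-mass for mortality trees ``sel`` at effect values ``e``."""
        x = self.mort_logit_m[sel] + e
        log1m_annual = -np.logaddexp(0.0, x)  # log(1 - m')
        log_surv = self.mort_dt[sel] * log1m_annual
        died = self.mort_died[sel]
        with np.errstate(divide="ignore"):
            log_q = np.log(-np.expm1(log_surv))
        return np.where(died == 1.0, log_q, log_surv)

    def grow_loglik(self, e: np.ndarray, sel: np.ndarray, sigma: float) -> np.ndarray:
        """Normal log-density of diameter increments ``sel`` at effect values ``e``."""
        mean = np.exp(e) * self.grow_gdt[sel]
        var = sigma * sigma * self.grow_dt[sel]
        resid = self.grow_y[sel] - mean
        return -0.5 * (resid * resid / var + np.log(2.0 * np.pi * var))


def _effects_matrix(effects, plot_ids: np.ndarray) -> np.ndarray:
    """Normalize user-supplied effects into an (n_plots, 6) array."""
    if isinstance(effects, pd.DataFrame):
        sub = effects.reindex(plot_ids)
        if sub.isna().any().any():
            raise ValueError("effects missing for some plot ids")
        return sub[list(COMPONENTS)].to_numpy(float)
    out = np.empty((len(plot_ids), 6))
    for i, pid in enumerate(plot_ids):
        try:
            vec = effects[pid]
        except KeyError:
            raise ValueError(f"effects missing for plot id {pid!r}") from None
        out[i] = vec.v if isinstance(vec, PlotEffectVector) else np.asarray(vec, float)
    return out


def log_likelihood(tables, effects, dist: RegionEffectDistribution, params: DemographyParams) -> float:
    """Joint log density of tree observations and plot effects.

    Sums, over all trees, the Bernoulli log-mass of the observed survival
    outcome (annual effect-adjusted mortality compounded over the census
    interval) and the Normal log-density of the observed diameter increment
    (effect-adjusted expected growth, residual sd ``sigma*sqrt(interval)``),
    plus the MVN(mu, Sigma) log-density of every plot's effect vector.
    """
    design = _Design(tables.trees, tables.plots, params)
    v = _effects_matrix(effects, design.plot_ids)
    all_m = np.arange(len(design.mort_pos))
    e_m = v[design.mort_pos, design.mort_comp]
    ll = design.mort_loglik(e_m, all_m).sum()
    all_g = np.arange(len(design.grow_pos))
    e_g = v[design.grow_pos, design.grow_comp]
    ll += design.grow_loglik(e_g, all_g, dist.sigma_growth).sum()
    ll += stats.multivariate_normal.logpdf(v, mean=dist.mu, cov=dist.sigma_mat).sum()
    return float(ll)


# ---------------------------------------------------------------------------
# MCMC


@dataclass(frozen=True)
class FitConfig:
    """Sampler settings and priors for :func:`fit_region`.

    Priors are weakly informative (fully flat priors on a covariance are
    improper): the region covariance Sigma gets a marginally-noninformative
    hierarchical inverse-Wishart (Huang–Wand) prior with ``hw_nu = 2`` —
    marginally uniform(-1, 1) correlations and half-t sds with scale
    ``hw_scale`` — which avoids the variance–correlation coupling that makes
    a plain inverse-Wishart informative about correlations exactly where
    tree-level data are weakest; mu is Normal(0, ``mu_sd``^2) per component;
    the growth residual variance is Inverse-Gamma(``a0``, ``b0``).
    """

    chains: int = 2
    draws: int = 1000
    burn: int = 1000
    thin: int = 1
    seed: int = 0
    hw_nu: float = 2.0
    hw_scale: float = 2.5
    mu_sd: float = 10.0
    a0: float = 0.01
    b0: float = 0.01
    target_accept: float = 0.35
    rhat_threshold: float = 1.05
    fix_hyper: "tuple[np.ndarray, np.ndarray, float] | None" = None
    store_plot_draws: "Sequence | str | None" = None


@dataclass
class PosteriorSummary:
    """Posterior summaries from one region fit.

    ``plot_effects`` holds per-plot posterior mean and sd for each of the
    six components (wide, indexed by plot id).  ``mu_draws`` has shape
    (chains, draws, 6), ``sigma_mat_draws`` (chains, draws, 6, 6) and
    ``sigma_growth_draws`` (chains, draws).  ``diagnostics`` maps quantity
    names to split-R-hat and bulk effective sample size; ``converged`` is
    False (with ``warning``) when any R-hat exceeds the configured threshold.
    """

    plot_ids: np.ndarray
    plot_effects: pd.DataFrame
    mu_draws: np.ndarray
    sigma_mat_draws: np.ndarray
    sigma_growth_draws: np.ndarray
    diagnostics: dict
    converged: bool
    warning: str | None = None
    effect_draws: "dict | None" = None

    @property
    def mu_mean(self) -> np.ndarray:
        return self.mu_draws.reshape(-1, 6).mean(axis=0)

    @property
    def sigma_mat_mean(self) -> np.ndarray:
        return self.sigma_mat_draws.reshape(-1, 6, 6).mean(axis=0)

    @property
    def sigma_growth_mean(self) -> float:
        return float(self.sigma_growth_draws.mean())

    def correlation_mean(self) -> np.ndarray:
        """Posterior-mean effect correlation matrix (mean of per-draw correlations)."""
        draws = self.sigma_mat_draws.reshape(-1, 6, 6)
        sd = np.sqrt(np.einsum("kii->ki", draws))
        return (draws / (sd[:, :, None] * sd[:, None, :])).mean(axis=0)

    def mu_interval(self, prob: float = 0.90) -> np.ndarray:
        """Central credible interval for each mu component, shape (6, 2)."""
        flat = self.mu_draws.reshape(-1, 6)
        lo = np.quantile(flat, (1 - prob) / 2, axis=0)
        hi = np.quantile(flat, 1 - (1 - prob) / 2, axis=0)
        return np.column_stack([lo, hi])

    def distribution(self) -> RegionEffectDistribution:
        """Posterior-mean region effect distribution."""
        return RegionEffectDistribution(
            mu=self.mu_mean,
            sigma_mat=self.sigma_mat_mean,
            sigma_growth=self.sigma_growth_mean,
        )


def _run_chain(design: _Design, cfg: FitConfig, seed: int, store_idx: np.ndarray):
    rng = np.random.default_rng(seed)
    n = design.n_plots
    fixed = cfg.fix_hyper is not None
    if fixed:
        mu = np.asarray(cfg.fix_hyper[0], float).copy()
        sigma_mat = np.asarray(cfg.fix_hyper[1], float).copy()
        sigma_g = float(cfg.fix_hyper[2])
    else:
        mu = np.zeros(6)
        sigma_mat = np.eye(6) * 0.25
        sigma_g = 0.2
    v = mu + 0.1 * rng.standard_normal((n, 6))
    aux = np.full(6, cfg.hw_scale**2)  # Huang-Wand auxiliary scales

    # tree indices per component
    mort_sets = [np.flatnonzero(design.mort_comp == c) for c in range(6)]
    grow_sets = [np.flatnonzero(design.grow_comp == c) for c in range(6)]

    # approximate per-plot likelihood information, for proposal scaling
    info = np.zeros((n, 6))
    m_ann = expit(design.mort_logit_m)
    np.add.at(info, (design.mort_pos, design.mort_comp), design.mort_dt * m_ann)
    np.add.at(
        info,
        (design.grow_pos, design.grow_comp),
        design.grow_gdt**2 / (0.15**2 * design.grow_dt),
    )
    log_scale = np.zeros(6)  # adaptive global log step scale per component
    mu_step = np.full(6, 0.1)  # adaptive scale of the joint translation move

    n_keep = cfg.draws
    mu_out = np.empty((n_keep, 6))
    sig_out = np.empty((n_keep, 6, 6))
    sg_out = np.empty(n_keep)
    v_sum = np.zeros((n, 6))
    v_sumsq = np.zeros((n, 6))
    v_store = np.empty((n_keep, len(store_idx), 6)) if len(store_idx) else None

    total = cfg.burn + cfg.draws * cfg.thin
    for it in range(total):
        lam = np.linalg.inv(sigma_mat)
        # --- per-component vectorized random-walk Metropolis on v ---------
        for c in range(6):
            cond_prec = lam[c, c]
            resid = (v - mu) @ lam[:, c] - (v[:, c] - mu[c]) * cond_prec
            cond_mean = mu[c] - resid / cond_prec
            step = np.exp(log_scale[c]) * 2.4 / np.sqrt(cond_prec + info[:, c])
            prop = v[:, c] + step * rng.standard_normal(n)

            delta = np.zeros(n)
            ms = mort_sets[c]
            if len(ms):
                pos = design.mort_pos[ms]
                d_ll = design.mort_loglik(prop[pos], ms) - design.mort_loglik(v[pos, c], ms)
                delta += np.bincount(pos, weights=d_ll, minlength=n)
            gs = grow_sets[c]
            if len(gs):
                pos = design.grow_pos[gs]
                d_ll = design.grow_loglik(prop[pos], gs, sigma_g) - design.grow_loglik(
                    v[pos, c], gs, sigma_g
                )
                delta += np.bincount(pos, weights=d_ll, minlength=n)
            delta += -0.5 * cond_prec * ((prop - cond_mean) ** 2 - (v[:, c] - cond_mean) ** 2)
            accept = np.log(rng.random(n)) < delta
            v[accept, c] = prop[accept]
            if it < cfg.burn:
                rate = accept.mean()
                log_scale[c] += (rate - cfg.target_accept) / np.sqrt(1.0 + 0.1 * it)

            # independence proposal from the conditional prior: plots with
            # little or no data in this component mix in one step instead of
            # random-walking (their likelihood delta is ~0)
            cond_sd = 1.0 / np.sqrt(cond_prec)
            prop = cond_mean + cond_sd * rng.standard_normal(n)
            delta = np.zeros(n)
            if len(ms):
                pos = design.mort_pos[ms]
                d_ll = design.mort_loglik(prop[pos], ms) - design.mort_loglik(v[pos, c], ms)
                delta += np.bincount(pos, weights=d_ll, minlength=n)
            if len(gs):
                pos = design.grow_pos[gs]
                d_ll = design.grow_loglik(prop[pos], gs, sigma_g) - design.grow_loglik(
                    v[pos, c], gs, sigma_g
                )
                delta += np.bincount(pos, weights=d_ll, minlength=n)
            accept = np.log(rng.random(n)) < delta
            v[accept, c] = prop[accept]

            # joint translation of (mu_c, v[:, c]): breaks the slow random
            # walk of weakly-identified hyperparameter means through the
            # hierarchy (the group-level prior term is shift-invariant)
            if not fixed:
                shift = mu_step[c] * rng.standard_normal()
                d_ll = 0.0
                if len(ms):
                    pos = design.mort_pos[ms]
                    d_ll += (
                        design.mort_loglik(v[pos, c] + shift, ms)
                        - design.mort_loglik(v[pos, c], ms)
                    ).sum()
                if len(gs):
                    pos = design.grow_pos[gs]
                    d_ll += (
                        design.grow_loglik(v[pos, c] + shift, gs, sigma_g)
                        - design.grow_loglik(v[pos, c], gs, sigma_g)
                    ).sum()
                # prior on mu: mu_c ~ N(0, mu_sd^2)
                d_ll += -0.5 / cfg.mu_sd**2 * ((mu[c] + shift) ** 2 - mu[c] ** 2)
                if np.log(rng.random()) < d_ll:
                    v[:, c] += shift
                    mu[c] += shift
                    cond_mean = cond_mean + shift
                    if it < cfg.burn:
                        mu_step[c] *= 1.03
                elif it < cfg.burn:
                    mu_step[c] *= 0.99

        # --- conjugate hyperparameter updates ------------------------------
        if not fixed:
            # Sigma | v, mu, aux  (Huang-Wand hierarchical inverse-Wishart)
            resid_v = v - mu
            s_mu = resid_v.T @ resid_v
            df_n = cfg.hw_nu + 5.0 + n  # (nu + d - 1) + n with d = 6
            scale_n = 2.0 * cfg.hw_nu * np.diag(1.0 / aux) + s_mu
            sigma_mat = stats.invwishart.rvs(df=df_n, scale=scale_n, random_state=rng)
            # aux_k | Sigma ~ InvGamma((nu + d)/2, nu*(Sigma^-1)_kk + 1/A^2)
            lam_new = np.linalg.inv(sigma_mat)
            a_shape = 0.5 * (cfg.hw_nu + 6.0)
            a_rate = cfg.hw_nu * np.diag(lam_new) + 1.0 / cfg.hw_scale**2
            aux = 1.0 / rng.gamma(a_shape, 1.0 / a_rate)
            # mu | Sigma, v  (Normal prior, semi-conjugate)
            prec = n * lam_new + np.eye(6) / cfg.mu_sd**2
            cov_mu = np.linalg.inv(prec)
            mean_mu = cov_mu @ (lam_new @ v.sum(axis=0))
            mu = rng.multivariate_normal(mean_mu, cov_mu)

            if len(design.grow_y):
                e_g = v[design.grow_pos, design.grow_comp]
                resid2 = (design.grow_y - np.exp(e_g) * design.grow_gdt) ** 2 / design.grow_dt
                a = cfg.a0 + 0.5 * len(design.grow_y)
                b = cfg.b0 + 0.5 * resid2.sum()
                sigma_g = float(np.sqrt(1.0 / rng.gamma(a, 1.0 / b)))

        if it >= cfg.burn and (it - cfg.burn) % cfg.thin == 0:
            k = (it - cfg.burn) // cfg.thin
            mu_out[k] = mu
            sig_out[k] = sigma_mat
            sg_out[k] = sigma_g
            v_sum += v
            v_sumsq += v * v
            if v_store is not None:
                v_store[k] = v[store_idx]

    return mu_out, sig_out, sg_out, v_sum, v_sumsq, v_store


def fit_region(
    tables,
    region,
    config: FitConfig | None = None,
    params: DemographyParams | None = None,
) -> PosteriorSummary:
    """Fit the hierarchical plot-effect model for one forest region.

    Returns posterior summaries for every plot's six effects and for the
    region-level hyperparameters (mu, Sigma, sigma).  Convergence is
    assessed with split-R-hat and effective sample size on mu and sigma
    across chains; a failed check sets ``converged=False`` and raises a
    warning, never silently.

    With ``config.fix_hyper = (mu, sigma_mat, sigma_growth)`` the
    hyperparameters are held fixed (useful for oracle checks and for
    conditioning studies); otherwise at least two plots are required.
    """
    cfg = config or FitConfig()
    plots = tables.plots[tables.plots["region"] == region]
    if plots.empty:
        raise ValueError(f"region {region!r} not present in plot table")
    trees = tables.trees[tables.trees["plot_id"].isin(plots["plot_id"])]
    n_plots = plots["plot_id"].nunique()
    if cfg.fix_hyper is None and n_plots < 2:
        raise ValueError("need at least 2 plots to estimate region hyperparameters")

    if params is None:
        from .demography import default_params

        params = default_params()
    design = _Design(trees, plots.reset_index(drop=True), params)

    if cfg.store_plot_draws is None:
        store_idx = np.array([], dtype=int)
    elif isinstance(cfg.store_plot_draws, str) and cfg.store_plot_draws == "all":
        store_idx = np.arange(design.n_plots)
    else:
        wanted = set(cfg.store_plot_draws)
        store_idx = np.array([i for i, pid in enumerate(design.plot_ids) if pid in wanted], int)

    results = [
        _run_chain(design, cfg, int(np.random.SeedSequence([cfg.seed, ch]).generate_state(1)[0] % (2**31)), store_idx)
        for ch in range(cfg.chains)
    ]
    mu_draws = np.stack([r[0] for r in results])
    sig_draws = np.stack([r[1] for r in results])
    sg_draws = np.stack([r[2] for r in results])
    v_mean = sum(r[3] for r in results) / (cfg.chains * cfg.draws)
    v_second = sum(r[4] for r in results) / (cfg.chains * cfg.draws)
    v_sd = np.sqrt(np.maximum(v_second - v_mean**2, 0.0))

    effect_draws = None
    if len(store_idx):
        stacked = np.concatenate([r[5] for r in results], axis=0)
        effect_draws = {design.plot_ids[j]: stacked[:, k] for k, j in enumerate(store_idx)}

    import arviz as az

    idata = az.from_dict(
        posterior={
            "mu": mu_draws,
            "sigma_growth": sg_draws,
        }
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = az.rhat(idata)
        ess = az.ess(idata)
    diag = {
        "rhat_mu": np.asarray(rhat["mu"]),
        "rhat_sigma_growth": float(rhat["sigma_growth"]),
        "ess_mu": np.asarray(ess["mu"]),
        "ess_sigma_growth": float(ess["sigma_growth"]),
    }
    if cfg.fix_hyper is not None:
        # hyperparameters are constants; R-hat on them is undefined
        converged, warning = True, None
    else:
        worst = max(np.max(diag["rhat_mu"]), diag["rhat_sigma_growth"])
        converged = bool(worst <= cfg.rhat_threshold)
        warning = None
        if not converged:
            warning = f"sampler convergence check failed: max split-R-hat = {worst:.3f}"
            warnings.warn(warning, RuntimeWarning, stacklevel=2)

    cols = {}
    for c, name in enumerate(COMPONENTS):
        cols[f"mean_{name}"] = v_mean[:, c]
        cols[f"sd_{name}"] = v_sd[:, c]
    plot_effects = pd.DataFrame(cols, index=pd.Index(design.plot_ids, name="plot_id"))

    return PosteriorSummary(
        plot_ids=design.plot_ids,
        plot_effects=plot_effects,
        mu_draws=mu_draws,
        sigma_mat_draws=sig_draws,
        sigma_growth_draws=sg_draws,
        diagnostics=diag,
        converged=converged,
        warning=warning,
        effect_draws=effect_draws,
    )
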