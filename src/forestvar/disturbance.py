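"""Disturbance statistics derived from estimated plot-effect distributions.

Three summaries:

* a Monte-Carlo comparison of the observed distribution of plot-level
  mortality fractions against what tree-level background rates alone can
  produce — an upper-tail deficit in the simulated curve is the signature
  of disturbance;
* the probability that a plot's mortality effect implies at least a
  ``threshold``-fold elevation of its expected mortality rate (on the
  multiplicative ``exp(E_M)`` scale, under which the effect multiplier is
  log-normal), either relative to the region mean or to the plot's own
  long-term mean;
* pairwise correlations among plot effects (growth vs mortality, small vs
  large trees, earlier vs recent period).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .demography import DemographyParams, vector_rates
from .effects import COMPONENTS, PosteriorSummary, RegionEffectDistribution, derive_blocks

__all__ = [
    "DisturbanceSummary",
    "simulate_plot_mortality_cdf",
    "disturbance_probability",
    "region_disturbance_probability",
    "effect_correlations",
    "CORRELATION_PAIRS",
]


@dataclass(frozen=True)
class DisturbanceSummary:
    """Per-region fourfold-elevation probabilities and effect correlations."""

    fourfold_probability: pd.DataFrame
    correlations: pd.DataFrame

    def __post_init__(self) -> None:
        p = self.fourfold_probability.select_dtypes("number").to_numpy()
        if np.any((p < 0) | (p > 1)):
            raise ValueError("probabilities must lie in [0, 1]")


def simulate_plot_mortality_cdf(tables, params: DemographyParams, seed: int = 0) -> pd.DataFrame:
    """Observed vs background-simulated CDFs of plot-level mortality fractions.

    The unit is a plot x period record.  The observed curve is the empirical
    CDF of the fraction of trees that died; the simulated curve replaces
    each tree's outcome with a Bernoulli draw from its background death
    probability (annual rate compounded over the census interval) and
    aggregates identically.  Returns columns ``fraction``, ``observed``,
    ``simulated`` — both cumulative frequencies are non-decreasing and end
    at 1.
    """
    trees, plots = tables.trees, tables.plots
    if len(trees) == 0 or len(plots) == 0:
        raise ValueError("need at least one plot with at least one tree")

    t = trees.reset_index(drop=True).copy()
    meta = plots.drop_duplicates("plot_id").set_index("plot_id")
    t["_mat"] = meta["mat"].reindex(t["plot_id"]).to_numpy()
    t["_map"] = meta["map"].reindex(t["plot_id"]).to_numpy()
    iv = plots.set_index(["plot_id", "period"])["interval_yr"]
    t["_dt"] = iv.reindex(pd.MultiIndex.from_frame(t[["plot_id", "period"]])).to_numpy()

    m_bg = np.empty(len(t))
    for pft, grp in t.groupby("pft", sort=False):
        idx = grp.index.to_numpy()
        _, m = vector_rates(
            grp["dbh_t0"].to_numpy(),
            grp["shading_cai"].to_numpy(),
            grp["_mat"].to_numpy(),
            grp["_map"].to_numpy(),
            str(pft),
            params,
        )
        m_bg[idx] = m
    q = 1.0 - (1.0 - m_bg) ** t["_dt"].to_numpy(float)

    rng = np.random.default_rng(seed)
    sim_died = rng.random(len(t)) < q
    t["_obs"] = (t["status_t1"] == "dead").astype(float)
    t["_sim"] = sim_died.astype(float)
    by = t.groupby(["plot_id", "period"])[["_obs", "_sim"]].mean()

    grid = np.unique(np.concatenate([by["_obs"].to_numpy(), by["_sim"].to_numpy()]))
    obs = np.searchsorted(np.sort(by["_obs"].to_numpy()), grid, side="right") / len(by)
    sim = np.searchsorted(np.sort(by["_sim"].to_numpy()), grid, side="right") / len(by)
    return pd.DataFrame({"fraction": grid, "observed": obs, "simulated": sim})


def disturbance_probability(effect_sd: float, threshold_fold: float = 4.0) -> float:
    """P(mortality multiplier >= threshold relative to the distribution mean).

    For a Normal mortality effect E with sd ``effect_sd`` this is
    ``P(E >= mu + ln(threshold)) = 1 - Phi(ln(threshold)/effect_sd)``.
    """
    if effect_sd < 0:
        raise ValueError("effect_sd must be >= 0")
    if threshold_fold < 1:
        raise ValueError("threshold_fold must be >= 1")
    log_t = np.log(threshold_fold)
    if effect_sd == 0:
        return float(log_t <= 0.0)
    return float(stats.norm.sf(log_t / effect_sd))


_SIZE_COMPONENT = {
    ("small", "earlier"): 1,
    ("large", "earlier"): 2,
    ("small", "recent"): 4,
    ("large", "recent"): 5,
}


def region_disturbance_probability(
    dist: RegionEffectDistribution,
    size_class: str = "large",
    period: str = "recent",
    threshold_fold: float = 4.0,
    baseline: str = "region",
) -> float:
    """Fourfold-elevation probability for one mortality component.

    ``baseline='region'`` measures elevation relative to the region-mean
    effect (marginal sd of the component).  ``baseline='plot'`` measures it
    relative to the plot's own long-term mean: decomposing the effect into a
    persistent plot-level component (variance = the cross-period covariance)
    plus a transient part, the relevant spread is
    ``sqrt(c0_ii - c1_ii)``.
    """
    c = _SIZE_COMPONENT[(size_class, period)]
    if baseline == "region":
        sd = float(np.sqrt(dist.sigma_mat[c, c]))
    elif baseline == "plot":
        c0, c1 = derive_blocks(dist)
        i = c if c < 3 else c - 3
        sd = float(np.sqrt(max(c0[i, i] - c1[i, i], 0.0)))
    else:
        raise ValueError("baseline must be 'region' or 'plot'")
    return disturbance_probability(sd, threshold_fold)


#: Named effect pairs reported by :func:`effect_correlations`.  Same-period
#: pairs pool the earlier and recent periods.
CORRELATION_PAIRS = {
    "growth_vs_small_mort": (("growth_earlier", "mort_small_earlier"), ("growth_recent", "mort_small_recent")),
    "growth_vs_large_mort": (("growth_earlier", "mort_large_earlier"), ("growth_recent", "mort_large_recent")),
    "small_vs_large_mort": (("mort_small_earlier", "mort_large_earlier"), ("mort_small_recent", "mort_large_recent")),
    "growth_persistence": (("growth_earlier", "growth_recent"),),
    "small_mort_persistence": (("mort_small_earlier", "mort_small_recent"),),
    "large_mort_persistence": (("mort_large_earlier", "mort_large_recent"),),
}


def _as_effect_frame(summary) -> pd.DataFrame:
    if isinstance(summary, PosteriorSummary):
        df = summary.plot_effects[[f"mean_{c}" for c in COMPONENTS]].copy()
        df.columns = list(COMPONENTS)
        return df
    df = pd.DataFrame(summary)
    missing = [c for c in COMPONENTS if c not in df.columns]
    if missing:
        raise ValueError(f"effect frame missing components: {missing}")
    return df


def effect_correlations(summary, by_region: "pd.Series | None" = None) -> pd.DataFrame:
    """Pearson correlations among (posterior-mean) plot effects.

    Accepts a :class:`PosteriorSummary` or a wide DataFrame with the six
    component columns.  Returns one row per named pair (see
    :data:`CORRELATION_PAIRS`), with an ``overall`` column and, when
    ``by_region`` labels are supplied, one column per region.
    """
    df = _as_effect_frame(summary)
    if len(df) < 3:
        raise ValueError("need at least 3 plots to estimate correlations")

    def pooled_corr(frame: pd.DataFrame, pairs) -> float:
        xs, ys = [], []
        for a, b in pairs:
            xs.append(frame[a].to_numpy(float))
            ys.append(frame[b].to_numpy(float))
        x = np.concatenate([xi - xi.mean() for xi in xs])
        y = np.concatenate([yi - yi.mean() for yi in ys])
        return float(np.corrcoef(x, y)[0, 1])

    out = {"overall": {name: pooled_corr(df, pairs) for name, pairs in CORRELATION_PAIRS.items()}}
    if by_region is not None:
        for region, idx in pd.Series(by_region).groupby(by_region).groups.items():
            sub = df.loc[idx]
            if len(sub) >= 3:
                out[str(region)] = {
                    name: pooled_corr(sub, pairs) for name, pairs in CORRELATION_PAIRS.items()
                }
    result = pd.DataFrame(out)
    result.index.name = "pair"
    return result
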