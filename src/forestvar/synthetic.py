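"""Synthetic inventory data with known ground truth.

Emulates the structure of national forest-inventory remeasurement data —
re-surveyed plots with 3-8 yr census intervals split into an "earlier"
(first measurement before 2003) and a "recent" period, trees measured on
7.3 m-radius subplots (>= 12.7 cm DBH) and 2.1 m microplots (smaller trees,
hence far fewer sampled per plot), nine forest regions along a
climate/disturbance gradient — while every latent quantity is recorded:
the demographic parameters, the per-region effect distributions, and the
exact per-plot effect vectors used to generate each tree outcome.

The region-level defaults encode the study conditions: growth-effect sd
0.30 with cross-period correlation 0.70; mortality-effect sds rising from
0.60 in the northeast to 0.85 in the subtropical south (fourfold-disturbance
probabilities of roughly 1-5 %); small-vs-large mortality correlation 0.47;
mortality persistence 0.25 (small) and 0.45 (large); growth-mortality
correlation 0.  Effect means default to ``-sd^2/2`` so the mean mortality
multiplier ``E[exp(E_M)]`` is 1 and plot effects redistribute — rather than
inflate — the background rates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .demography import (
    PFTS,
    ClimateConditions,
    CohortRecord,
    DemographyParams,
    climate_suitability,
    default_params,
    vector_rates,
)
from .effects import COMPONENTS, GROWTH_IDX, MORT_IDX, RegionEffectDistribution
from .io import InventoryTables
from .simulator import StandState

__all__ = [
    "REGION_TABLE",
    "SyntheticTruth",
    "generate_truth",
    "generate_inventory",
    "generate_initial_stand",
]

#: (region label, MAT degC, MAP mm/yr, small-mortality sd, large-mortality sd)
REGION_TABLE = (
    ("northern_hardwoods_hemlock", 5.0, 1000.0, 0.65, 0.60),
    ("aspen_birch", 4.0, 800.0, 0.68, 0.66),
    ("northern_pine", 5.5, 850.0, 0.70, 0.68),
    ("oak_hickory", 12.0, 1050.0, 0.72, 0.70),
    ("mesophytic", 13.0, 1200.0, 0.72, 0.72),
    ("prairie", 10.0, 900.0, 0.74, 0.72),
    ("southern_mixed", 18.0, 1300.0, 0.82, 0.80),
    ("mississippi_alluvial", 17.0, 1350.0, 0.82, 0.78),
    ("subtropical_evergreen", 21.5, 1300.0, 0.85, 0.85),
)


def _correlation_template(
    growth_persistence: float,
    small_large: float,
    small_persistence: float,
    large_persistence: float,
    cross_size_period: float,
    growth_mortality: float,
) -> np.ndarray:
    r = np.eye(6)

    def put(i, j, v):
        r[i, j] = r[j, i] = v

    put(0, 3, growth_persistence)
    put(1, 2, small_large)
    put(4, 5, small_large)
    put(1, 4, small_persistence)
    put(2, 5, large_persistence)
    put(1, 5, cross_size_period)
    put(2, 4, cross_size_period)
    for g in (0, 3):
        for m in (1, 2, 4, 5):
            if r[g, m] == 0.0:
                put(g, m, growth_mortality)
    return r


@dataclass
class SyntheticTruth:
    """Everything needed to score a downstream stage against ground truth."""

    params: DemographyParams
    regions: "dict[str, RegionEffectDistribution]"
    climates: "dict[str, ClimateConditions]"
    seed: int
    plot_effects: "pd.DataFrame | None" = None  # filled by generate_inventory

    def to_json(self) -> str:
        import json

        payload = {
            "schema": "forestvar-truth-1",
            "seed": self.seed,
            "params": json.loads(self.params.to_json()),
            "regions": {
                name: {
                    "mu": dist.mu.tolist(),
                    "sigma_mat": dist.sigma_mat.tolist(),
                    "sigma_growth": dist.sigma_growth,
                    "mat": self.climates[name].mat,
                    "map": self.climates[name].map,
                }
                for name, dist in self.regions.items()
            },
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        import json

        payload = json.loads(text)
        if payload.get("schema") != "forestvar-truth-1":
            raise ValueError(f"unsupported truth schema: {payload.get('schema')!r}")
        params = DemographyParams.from_json(json.dumps(payload["params"]))
        regions, climates = {}, {}
        for name, blk in payload["regions"].items():
            regions[name] = RegionEffectDistribution(
                mu=np.array(blk["mu"]),
                sigma_mat=np.array(blk["sigma_mat"]),
                sigma_growth=blk["sigma_growth"],
            )
            climates[name] = ClimateConditions(mat=blk["mat"], map=blk["map"])
        return cls(params=params, regions=regions, climates=climates, seed=payload["seed"])


def generate_truth(
    n_regions: int = 9,
    seed: int = 0,
    growth_sd: float = 0.30,
    growth_persistence: float = 0.70,
    small_large_corr: float = 0.47,
    small_persistence: float = 0.25,
    large_persistence: float = 0.45,
    cross_size_period_corr: float = 0.16,
    growth_mortality_corr: float = 0.0,
    mort_sd_scale: float = 1.0,
    sigma_growth: float = 0.15,
    center_mean: bool = True,
    params: "DemographyParams | None" = None,
    regions: "Sequence[str] | None" = None,
) -> SyntheticTruth:
    """Construct per-region effect distributions with the default structure.

    Deterministic given its arguments (the seed is recorded and threaded to
    the data generators).  Every covariance is built as ``R * sd sd^T`` from
    the explicit correlation template, then checked positive definite.
    With ``center_mean`` the component means are ``-sd^2/2`` (unit mean
    multiplier); otherwise 0.
    """
    if regions is not None:
        known = {row[0] for row in REGION_TABLE}
        bad = set(regions) - known
        if bad:
            raise ValueError(f"unknown region labels: {sorted(bad)}")
        table = [row for row in REGION_TABLE if row[0] in set(regions)]
    else:
        if n_regions < 1 or n_regions > len(REGION_TABLE):
            raise ValueError(f"n_regions must be in [1, {len(REGION_TABLE)}]")
        table = list(REGION_TABLE[:n_regions])
    corr = _correlation_template(
        growth_persistence,
        small_large_corr,
        small_persistence,
        large_persistence,
        cross_size_period_corr,
        growth_mortality_corr,
    )
    params = params or default_params()
    regions: dict[str, RegionEffectDistribution] = {}
    climates: dict[str, ClimateConditions] = {}
    for name, mat, mapv, sd_ms, sd_ml in table:
        sd = np.array(
            [
                growth_sd,
                sd_ms * mort_sd_scale,
                sd_ml * mort_sd_scale,
                growth_sd,
                sd_ms * mort_sd_scale,
                sd_ml * mort_sd_scale,
            ]
        )
        sigma = corr * np.outer(sd, sd)
        mu = -0.5 * sd**2 if center_mean else np.zeros(6)
        regions[name] = RegionEffectDistribution(
            mu=mu, sigma_mat=sigma, sigma_growth=sigma_growth
        )
        climates[name] = ClimateConditions(mat=mat, map=mapv)
    return SyntheticTruth(params=params, regions=regions, climates=climates, seed=seed)


_INTERVALS = np.array([3, 4, 5, 6, 7, 8])
_INTERVAL_P = np.array([0.05, 0.15, 0.45, 0.20, 0.10, 0.05])  # median 5 yr


def _pft_weights(climate: ClimateConditions, params: DemographyParams) -> np.ndarray:
    w = np.array([climate_suitability(climate, p, params) for p in PFTS])
    w = w**2
    return w / w.sum()


def generate_inventory(
    truth: SyntheticTruth,
    n_plots: int,
    mean_trees_per_plot: float = 20.0,
    seed: int = 0,
    frac_both_periods: float = 0.2,
    frac_small: float = 0.3,
    flag_fracs: "tuple[float, float, float]" = (0.0, 0.0, 0.0),
) -> InventoryTables:
    """Generate tree/plot tables under the stored truth.

    Plots are spread round-robin over the truth's regions; a fraction
    ``frac_both_periods`` is measured in both census periods (the rest split
    evenly between earlier-only and recent-only, their latent effects for
    the unmeasured period retained in the truth).  Per plot x period, small
    and large tree counts are Poisson with means ``frac_small`` /
    ``1 - frac_small`` times ``mean_trees_per_plot`` (small trees rarer —
    the microplot-vs-subplot area ratio).  Survival is Bernoulli with the
    plot's logit-offset annual mortality compounded over the interval;
    increments of survivors are Normal with the multiplicative growth
    effect.  ``flag_fracs`` = probabilities a plot x period record is
    flagged (non-forestland, harvested, condition-boundary) for filter
    testing; flagged records still have tree rows and stored effects.

    The exact effect draws used are stored on ``truth.plot_effects``.
    """
    if n_plots < 1:
        raise ValueError("n_plots must be >= 1")
    if mean_trees_per_plot <= 0:
        raise ValueError("mean_trees_per_plot must be > 0")
    rng = np.random.default_rng(seed)
    region_names = list(truth.regions)
    params = truth.params

    plot_region = [region_names[i % len(region_names)] for i in range(n_plots)]
    plot_ids = np.arange(1, n_plots + 1)

    # latent effects, drawn per region in one shot
    v = np.empty((n_plots, 6))
    for name in region_names:
        idx = np.flatnonzero(np.array(plot_region) == name)
        dist = truth.regions[name]
        v[idx] = rng.multivariate_normal(dist.mu, dist.sigma_mat, size=len(idx))
    truth.plot_effects = pd.DataFrame(
        v, columns=list(COMPONENTS), index=pd.Index(plot_ids, name="plot_id")
    ).assign(region=plot_region)

    # which periods each plot was measured in
    u = rng.random(n_plots)
    both = u < frac_both_periods
    earlier_only = (~both) & (u < frac_both_periods + (1 - frac_both_periods) / 2)
    periods_of = [
        ("earlier", "recent") if b else (("earlier",) if e else ("recent",))
        for b, e in zip(both, earlier_only)
    ]

    plot_rows = []
    tree_chunks = []
    for i, pid in enumerate(plot_ids):
        name = plot_region[i]
        base = truth.climates[name]
        mat = base.mat + rng.normal(0.0, 1.5)
        mapv = max(base.map + rng.normal(0.0, 100.0), 0.0)
        weights = _pft_weights(ClimateConditions(mat=mat, map=mapv), params)
        for period in periods_of[i]:
            interval = int(rng.choice(_INTERVALS, p=_INTERVAL_P))
            year = int(rng.integers(1998, 2003)) if period == "earlier" else int(
                rng.integers(2003, 2009)
            )
            flags = rng.random(3) < np.asarray(flag_fracs)
            plot_rows.append(
                {
                    "plot_id": pid,
                    "region": name,
                    "mat": mat,
                    "map": mapv,
                    "period": period,
                    "meas_year": year,
                    "interval_yr": interval,
                    "forestland": int(not flags[0]),
                    "harvested": int(flags[1]),
                    "cond_boundary": int(flags[2]),
                }
            )
            n_small = rng.poisson(frac_small * mean_trees_per_plot)
            n_large = rng.poisson((1 - frac_small) * mean_trees_per_plot)
            n_tree = n_small + n_large
            if n_tree == 0:
                continue
            small = np.zeros(n_tree, dtype=bool)
            small[:n_small] = True
            dbh = np.where(
                small,
                np.clip(rng.lognormal(np.log(6.0), 0.35, n_tree), 2.54, 12.6),
                np.clip(rng.lognormal(np.log(20.0), 0.40, n_tree), 12.7, 90.0),
            )
            shading = rng.uniform(0.0, 3.0, n_tree)
            pft = rng.choice(len(PFTS), size=n_tree, p=weights)
            tree_chunks.append(
                pd.DataFrame(
                    {
                        "plot_id": pid,
                        "subplot_id": rng.integers(1, 5, n_tree),
                        "size_class": np.where(small, "small", "large"),
                        "pft": np.array(PFTS, dtype=object)[pft],
                        "dbh_t0": dbh,
                        "period": period,
                        "shading_cai": shading,
                        "_mat": mat,
                        "_map": mapv,
                        "_dt": float(interval),
                        "_pos": i,
                    }
                )
            )

    plots = pd.DataFrame(plot_rows)
    if not tree_chunks:
        raise ValueError("no trees generated; increase mean_trees_per_plot")
    trees = pd.concat(tree_chunks, ignore_index=True)

    # background rates, effect-adjusted outcomes
    g_bg = np.empty(len(trees))
    m_bg = np.empty(len(trees))
    for pft_name, grp in trees.groupby("pft", sort=False):
        idx = grp.index.to_numpy()
        g, m = vector_rates(
            grp["dbh_t0"].to_numpy(),
            grp["shading_cai"].to_numpy(),
            grp["_mat"].to_numpy(),
            grp["_map"].to_numpy(),
            str(pft_name),
            params,
        )
        g_bg[idx] = g
        m_bg[idx] = m

    comp_m = np.array(
        [MORT_IDX[(s, p)] for s, p in zip(trees["size_class"], trees["period"])]
    )
    comp_g = np.array([GROWTH_IDX[p] for p in trees["period"]])
    pos = trees["_pos"].to_numpy(int)
    dt = trees["_dt"].to_numpy(float)

    m_adj = expit(logit(m_bg) + v[pos, comp_m])
    q = 1.0 - (1.0 - m_adj) ** dt
    died = rng.random(len(trees)) < q
    incr = rng.normal(
        np.exp(v[pos, comp_g]) * g_bg * dt, params.sigma_growth * np.sqrt(dt)
    )
    dbh_t1 = np.where(died, np.nan, trees["dbh_t0"].to_numpy() + incr)

    trees["status_t1"] = np.where(died, "dead", "live")
    trees["dbh_t1"] = dbh_t1
    trees = trees.drop(columns=["_mat", "_map", "_dt", "_pos"])
    order = [
        "plot_id",
        "subplot_id",
        "size_class",
        "pft",
        "dbh_t0",
        "dbh_t1",
        "status_t1",
        "period",
        "shading_cai",
    ]
    report = {"generator_seed": seed, "n_plots": n_plots}
    return InventoryTables(trees=trees[order], plots=plots, report=report)


def generate_initial_stand(
    kind: str,
    params: DemographyParams,
    seed: int = 0,
    climate: "ClimateConditions | None" = None,
) -> StandState:
    """Initial simulator state: ``bare_ground`` (empty) or ``random``."""
    climate = climate or ClimateConditions(mat=12.0, map=1100.0)
    if kind == "bare_ground":
        return StandState(cohorts=[], effects=np.zeros(3), time=0.0, climate=climate)
    if kind == "random":
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 25))
        weights = _pft_weights(climate, params)
        pfts = rng.choice(len(PFTS), size=n, p=weights)
        dbh = np.clip(rng.lognormal(np.log(15.0), 0.6, n), 2.54, 80.0)
        dens = rng.lognormal(np.log(50.0), 0.8, n)
        cohorts = [
            CohortRecord(PFTS[k], float(d), float(x)) for k, d, x in zip(pfts, dbh, dens)
        ]
        return StandState(cohorts=cohorts, effects=np.zeros(3), time=0.0, climate=climate)
    raise ValueError(f"unknown initial stand kind: {kind!r}")
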