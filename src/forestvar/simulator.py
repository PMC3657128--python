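"""Cohort-based stand dynamics with stochastically varying demographic rates.

A stand is a list of cohorts (PFT, DBH, stems/ha) plus a 3-vector of current
demographic effects ``(E_G, E_M^small, E_M^large)``.  Every 5-year timestep:

1. the effect vector advances one step of a stationary first-order vector
   autoregression (VAR-1) whose stationary covariance ``c0`` and lag-one
   cross-covariance ``c1`` come from the fitted region-level effect
   distribution — the minimal process consistent with an MVN stationary law
   plus persistence between censuses;
2. every cohort grows by ``5 * exp(E_G) * G`` where ``G`` is background
   growth under the current crown-shading profile;
3. cohort densities are thinned deterministically by the 5-yr survival
   fraction under the logit-offset mortality effect for the cohort's size
   class (DBH vs 12.7 cm at the start of the step);
4. deterministic recruitment adds new cohorts at 2.54 cm DBH, driven by the
   post-thinning canopy openness (so a disturbance immediately opens
   recruitment opportunities);
5. cohorts below a density floor are dropped and near-identical cohorts
   merged to keep the state compact.

In the ``fixed`` scenario the two mortality components are pinned at their
process mean while growth still varies; the same random numbers are consumed
either way, so fixed and variable runs with one seed share identical growth
noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .demography import (
    PFTS,
    ClimateConditions,
    CohortRecord,
    DemographyParams,
    aboveground_biomass,
    recruitment,
    vector_rates,
)
from .effects import RegionEffectDistribution, derive_blocks

__all__ = [
    "SIZE_THRESHOLD",
    "RECRUIT_DBH",
    "DENSITY_FLOOR",
    "StandState",
    "EffectProcess",
    "var1_from_blocks",
    "effect_process",
    "step_effects",
    "step_stand",
    "simulate_stand",
    "stand_biomass",
]

SIZE_THRESHOLD = 12.7  # cm DBH separating small from large trees
RECRUIT_DBH = 2.54  # cm, recruit entry size (inventory minimum)
DENSITY_FLOOR = 1e-3  # stems/ha below which a cohort is dropped
MERGE_BIN = 1.0  # cm DBH bin within which same-PFT cohorts merge


@dataclass
class StandState:
    """Simulator state: cohorts, current 3-vector of effects, time, climate."""

    cohorts: list[CohortRecord]
    effects: np.ndarray
    time: float
    climate: ClimateConditions

    def __post_init__(self) -> None:
        self.effects = np.asarray(self.effects, dtype=float)
        if self.effects.shape != (3,):
            raise ValueError("effects must be a 3-vector (growth, small-mort, large-mort)")
        if self.time % 5 != 0:
            raise ValueError("time must be a multiple of 5 years")


@dataclass(frozen=True)
class EffectProcess:
    """Stationary VAR-1 on the 3-vector of effects.

    ``x_{t+1} = mu + a_mat (x_t - mu) + eta``, ``eta ~ MVN(0, q_mat)``.
    ``mode='fixed'`` pins the two mortality components at their mean.
    """

    mu: np.ndarray
    a_mat: np.ndarray
    q_mat: np.ndarray
    mode: str = "variable"
    pin: "np.ndarray | None" = None

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=float)
        a = np.asarray(self.a_mat, dtype=float)
        q = np.asarray(self.q_mat, dtype=float)
        if mu.shape != (3,) or a.shape != (3, 3) or q.shape != (3, 3):
            raise ValueError("mu must be length 3; a_mat and q_mat 3x3")
        if self.pin is not None:
            pin = np.asarray(self.pin, dtype=float)
            if pin.shape != (3,):
                raise ValueError("pin must be a 3-vector")
            object.__setattr__(self, "pin", pin)
        if np.max(np.abs(np.linalg.eigvals(a))) >= 1.0:
            raise ValueError("transition matrix must have spectral radius < 1")
        if not np.allclose(q, q.T, atol=1e-10):
            raise ValueError("q_mat must be symmetric")
        if np.linalg.eigvalsh(q).min() < -1e-10:
            raise ValueError("q_mat must be positive semidefinite")
        if self.mode not in ("fixed", "variable"):
            raise ValueError("mode must be 'fixed' or 'variable'")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "a_mat", a)
        object.__setattr__(self, "q_mat", 0.5 * (q + q.T))

    @property
    def chol(self) -> np.ndarray:
        """Matrix square root of q_mat (eigendecomposition; tolerates PSD)."""
        w, u = np.linalg.eigh(self.q_mat)
        return u * np.sqrt(np.clip(w, 0.0, None))


def var1_from_blocks(c0: np.ndarray, c1: np.ndarray):
    """Build VAR-1 matrices whose stationary and lag-1 moments are (c0, c1).

    ``a_mat = c1.T @ c0^-1`` and ``q_mat = c0 - a_mat c0 a_mat.T``; the
    resulting process has stationary covariance exactly ``c0`` and lag-one
    cross-covariance ``c1`` (for symmetric ``c1``).  Raises if the implied
    innovation covariance is not positive semidefinite — in that case the
    blocks are inconsistent with a stationary VAR-1 and ``c1`` should be
    shrunk toward zero.
    """
    c0 = np.asarray(c0, dtype=float)
    c1 = np.asarray(c1, dtype=float)
    if np.linalg.eigvalsh(0.5 * (c0 + c0.T)).min() <= 0:
        raise ValueError("c0 must be positive definite")
    a = c1.T @ np.linalg.inv(c0)
    q = c0 - a @ c0 @ a.T
    q = 0.5 * (q + q.T)
    evals = np.linalg.eigvalsh(q)
    if evals.min() < -1e-8 * max(1.0, np.abs(np.diag(c0)).max()):
        raise ValueError(
            "implied innovation covariance is not positive semidefinite; "
            "shrink the cross-period block c1 toward 0 (e.g. multiply by 0.9) "
            "until the blocks admit a stationary VAR-1"
        )
    if evals.max() < 1e-12:
        warnings.warn(
            "degenerate effect process: innovation covariance is ~0 "
            "(perfect persistence)",
            RuntimeWarning,
            stacklevel=2,
        )
    return a, q


def effect_process(
    dist: RegionEffectDistribution, mode: str = "variable", pin_scale: str = "rate"
) -> EffectProcess:
    """Effect process implied by a fitted region distribution.

    The process mean averages the earlier- and recent-period means; the
    stationary covariance and lag-1 cross-covariance are the ``c0``/``c1``
    blocks of the 6x6 effect covariance, treating the estimated cross-census
    correlation as the one-step (~5 yr) correlation.

    ``pin_scale`` selects what "holding mortality effects at their expected
    mean" means in the fixed scenario.  ``'rate'`` (default) pins each
    mortality component at ``mu + var/2``, i.e. at the log of the mean
    multiplier ``E[exp(E_M)]``, so the fixed scenario experiences the same
    long-run expected mortality *rate* as the time average of the variable
    scenario — the comparison then isolates the effect of temporal
    variability itself.  ``'effect'`` pins at the mean of the effect
    (``mu``), the literal log-scale mean, which gives the fixed scenario a
    lower time-averaged rate by the log-normal factor ``exp(var/2)``.
    """
    c0, c1 = derive_blocks(dist)
    a, q = var1_from_blocks(c0, c1)
    mu3 = 0.5 * (dist.mu[:3] + dist.mu[3:])
    if pin_scale == "rate":
        pin = mu3.copy()
        pin[1] += 0.5 * c0[1, 1]
        pin[2] += 0.5 * c0[2, 2]
    elif pin_scale == "effect":
        pin = mu3.copy()
    else:
        raise ValueError("pin_scale must be 'rate' or 'effect'")
    return EffectProcess(mu=mu3, a_mat=a, q_mat=q, mode=mode, pin=pin)


def step_effects(e: np.ndarray, proc: EffectProcess, rng: np.random.Generator) -> np.ndarray:
    """Advance the effect vector one 5-yr step.

    Always consumes three standard normals, so fixed- and variable-mode runs
    from the same seed see identical growth innovations.
    """
    eta = proc.chol @ rng.standard_normal(3)
    out = proc.mu + proc.a_mat @ (np.asarray(e, dtype=float) - proc.mu) + eta
    if proc.mode == "fixed":
        pin = proc.mu if proc.pin is None else proc.pin
        out[1] = pin[1]
        out[2] = pin[2]
    return out


# ---------------------------------------------------------------------------
# stand stepping (vectorized over cohorts)


def _arrays(cohorts: Sequence[CohortRecord]):
    pft = np.array([c.pft for c in cohorts], dtype=object)
    dbh = np.array([c.dbh for c in cohorts], dtype=float)
    dens = np.array([c.density for c in cohorts], dtype=float)
    return pft, dbh, dens


def _merge(pft, dbh, dens):
    """Drop empty cohorts and merge same-PFT cohorts within a DBH bin."""
    keep = dens >= DENSITY_FLOOR
    pft, dbh, dens = pft[keep], dbh[keep], dens[keep]
    if len(dbh) == 0:
        return pft, dbh, dens
    bins = np.floor(dbh / MERGE_BIN).astype(int)
    df = pd.DataFrame({"pft": pft, "bin": bins, "dbh": dbh, "dens": dens})
    df["wd"] = df["dbh"] * df["dens"]
    g = df.groupby(["pft", "bin"], sort=False).agg(dens=("dens", "sum"), wd=("wd", "sum"))
    g["dbh"] = g["wd"] / g["dens"]
    g = g.reset_index()
    return (
        g["pft"].to_numpy(object),
        g["dbh"].to_numpy(float),
        g["dens"].to_numpy(float),
    )


def step_stand(
    stand: StandState,
    params: DemographyParams,
    proc: EffectProcess,
    rng: np.random.Generator,
) -> StandState:
    """One 5-yr timestep: advance effects, grow, thin, recruit."""
    effects = step_effects(stand.effects, proc, rng)
    e_g, e_ms, e_ml = effects
    climate = stand.climate

    pft, dbh, dens = _arrays(stand.cohorts)
    if len(dbh):
        # crown geometry and shading: CAI of strictly taller cohorts
        heights = np.empty(len(dbh))
        areas = np.empty(len(dbh))
        g_bg = np.empty(len(dbh))
        m_bg = np.empty(len(dbh))
        for name in np.unique(pft):
            sel = pft == name
            p = params.pft(str(name))
            heights[sel] = p.h_max * (1.0 - np.exp(-p.a_h * dbh[sel]))
            areas[sel] = p.a_c * dbh[sel] ** p.b_c * dens[sel] / 1.0e4
        order = np.argsort(-heights)
        cum = np.concatenate([[0.0], np.cumsum(areas[order])])
        # shading of a cohort = summed crown area of strictly taller cohorts
        ranked_heights = heights[order]
        k = np.searchsorted(-ranked_heights, -ranked_heights, side="left")
        shading = np.empty(len(dbh))
        shading[order] = cum[k]

        for name in np.unique(pft):
            sel = pft == name
            g, m = vector_rates(
                dbh[sel], shading[sel], climate.mat, climate.map, str(name), params
            )
            g_bg[sel] = g
            m_bg[sel] = m

        small = dbh < SIZE_THRESHOLD
        e_m = np.where(small, e_ms, e_ml)
        m_adj = expit(logit(m_bg) + e_m)
        surv5 = (1.0 - m_adj) ** 5
        dbh = dbh + 5.0 * np.exp(e_g) * g_bg
        dens = dens * surv5

    # recruitment responds to the post-thinning ground-level canopy
    floor_cai = 0.0
    for name in np.unique(pft) if len(dbh) else []:
        sel = pft == name
        p = params.pft(str(name))
        floor_cai += float(np.sum(p.a_c * dbh[sel] ** p.b_c * dens[sel] / 1.0e4))
    new_pft, new_dbh, new_dens = [], [], []
    for name in PFTS:
        r = float(recruitment(name, floor_cai, climate, params))
        if r >= DENSITY_FLOOR:
            new_pft.append(name)
            new_dbh.append(RECRUIT_DBH)
            new_dens.append(r)
    pft = np.concatenate([pft, np.array(new_pft, dtype=object)]) if len(dbh) else np.array(new_pft, dtype=object)
    dbh = np.concatenate([dbh, np.array(new_dbh)]) if len(dbh) else np.array(new_dbh)
    dens = np.concatenate([dens, np.array(new_dens)]) if len(dens) else np.array(new_dens)

    pft, dbh, dens = _merge(pft, dbh, dens)
    cohorts = [CohortRecord(str(p), float(d), float(n)) for p, d, n in zip(pft, dbh, dens)]
    return StandState(
        cohorts=cohorts, effects=effects, time=stand.time + 5.0, climate=climate
    )


def stand_biomass(stand: StandState, params: DemographyParams) -> dict:
    """Aboveground biomass (Mg/ha) per PFT plus ``'total'``."""
    out = {p: 0.0 for p in PFTS}
    for c in stand.cohorts:
        out[c.pft] += float(aboveground_biomass(c.dbh, c.pft, params)) * c.density / 1000.0
    out["total"] = sum(out[p] for p in PFTS)
    return out


def simulate_stand(
    init: StandState,
    years: int,
    scenario: str,
    params: DemographyParams,
    proc: EffectProcess,
    seed: int,
) -> pd.DataFrame:
    """Run a stand for ``years`` (multiple of 5); returns the biomass trajectory.

    One row per 5-yr step (including year 0) with total and per-PFT
    aboveground biomass in Mg/ha.  ``scenario`` overrides the process mode.
    """
    if years % 5 != 0 or years < 0:
        raise ValueError("years must be a non-negative multiple of 5")
    proc = replace(proc, mode=scenario)
    rng = np.random.default_rng(seed)
    stand = init
    rows = []

    def record(s: StandState) -> None:
        bm = stand_biomass(s, params)
        rows.append({"time": s.time, **bm})

    record(stand)
    for _ in range(years // 5):
        stand = step_stand(stand, params, proc, rng)
        record(stand)
    return pd.DataFrame(rows)
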