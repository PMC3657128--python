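"""Background tree demography: growth, mortality, recruitment and allometry.

Expected diameter growth ``G`` and expected longevity ``L`` of an individual
tree are modelled as products of three nonlinear terms each — a size term, a
competition (crown shading) term, and a climate term::

    G = g0 * G_S(dbh) * G_C(cai) * G_E(mat, map) + delta
    L = l0 * L_S(dbh) * L_C(cai) * L_E(mat, map) + psi
    M = 1 / (1 + L)

where ``M`` is the annual mortality probability (the ``1 +`` keeps it in
(0, 1]).  Shading is summarized by the crown-area index of taller neighbours
(CAI, m2 of crown per m2 of ground above the focal tree's height).  The
concrete term shapes used here are standard forest-ecology forms:

* size effect on growth: hump-shaped ``d**alpha * exp(-beta*d)`` (normalized
  to peak at 1);
* competition: exponential decay in CAI for growth, and for longevity
  (more shading, shorter life);
* climate: Gaussian suitability in mean annual temperature (MAT, degC) and
  precipitation (MAP, mm/yr), centred on per-PFT optima, in (0, 1];
* longevity-size: saturating increase with a slow senescence decline.

All constants live in :class:`DemographyParams` and are fully pluggable; the
defaults describe seven eastern-North-American plant functional types (PFTs)
split by latitudinal range and leaf habit, calibrated so a closed-canopy
temperate stand equilibrates at roughly 150-300 Mg/ha of aboveground biomass
with annual background mortality near 1.5 %/yr.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "PFTS",
    "ClimateConditions",
    "PftParams",
    "DemographyParams",
    "CohortRecord",
    "CanopyProfile",
    "default_params",
    "canopy_profile",
    "shading_at_height",
    "tree_height",
    "crown_area",
    "background_growth",
    "background_mortality",
    "vector_rates",
    "interval_death_prob",
    "climate_suitability",
    "recruitment",
    "aboveground_biomass",
]

#: The seven plant functional types: three latitudinal ranges x two leaf
#: habits, plus a southern hydric (swamp) type.
PFTS = (
    "boreal_hardwood",
    "boreal_conifer",
    "north_temperate_hardwood",
    "north_temperate_conifer",
    "south_temperate_hardwood",
    "south_temperate_conifer",
    "south_temperate_hydric",
)

PARAMS_SCHEMA = "forestvar-demography-1"


@dataclass(frozen=True)
class ClimateConditions:
    """Site climate: mean annual temperature (degC) and precipitation (mm/yr)."""

    mat: float
    map: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.mat) or not np.isfinite(self.map):
            raise ValueError("climate values must be finite")
        if self.map < 0:
            raise ValueError("mean annual precipitation must be >= 0")


@dataclass(frozen=True)
class PftParams:
    """All demographic constants for one plant functional type.

    Growth: ``g0`` (cm/yr at the size optimum, unshaded, optimal climate),
    ``alpha``/``beta`` shape the size hump, ``gamma_g`` is the shading decay
    rate (per CAI unit).  Longevity: ``l0`` (yr), ``d_half`` (cm, size at
    half-maximal longevity), ``senesc`` (1/cm senescence decline),
    ``gamma_l`` shading decay.  Climate: Gaussian optima/widths shared by
    growth, longevity and recruitment suitability.  Allometry: height
    ``H = h_max*(1-exp(-a_h*d))``, crown area ``a_c*d**b_c`` (m2), biomass
    ``a_b*d**b_b`` (kg).  Recruitment: ``r_max`` recruits/ha per 5-yr step in
    the open under optimal climate, ``gamma_r`` canopy shading decay.
    """

    g0: float
    alpha: float
    beta: float
    gamma_g: float
    l0: float
    d_half: float
    senesc: float
    gamma_l: float
    t_opt: float
    t_width: float
    p_opt: float
    p_width: float
    h_max: float
    a_h: float
    a_c: float
    b_c: float
    a_b: float
    b_b: float
    r_max: float
    gamma_r: float


@dataclass(frozen=True)
class DemographyParams:
    """Per-PFT parameter blocks plus model-level constants.

    ``delta`` and ``psi`` are reserved additive offsets on expected growth
    and longevity respectively (default 0); ``sigma_growth`` is the residual
    standard deviation of observed diameter increments (cm/yr^0.5 — the
    increment over an interval of ``t`` years has sd ``sigma_growth*sqrt(t)``).
    """

    pfts: Mapping[str, PftParams]
    delta: float = 0.0
    psi: float = 0.0
    sigma_growth: float = 0.15

    def __post_init__(self) -> None:
        if self.sigma_growth <= 0:
            raise ValueError("sigma_growth must be > 0")
        for name, p in self.pfts.items():
            vals = asdict(p)
            if not all(np.isfinite(v) for v in vals.values()):
                raise ValueError(f"non-finite parameter for PFT {name!r}")
            if p.a_b <= 0 or p.b_b <= 0:
                raise ValueError("biomass allometry must be strictly increasing")

    def pft(self, name: str) -> PftParams:
        try:
            return self.pfts[name]
        except KeyError:
            raise KeyError(f"unknown PFT label: {name!r}") from None

    # -- JSON round trip ----------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "schema": PARAMS_SCHEMA,
            "delta": self.delta,
            "psi": self.psi,
            "sigma_growth": self.sigma_growth,
            "pfts": {name: asdict(p) for name, p in self.pfts.items()},
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "DemographyParams":
        payload = json.loads(text)
        if payload.get("schema") != PARAMS_SCHEMA:
            raise ValueError(f"unsupported params schema: {payload.get('schema')!r}")
        pfts = {name: PftParams(**blk) for name, blk in payload["pfts"].items()}
        return cls(
            pfts=pfts,
            delta=payload["delta"],
            psi=payload["psi"],
            sigma_growth=payload["sigma_growth"],
        )


@dataclass
class CohortRecord:
    """A cohort: one PFT, one diameter, a stem density (stems/ha)."""

    pft: str
    dbh: float
    density: float

    def __post_init__(self) -> None:
        if self.dbh < 0:
            raise ValueError("dbh must be >= 0")
        if self.density < 0:
            raise ValueError("density must be >= 0")


@dataclass(frozen=True)
class CanopyProfile:
    """Crown-area index (m2/m2) evaluated at ascending heights (m).

    ``cai[i]`` is the summed crown area per unit ground area of all trees
    whose crown top lies strictly above ``heights[i]``; it is non-increasing
    with height by construction.
    """

    heights: np.ndarray
    cai: np.ndarray

    def at(self, h: float | np.ndarray) -> np.ndarray:
        """CAI at arbitrary height(s): right-continuous step interpolation."""
        idx = np.searchsorted(self.heights, np.asarray(h, dtype=float), side="right") - 1
        idx = np.clip(idx, 0, len(self.heights) - 1)
        return self.cai[idx]


# ---------------------------------------------------------------------------
# default parameterization


def default_params() -> DemographyParams:
    """Default seven-PFT parameterization (see module docstring)."""

    def blk(g0, gamma_g, l0, gamma_l, t_opt, r_max, gamma_r, h_max=32.0) -> PftParams:
        return PftParams(
            g0=g0,
            alpha=0.8,
            beta=0.8 / 15.0,  # growth hump at 15 cm DBH
            gamma_g=gamma_g,
            l0=l0,
            d_half=8.0,
            senesc=1.0 / 35.0,
            gamma_l=gamma_l,
            t_opt=t_opt,
            t_width=7.0,
            p_opt=1150.0,
            p_width=900.0,
            h_max=h_max,
            a_h=0.045,
            a_c=0.63,
            b_c=1.25,
            a_b=0.1,
            b_b=2.4,
            r_max=r_max,
            gamma_r=gamma_r,
        )

    # Longevity is dominated by competition (high gamma_l): open-grown trees
    # are long-lived, shaded ones die quickly.  This self-thinning feedback
    # keeps equilibrium biomass canopy-limited and buffers it against
    # imposed changes in mortality, while typical in-stand shading yields
    # annual mortality near 1.5 %/yr.
    pfts = {
        # early-successional, shade-intolerant, fast and short-lived
        "boreal_hardwood": blk(0.44, 0.75, 900.0, 1.25, 4.0, 450.0, 1.3, 26.0),
        "boreal_conifer": blk(0.32, 0.45, 1400.0, 1.10, 4.5, 250.0, 0.8, 28.0),
        # late-successional northern temperate types: slow, shade-tolerant
        "north_temperate_hardwood": blk(0.30, 0.30, 2100.0, 0.95, 11.0, 160.0, 0.40),
        "north_temperate_conifer": blk(0.28, 0.28, 2300.0, 0.95, 10.0, 140.0, 0.38),
        "south_temperate_hardwood": blk(0.36, 0.40, 1700.0, 1.00, 18.0, 220.0, 0.65),
        # southern pines: early-successional
        "south_temperate_conifer": blk(0.48, 0.80, 1000.0, 1.30, 19.0, 480.0, 1.4, 30.0),
        "south_temperate_hydric": blk(0.34, 0.38, 1800.0, 1.00, 21.0, 180.0, 0.55),
    }
    return DemographyParams(pfts=pfts)


# ---------------------------------------------------------------------------
# allometry


def tree_height(dbh, pft: str, params: DemographyParams):
    """Tree height (m) from DBH (cm): saturating ``h_max*(1-exp(-a_h*d))``."""
    p = params.pft(pft)
    return p.h_max * (1.0 - np.exp(-p.a_h * np.asarray(dbh, dtype=float)))


def crown_area(dbh, pft: str, params: DemographyParams):
    """Crown area (m2/tree) from DBH (cm): power law ``a_c*d**b_c``."""
    p = params.pft(pft)
    return p.a_c * np.asarray(dbh, dtype=float) ** p.b_c


def aboveground_biomass(dbh, pft: str, params: DemographyParams):
    """Aboveground biomass (kg/tree): power law ``a_b * dbh**b_b``.

    Strictly increasing in DBH; 0 at DBH 0.
    """
    p = params.pft(pft)
    d = np.asarray(dbh, dtype=float)
    if np.any(d < 0):
        raise ValueError("dbh must be >= 0")
    return p.a_b * d**p.b_b


# ---------------------------------------------------------------------------
# canopy structure


def canopy_profile(cohorts: Sequence[CohortRecord], params: DemographyParams) -> CanopyProfile:
    """Vertical crown-area-index profile of a stand.

    CAI at height h sums ``crown_area * density / 10_000`` over every cohort
    whose crown top exceeds h.  The profile is returned as a step function
    with breakpoints at the cohort heights (plus height 0).
    """
    for c in cohorts:
        if not np.isfinite(c.density) or c.density < 0:
            raise ValueError("cohort densities must be finite and >= 0")
    if len(cohorts) == 0:
        return CanopyProfile(heights=np.array([0.0]), cai=np.array([0.0]))

    tops = np.array([tree_height(c.dbh, c.pft, params) for c in cohorts], dtype=float)
    areas = np.array(
        [crown_area(c.dbh, c.pft, params) * c.density / 1.0e4 for c in cohorts],
        dtype=float,
    )
    heights = np.unique(np.concatenate([[0.0], tops]))
    cai = np.array([areas[tops > h].sum() for h in heights])
    return CanopyProfile(heights=heights, cai=cai)


def shading_at_height(profile: CanopyProfile, h) -> np.ndarray:
    """Shading covariate of a tree = CAI of taller neighbours at its height."""
    return profile.at(h)


# ---------------------------------------------------------------------------
# vital rates


def _climate_term_arr(mat, mapv, p: PftParams):
    zt = (np.asarray(mat, dtype=float) - p.t_opt) / p.t_width
    zp = (np.asarray(mapv, dtype=float) - p.p_opt) / p.p_width
    return np.exp(-0.5 * (zt * zt + zp * zp))


def _climate_term(climate: ClimateConditions, p: PftParams) -> float:
    return float(_climate_term_arr(climate.mat, climate.map, p))


def vector_rates(dbh, shading_cai, mat, mapv, pft: str, params: DemographyParams):
    """Vectorized (growth, annual mortality) for one PFT with per-tree climate.

    Same model as :func:`background_growth` / :func:`background_mortality`
    but accepting arrays for all tree-level covariates including climate.
    """
    d = np.asarray(dbh, dtype=float)
    c = np.asarray(shading_cai, dtype=float)
    p = params.pft(pft)
    env = _climate_term_arr(mat, mapv, p)
    d_opt = p.alpha / p.beta
    size_g = (d / d_opt) ** p.alpha * np.exp(-p.beta * (d - d_opt))
    g = np.maximum(p.g0 * size_g * np.exp(-p.gamma_g * c) * env + params.delta, 0.0)
    size_l = (d / (d + p.d_half)) * np.exp(-p.senesc * d)
    longevity = p.l0 * size_l * np.exp(-p.gamma_l * c) * env + params.psi
    m = 1.0 / (1.0 + longevity)
    return g, m


def climate_suitability(climate: ClimateConditions, pft: str, params: DemographyParams) -> float:
    """Gaussian climate suitability in (0, 1], peaking at the PFT optimum."""
    return _climate_term(climate, params.pft(pft))


def background_growth(
    dbh, shading_cai, climate: ClimateConditions, pft: str, params: DemographyParams
):
    """Expected annual diameter growth (cm/yr).

    ``G = g0 * G_S(dbh) * G_C(cai) * G_E(mat, map) + delta`` with the size
    term normalized to 1 at its optimum and the competition term normalized
    to 1 at zero shading, so ``g0`` is the maximum expected growth rate.
    """
    d = np.asarray(dbh, dtype=float)
    c = np.asarray(shading_cai, dtype=float)
    if np.any(d <= 0):
        raise ValueError("dbh must be > 0")
    if np.any(c < 0):
        raise ValueError("shading_cai must be >= 0")
    p = params.pft(pft)
    d_opt = p.alpha / p.beta
    size = (d / d_opt) ** p.alpha * np.exp(-p.beta * (d - d_opt))
    comp = np.exp(-p.gamma_g * c)
    g = p.g0 * size * comp * _climate_term(climate, p) + params.delta
    return np.maximum(g, 0.0)


def background_mortality(
    dbh, shading_cai, climate: ClimateConditions, pft: str, params: DemographyParams
):
    """Expected annual mortality probability, ``M = 1/(1 + L)``.

    Longevity ``L = l0 * L_S(dbh) * L_C(cai) * L_E(mat, map) + psi`` rises
    with size (saturating at ``d_half``) until a slow senescence decline and
    falls exponentially with crown shading, so mortality is U-shaped in size
    and increasing in shading.
    """
    d = np.asarray(dbh, dtype=float)
    c = np.asarray(shading_cai, dtype=float)
    if np.any(d <= 0):
        raise ValueError("dbh must be > 0")
    if np.any(c < 0):
        raise ValueError("shading_cai must be >= 0")
    p = params.pft(pft)
    size = (d / (d + p.d_half)) * np.exp(-p.senesc * d)
    comp = np.exp(-p.gamma_l * c)
    longevity = p.l0 * size * comp * _climate_term(climate, p) + params.psi
    if np.any(longevity < 0):
        raise ValueError("expected longevity must be >= 0")
    return 1.0 / (1.0 + longevity)


def interval_death_prob(m_annual, interval):
    """Death probability over a census interval: ``1 - (1 - m)**t``."""
    m = np.asarray(m_annual, dtype=float)
    t = np.asarray(interval, dtype=float)
    if np.any((m < 0) | (m > 1)):
        raise ValueError("annual mortality must lie in [0, 1]")
    if np.any(t <= 0):
        raise ValueError("interval must be > 0 years")
    return 1.0 - (1.0 - m) ** t


def recruitment(
    pft: str, floor_cai, climate: ClimateConditions, params: DemographyParams
):
    """Expected recruits/ha entering per 5-yr step.

    Deterministic: maximal in the open under optimal climate (``r_max``),
    decays exponentially with canopy crown-area index (fast for
    shade-intolerant PFTs), and scales with climate suitability in (0, 1].
    """
    c = np.asarray(floor_cai, dtype=float)
    if np.any(c < 0):
        raise ValueError("floor_cai must be >= 0")
    p = params.pft(pft)
    return p.r_max * np.exp(-p.gamma_r * c) * _climate_term(climate, p)
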