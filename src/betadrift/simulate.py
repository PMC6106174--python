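"""Synthetic atlases, traits and climate with known, controllable structure.

The generator emulates a national breeding-bird atlas study: a square lattice
of 10 km cells, ~tens to hundreds of species whose occupancy follows a
Gaussian niche on a smooth latent environmental gradient, a mixed-type trait
table, and 30 years of monthly climate per cell.  Temporal homogenization is
injected directly: inside a configurable region, period-2 occupancy is redrawn
from a mixture of the period-1 occupancy probability and the period-1
neighborhood majority state, so locally common species expand and locally rare
species contract, pulling neighborhood turnover down by a known amount.
Outside the region period 2 copies period 1 exactly.

Trait-environment coupling ties trait values to species' niche optima, which
creates real functional structure for the trait-shuffle null model to detect;
at coupling 0 traits are independent of ranges and the null holds exactly.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .atlas import Grid, OccurrenceAtlas
from .traits import TraitTable

DAYS_IN_MONTH = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])


@dataclass
class AttrSpec:
    """Monthly climate generator settings for one attribute.

    ``trend`` is per year; ``phi`` the AR(1) coefficient of the monthly
    anomaly; ``sd`` the innovation scale; ``df`` the Student-t degrees of
    freedom of innovations (``inf`` = Gaussian).
    """

    base: float
    seasonal_amp: float
    trend: float = 0.0
    phi: float = 0.3
    sd: float = 1.0
    df: float = float("inf")

    def __post_init__(self):
        if not -1.0 < self.phi < 1.0:
            raise ValueError("AR(1) coefficient must lie in (-1, 1)")


DEFAULT_TRAIT_SPEC = (
    ("body_mass", "continuous"),
    ("clutch_size", "continuous"),
    ("age_first_breeding", "ordinal"),
    ("young_type", "categorical"),
    ("nesting_behavior", "binary-set"),
    ("nest_type", "binary-set"),
    ("migratory_behavior", "categorical"),
    ("diet", "binary-set"),
)

_CATEGORY_LEVELS = {
    "young_type": ("altricial", "semialtricial", "precocial"),
    "migratory_behavior": ("resident", "partial", "migrant"),
}
_SET_LABELS = {
    "nesting_behavior": ("solitary", "semicolonial", "colonial"),
    "nest_type": ("ground", "hole", "open_arboreal", "closed_arboreal",
                  "ground_closed", "parasite"),
    "diet": ("invertebrates", "seeds", "fruit", "vertebrates", "plants"),
}


def _default_climate_spec():
    return {
        "tmin": AttrSpec(base=4.0, seasonal_amp=6.5, trend=0.02, phi=0.3, sd=1.4),
        "tmean": AttrSpec(base=9.0, seasonal_amp=6.0, trend=0.02, phi=0.3, sd=1.1),
        "precip": AttrSpec(base=80.0, seasonal_amp=20.0, trend=0.0, phi=0.2, sd=22.0),
    }


@dataclass
class SimConfig:
    """All knobs of the synthetic study, a pure function of which (plus the
    seed) every generated artifact is."""

    grid_size: int = 27
    n_species: int = 60
    seed: int = 0
    cell_size: int = 10
    homog_region: tuple | None = None  # (col0, row0, col1, row1) inclusive
    homog_strength: float = 0.0
    trait_coupling: float = 0.0
    trait_spec: tuple = DEFAULT_TRAIT_SPEC
    climate_spec: dict = field(default_factory=_default_climate_spec)
    n_years: int = 30
    start_year: int = 1961
    latitude_deg: float = 54.0
    niche_width: float = 1.0

    def __post_init__(self):
        if self.grid_size < 3:
            raise ValueError("grid_size must be at least 3")
        if not 0.0 <= self.homog_strength <= 1.0:
            raise ValueError("homog_strength must lie in [0, 1]")
        if not 0.0 <= self.trait_coupling <= 1.0:
            raise ValueError("trait_coupling must lie in [0, 1]")
        if self.homog_region is not None:
            c0, r0, c1, r1 = self.homog_region
            g = self.grid_size
            if not (0 <= c0 <= c1 < g and 0 <= r0 <= r1 < g):
                raise ValueError("homog_region outside grid")

    def region_mask(self) -> np.ndarray:
        """Boolean (grid_size, grid_size) mask of the homogenized region,
        indexed [row, col]."""
        g = self.grid_size
        if self.homog_region is None:
            return np.ones((g, g), dtype=bool)
        c0, r0, c1, r1 = self.homog_region
        m = np.zeros((g, g), dtype=bool)
        m[r0:r1 + 1, c0:c1 + 1] = True
        return m


def _stream_rng(seed: int, tag: int) -> np.random.Generator:
    # independent, reproducible stream per artifact so e.g. the trait table
    # does not change when atlas settings do
    return np.random.default_rng(np.random.SeedSequence([seed, tag]))


def latent_surface(cfg: SimConfig) -> np.ndarray:
    """Smooth standardized environmental field, shape (grid_size, grid_size)."""
    g = cfg.grid_size
    rng = _stream_rng(cfg.seed, 1)
    x, y = np.meshgrid(np.linspace(0, 1, g), np.linspace(0, 1, g))
    phase = rng.uniform(0, 2 * np.pi, size=4)
    e = (1.5 * x + 0.8 * y
         + 0.6 * np.sin(2 * np.pi * x + phase[0])
         + 0.6 * np.sin(2 * np.pi * y + phase[1])
         + 0.3 * np.sin(4 * np.pi * x + phase[2]) * np.cos(2 * np.pi * y + phase[3]))
    return (e - e.mean()) / e.std()


def _grid(cfg: SimConfig) -> Grid:
    g = cfg.grid_size
    rows, cols = np.divmod(np.arange(g * g), g)
    e = cols * cfg.cell_size
    n = rows * cfg.cell_size
    ids = tuple(f"h{ee}_{nn}" for ee, nn in zip(e, n))
    return Grid(ids, e, n, cfg.cell_size, np.ones(g * g))


def species_optima(cfg: SimConfig) -> np.ndarray:
    """Niche optima spread along the latent gradient (fixed per cfg.seed)."""
    rng = _stream_rng(cfg.seed, 2)
    env = latent_surface(cfg)
    lo, hi = np.quantile(env, [0.05, 0.95])
    opt = np.linspace(lo, hi, cfg.n_species) + rng.normal(0, 0.05, cfg.n_species)
    return opt


def occupancy_probability(cfg: SimConfig) -> np.ndarray:
    """Per-species Bernoulli occupancy probabilities, shape (n_cells, n_species)."""
    rng = _stream_rng(cfg.seed, 3)
    env = latent_surface(cfg).ravel()
    opt = species_optima(cfg)
    intercept = rng.normal(1.5, 0.5, cfg.n_species)
    logit = intercept[None, :] - ((env[:, None] - opt[None, :]) / cfg.niche_width) ** 2
    return 1.0 / (1.0 + np.exp(-logit))


def _neighborhood_fraction(occ: np.ndarray, g: int) -> np.ndarray:
    """Occupied fraction of each cell's 3x3 window (focal included), per species."""
    occ3 = occ.reshape(g, g, -1).astype(float)
    total = np.zeros_like(occ3)
    count = np.zeros((g, g, 1))
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            r0, r1 = max(dr, 0), g + min(dr, 0)
            s0, s1 = max(-dr, 0), g + min(-dr, 0)
            c0, c1 = max(dc, 0), g + min(dc, 0)
            t0, t1 = max(-dc, 0), g + min(-dc, 0)
            total[r0:r1, c0:c1] += occ3[s0:s1, t0:t1]
            count[r0:r1, c0:c1] += 1
    return (total / count).reshape(occ.shape)


def simulate_atlas_pair(cfg: SimConfig) -> tuple[OccurrenceAtlas, OccurrenceAtlas]:
    """Two-period atlas pair with homogenization injected in ``homog_region``.

    Period 1 draws occupancy from the niche model.  Inside the region,
    period-2 occupancy is redrawn from (1-h)*p + h*majority, where majority is
    the period-1 3x3-window occupied fraction thresholded at 1/2 (ties keep
    p); outside, period 2 copies period 1.  At h=0 period 2 is an independent
    redraw from the same law; at h=1 it is the deterministic majority state.
    """
    grid = _grid(cfg)
    p = occupancy_probability(cfg)
    rng1 = _stream_rng(cfg.seed, 4)
    rng2 = _stream_rng(cfg.seed, 5)
    occ1 = (rng1.uniform(size=p.shape) < p).astype(np.uint8)

    frac = _neighborhood_fraction(occ1, cfg.grid_size)
    majority = np.where(frac > 0.5, 1.0, np.where(frac < 0.5, 0.0, p))
    h = cfg.homog_strength
    p2 = (1.0 - h) * p + h * majority
    draw = (rng2.uniform(size=p.shape) < p2).astype(np.uint8)
    in_region = cfg.region_mask().ravel()
    occ2 = np.where(in_region[:, None], draw, occ1).astype(np.uint8)

    a1 = OccurrenceAtlas(grid, _species_names(cfg), "period1", occ1)
    a2 = OccurrenceAtlas(grid, _species_names(cfg), "period2", occ2)
    return a1, a2


def _species_names(cfg: SimConfig) -> tuple:
    return tuple(f"sp{k:03d}" for k in range(cfg.n_species))


# ---------------------------------------------------------------------------
# Traits
# ---------------------------------------------------------------------------

def simulate_traits(cfg: SimConfig) -> TraitTable:
    """Mixed-type trait table; ``trait_coupling`` ties values to niche optima.

    Each trait draws a latent score z = c*z_opt + sqrt(1-c^2)*noise where
    z_opt is the standardized species optimum, then maps z onto the trait's
    scale (lognormal for continuous, binned for ordinal/categorical, per-label
    logistic membership for binary-set).  At c=0 traits are independent of
    species ranges.
    """
    rng = _stream_rng(cfg.seed, 6)
    opt = species_optima(cfg)
    z_opt = (opt - opt.mean()) / opt.std()
    c = cfg.trait_coupling
    n = cfg.n_species
    cols, kinds = {}, {}

    def latent():
        return c * z_opt + np.sqrt(1.0 - c ** 2) * rng.normal(size=n)

    for name, kind in cfg.trait_spec:
        kinds[name] = kind
        z = latent()
        if kind == "continuous":
            if name == "body_mass":
                cols[name] = np.round(np.exp(3.5 + 1.1 * z), 1)  # grams
            else:
                cols[name] = np.round(np.exp(1.4 + 0.35 * z), 2)
        elif kind == "ordinal":
            cols[name] = 1 + np.searchsorted([-1.0, -0.25, 0.5, 1.3], z)
        elif kind == "categorical":
            levels = _CATEGORY_LEVELS.get(
                name, tuple(f"{name}_{i}" for i in range(4)))
            edges = np.quantile(z, np.linspace(0, 1, len(levels) + 1)[1:-1])
            cols[name] = [levels[k] for k in np.searchsorted(edges, z)]
        elif kind == "binary-set":
            labels = _SET_LABELS.get(
                name, tuple(f"{name}_{i}" for i in range(4)))
            sign = rng.choice([-1.0, 1.0], size=len(labels))
            shift = rng.normal(0, 0.5, size=len(labels))
            vals = []
            probs = 1.0 / (1.0 + np.exp(-(sign[None, :] * z[:, None] + shift[None, :])))
            member = rng.uniform(size=probs.shape) < probs
            for k in range(n):
                chosen = [labels[m] for m in np.flatnonzero(member[k])]
                if not chosen:  # every species belongs to at least one label
                    chosen = [labels[int(rng.integers(len(labels)))]]
                vals.append(";".join(chosen))
            cols[name] = vals
        else:
            raise ValueError(f"unknown trait kind {kind!r}")
    df = pd.DataFrame(cols, index=list(_species_names(cfg)))
    df.index.name = "species"
    return TraitTable(df, kinds, log_traits=("body_mass",)
                      if "body_mass" in kinds else ())


# ---------------------------------------------------------------------------
# Climate
# ---------------------------------------------------------------------------

def simulate_climate(cfg: SimConfig) -> pd.DataFrame:
    """Monthly climate per cell: seasonal cycle + linear trend + AR(1) noise
    with Student-t innovations.  Returns a long dataframe with columns
    cell_id, year, month, tmin_c, tmean_c, precip_mm."""
    if cfg.n_years < 5:
        raise ValueError("n_years must be at least 5")
    grid = _grid(cfg)
    g = cfg.grid_size
    env = latent_surface(cfg).ravel()
    rng = _stream_rng(cfg.seed, 7)
    n_months = cfg.n_years * 12
    years = np.repeat(np.arange(cfg.n_years), 12)
    months = np.tile(np.arange(12), cfg.n_years)
    season = np.cos(2 * np.pi * (months - 6) / 12.0)  # peak in July
    rows = grid.northing // cfg.cell_size

    out = {"cell_id": np.repeat(grid.cell_ids, n_months),
           "year": np.tile(cfg.start_year + years, grid.n_cells),
           "month": np.tile(months + 1, grid.n_cells)}
    spatial = {  # smooth per-cell offsets: cooler north, wetter on low env
        "tmin": -1.5 * rows / g + 0.4 * env,
        "tmean": -1.5 * rows / g + 0.4 * env,
        "precip": 15.0 * rows / g - 8.0 * env,
    }
    colname = {"tmin": "tmin_c", "tmean": "tmean_c", "precip": "precip_mm"}
    for attr, spec in cfg.climate_spec.items():
        if np.isfinite(spec.df):
            innov = rng.standard_t(spec.df, size=(grid.n_cells, n_months))
            innov *= spec.sd
        else:
            innov = rng.normal(0, spec.sd, size=(grid.n_cells, n_months))
        noise = np.empty_like(innov)
        noise[:, 0] = innov[:, 0] / np.sqrt(max(1.0 - spec.phi ** 2, 1e-12))
        for t in range(1, n_months):
            noise[:, t] = spec.phi * noise[:, t - 1] + innov[:, t]
        series = (spec.base + spatial[attr][:, None]
                  + spec.seasonal_amp * season[None, :]
                  + spec.trend * years[None, :] + noise)
        if attr == "precip":
            series = np.maximum(series, 0.0)
        out[colname[attr]] = np.round(series, 3).ravel()
    return pd.DataFrame(out)


def truth(cfg: SimConfig) -> dict:
    """Generator parameters worth recording for recovery tests."""
    d = asdict(cfg)
    d["climate_spec"] = {k: asdict(v) for k, v in cfg.climate_spec.items()}
    d["trait_spec"] = [list(t) for t in cfg.trait_spec]
    d["homog_region"] = list(cfg.homog_region) if cfg.homog_region else None
    return d
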