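"""Trait-shuffle null model for changes in functional turnover.

The null randomizes which species carries which trait row (a label
permutation over intact rows, the trait-matrix form of the independent-swap
randomization).  Occurrence data are untouched, so richness, taxonomic
turnover and the spatial structure of ranges are preserved exactly, as are
trait ranges and covariances; only the species-trait assignment is broken.
One shuffle serves both periods per replicate so the null distribution of
delta beta_rao isolates the trait assignment.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import Grid, OccurrenceAtlas
from .traits import DistanceMatrix, TraitTable, gower
from .turnover import DeltaField, _pair_values


def shuffle_traits(traits: TraitTable, rng: np.random.Generator) -> TraitTable:
    """Random reassignment of species labels to intact trait rows."""
    perm = rng.permutation(len(traits.species))
    return traits.relabel(perm)


@dataclass
class NullResult:
    """Observed and null delta-beta_rao per cell with two-tailed p-values."""

    grid: Grid
    observed: np.ndarray
    null_deltas: np.ndarray  # (n_reps, n_cells)
    p_two_tailed: np.ndarray
    n_reps: int
    seed: int


def _rao_field(atlas: OccurrenceAtlas, dmat: DistanceMatrix, pairs: np.ndarray,
               jost: bool, proportional: bool) -> np.ndarray:
    vals = _pair_values(atlas.presence, pairs, "rao", dmat, jost, proportional)
    n = atlas.grid.n_cells
    ok = ~np.isnan(vals)
    total = np.zeros(n)
    count = np.zeros(n)
    np.add.at(total, pairs[ok, 0], vals[ok])
    np.add.at(count, pairs[ok, 0], 1)
    out = np.full(n, np.nan)
    has = count > 0
    out[has] = total[has] / count[has]
    return out


def two_tailed_p(observed: float, null: np.ndarray) -> float:
    """Rank-based two-tailed p with the (r+1)/(n+1) convention.

    Ties are counted inclusively on both tails, which is conservative and
    guarantees p in (0, 1].
    """
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("null distribution is empty")
    if np.isnan(observed):
        return float("nan")
    r_low = int(np.sum(null <= observed))
    r_high = int(np.sum(null >= observed))
    n = null.size
    return min(1.0, 2.0 * min(r_low + 1, r_high + 1) / (n + 1))


def null_delta_distribution(a1: OccurrenceAtlas, a2: OccurrenceAtlas,
                            traits: TraitTable, n_reps: int = 999,
                            seed: int = 0, jost: bool = True,
                            proportional: bool = False) -> NullResult:
    """Null distribution of per-cell delta beta_rao under trait shuffling.

    Each replicate permutes the species-trait assignment once and recomputes
    delta beta_rao for every cell with the same shuffled table in both
    periods; the observed layer uses the unshuffled traits.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    if a1.grid.cell_ids != a2.grid.cell_ids or a1.species != a2.species:
        raise ValueError("atlases must share grid and species")
    table = traits.reindex(a1.species)
    dmat = gower(table)
    pairs = a1.grid.adjacency_pairs()
    observed = (_rao_field(a2, dmat, pairs, jost, proportional)
                - _rao_field(a1, dmat, pairs, jost, proportional))
    rng = np.random.default_rng(seed)
    n_cells = a1.grid.n_cells
    null = np.empty((n_reps, n_cells))
    for r in range(n_reps):
        perm = rng.permutation(len(dmat.species))
        dperm = dmat.permuted(perm)
        null[r] = (_rao_field(a2, dperm, pairs, jost, proportional)
                   - _rao_field(a1, dperm, pairs, jost, proportional))
    r_low = np.sum(null <= observed[None, :], axis=0)
    r_high = np.sum(null >= observed[None, :], axis=0)
    p = np.minimum(1.0, 2.0 * np.minimum(r_low + 1, r_high + 1) / (n_reps + 1))
    p = np.where(np.isnan(observed), np.nan, p)
    return NullResult(a1.grid, observed, null, p, n_reps, seed)


# ---------------------------------------------------------------------------
# Classification into the homogenization/differentiation quadrants
# ---------------------------------------------------------------------------

CATEGORIES = ("taxonomic homogenization + functional homogenization",
              "taxonomic homogenization + functional differentiation",
              "taxonomic differentiation + functional homogenization",
              "taxonomic differentiation + functional differentiation")


def classify(delta_sim: DeltaField, delta_rao: DeltaField, p: np.ndarray,
             alpha: float = 0.05) -> pd.DataFrame:
    """Label each cell by the sign pair of its turnover changes.

    Cells where the trait-shuffle null is rejected (p < alpha) get one of the
    four homogenization/differentiation categories; others are
    "null-consistent".  A rejected cell with delta beta_rao exactly 0 cannot
    be signed and is labeled NA with a warning.
    """
    if delta_sim.grid.cell_ids != delta_rao.grid.cell_ids:
        raise ValueError("delta fields are on different grids")
    ds = delta_sim.delta
    dr = delta_rao.delta
    p = np.asarray(p, dtype=float)
    cats = []
    warned = False
    for i in range(len(ds)):
        if np.isnan(p[i]) or np.isnan(ds[i]) or np.isnan(dr[i]):
            cats.append(None)
        elif p[i] >= alpha:
            cats.append("null-consistent")
        elif dr[i] == 0.0:
            if not warned:
                warnings.warn("rejected cell with delta beta_rao exactly 0: "
                              "cannot assign a direction, category NA")
                warned = True
            cats.append(None)
        else:
            tax = "taxonomic homogenization" if ds[i] < 0 else "taxonomic differentiation"
            fun = "functional homogenization" if dr[i] < 0 else "functional differentiation"
            cats.append(f"{tax} + {fun}")
    return pd.DataFrame({"cell_id": list(delta_sim.grid.cell_ids),
                         "delta_sim": ds, "delta_rao": dr, "p": p,
                         "category": cats})


def classification_counts(classified: pd.DataFrame,
                          alpha: float = 0.05) -> pd.DataFrame:
    """2x2 table of rejected-cell counts by sign pair, plus the rejection
    fraction in ``.attrs['rejection_fraction']``."""
    tbl = pd.DataFrame(0, index=["Taxonomic homogenization",
                                 "Taxonomic differentiation"],
                       columns=["Functional homogenization",
                                "Functional differentiation"])
    for cat in classified["category"]:
        if cat in CATEGORIES:
            tax, fun = cat.split(" + ")
            tbl.loc[tax.capitalize(), fun.capitalize()] += 1
    valid = classified["p"].notna()
    tbl.attrs["rejection_fraction"] = float(
        (classified.loc[valid, "p"] < alpha).mean()) if valid.any() else float("nan")
    return tbl
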