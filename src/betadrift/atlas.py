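"""Gridded occurrence atlases: data model, CSV IO, exclusion filters, scale aggregation.

Cells are squares of a regular national-style grid, identified by the integer
(easting, northing) of their lower-left corner in km.  The native recording
unit is the 10 km "hectad"; analyses can aggregate 3x3 and 9x9 blocks of
hectads into 30 km and 90 km squares.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("betadrift")

# The 8 lattice offsets of a Moore (queen) neighborhood.
MOORE_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass(frozen=True)
class Grid:
    """A set of surviving cells on a regular square lattice.

    Parameters
    ----------
    cell_ids
        Unique identifiers, one per cell, in a fixed order.
    easting, northing
        Lower-left corner coordinates in km; must be multiples of ``cell_size``.
    cell_size
        Lattice spacing in km (10, 30 or 90 in the standard workflow).
    land_fraction
        Fraction of each cell that is land, in [0, 1].
    """

    cell_ids: tuple
    easting: np.ndarray
    northing: np.ndarray
    cell_size: int
    land_fraction: np.ndarray

    def __post_init__(self):
        e = np.asarray(self.easting, dtype=np.int64)
        n = np.asarray(self.northing, dtype=np.int64)
        lf = np.asarray(self.land_fraction, dtype=float)
        object.__setattr__(self, "cell_ids", tuple(self.cell_ids))
        object.__setattr__(self, "easting", e)
        object.__setattr__(self, "northing", n)
        object.__setattr__(self, "land_fraction", lf)
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell_ids")
        if np.any((lf < 0) | (lf > 1)):
            raise ValueError("land_fraction outside [0, 1]")
        if np.any(e % self.cell_size) or np.any(n % self.cell_size):
            raise ValueError("cell corners must lie on the lattice")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def lattice_coords(self) -> np.ndarray:
        """Integer (col, row) lattice coordinates, shape (n_cells, 2)."""
        return np.column_stack([self.easting // self.cell_size,
                                self.northing // self.cell_size])

    def index_of(self, cell_id) -> int:
        try:
            return self.cell_ids.index(cell_id)
        except ValueError:
            raise KeyError(f"cell {cell_id!r} not in grid") from None

    def adjacency_pairs(self) -> np.ndarray:
        """Directed Moore-adjacent index pairs (i, j), shape (n_pairs, 2)."""
        coords = self.lattice_coords()
        lookup = {tuple(c): i for i, c in enumerate(coords)}
        pairs = []
        for i, (x, y) in enumerate(coords):
            for dx, dy in MOORE_OFFSETS:
                j = lookup.get((x + dx, y + dy))
                if j is not None:
                    pairs.append((i, j))
        return np.array(pairs, dtype=np.int64).reshape(-1, 2)


@dataclass(frozen=True)
class Neighborhood:
    """A focal cell and its surviving Moore neighbors (1-8 of them)."""

    focal: object
    neighbors: tuple


@dataclass
class OccurrenceAtlas:
    """Binary site x species matrix for one survey period on a :class:`Grid`."""

    grid: Grid
    species: tuple
    period: str
    presence: np.ndarray  # (n_cells, n_species) of {0, 1}

    def __post_init__(self):
        self.species = tuple(self.species)
        p = np.asarray(self.presence)
        if not np.isin(p, (0, 1)).all():
            raise ValueError("presence entries must be 0 or 1")
        self.presence = p.astype(np.uint8)
        if self.presence.shape != (self.grid.n_cells, len(self.species)):
            raise ValueError("presence shape does not match grid/species")

    def richness(self) -> np.ndarray:
        return self.presence.sum(axis=1).astype(np.int64)

    def to_frame(self) -> pd.DataFrame:
        """Long-format dataframe of the presences (one row per occurrence)."""
        rows, cols = np.nonzero(self.presence)
        g = self.grid
        return pd.DataFrame({
            "site_id": [g.cell_ids[i] for i in rows],
            "easting_km": g.easting[rows],
            "northing_km": g.northing[rows],
            "land_fraction": g.land_fraction[rows],
            "species": [self.species[j] for j in cols],
            "period": self.period,
        })


# ---------------------------------------------------------------------------
# CSV IO
# ---------------------------------------------------------------------------

LONG_COLUMNS = ["site_id", "easting_km", "northing_km", "land_fraction",
                "species", "period"]


def read_atlas(path, period: str, cell_size: int = 10) -> OccurrenceAtlas:
    """Read an atlas CSV (long or wide dialect, auto-detected by header).

    Long dialect has columns ``site_id,easting_km,northing_km,land_fraction,
    species,period``; each row records one presence.  Wide dialect has the
    coordinate columns followed by one 0/1 column per species.
    """
    df = pd.read_csv(path)
    if "species" in df.columns:
        return _read_long(df, period, cell_size, path)
    return _read_wide(df, period, cell_size, path)


def _site_table(df: pd.DataFrame, path) -> pd.DataFrame:
    sites = (df[["site_id", "easting_km", "northing_km", "land_fraction"]]
             .drop_duplicates())
    if sites["site_id"].duplicated().any():
        bad = sites.loc[sites["site_id"].duplicated(), "site_id"].iloc[0]
        raise ValueError(f"{path}: site {bad!r} has conflicting coordinates")
    coord_dup = sites.duplicated(subset=["easting_km", "northing_km"])
    if coord_dup.any():
        row = sites.index[coord_dup][0]
        raise ValueError(f"{path}: duplicate site coordinates at input row {row + 2}")
    return sites.sort_values(["northing_km", "easting_km"]).reset_index(drop=True)


def _read_long(df, period, cell_size, path):
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    known = set(df["period"].unique())
    if period not in known:
        raise ValueError(f"{path}: unknown period {period!r}; file has {sorted(known)}")
    df = df[df["period"] == period]
    ndup = df.duplicated(subset=["site_id", "species"]).sum()
    if ndup:
        logger.warning("%s: %d duplicate (site, species) rows collapsed", path, ndup)
        df = df.drop_duplicates(subset=["site_id", "species"])
    sites = _site_table(df, path)
    species = tuple(sorted(df["species"].unique()))
    site_idx = {s: i for i, s in enumerate(sites["site_id"])}
    sp_idx = {s: j for j, s in enumerate(species)}
    presence = np.zeros((len(sites), len(species)), dtype=np.uint8)
    presence[df["site_id"].map(site_idx), df["species"].map(sp_idx)] = 1
    grid = Grid(tuple(sites["site_id"]), sites["easting_km"].to_numpy(),
                sites["northing_km"].to_numpy(),
                cell_size, sites["land_fraction"].to_numpy())
    return OccurrenceAtlas(grid, species, period, presence)


def _read_wide(df, period, cell_size, path):
    meta = ["site_id", "easting_km", "northing_km", "land_fraction"]
    missing = [c for c in meta if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    species = tuple(c for c in df.columns if c not in meta and c != "period")
    vals = df[list(species)].to_numpy()
    bad = ~np.isin(vals, (0, 1))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: non-binary presence value {vals[r, c]!r} at input row "
            f"{r + 2}, species {species[c]!r}")
    sites = _site_table(df[meta], path)
    order = df.set_index("site_id").loc[list(sites["site_id"])]
    grid = Grid(tuple(sites["site_id"]), sites["easting_km"].to_numpy(),
                sites["northing_km"].to_numpy(),
                cell_size, sites["land_fraction"].to_numpy())
    return OccurrenceAtlas(grid, species, period,
                           order[list(species)].to_numpy().astype(np.uint8))


def write_atlas(atlas: OccurrenceAtlas, path) -> None:
    """Write an atlas in the wide CSV dialect (one 0/1 column per species),
    which round-trips empty cells and the full species list exactly."""
    g = atlas.grid
    frame = pd.DataFrame({"site_id": list(g.cell_ids),
                          "easting_km": g.easting, "northing_km": g.northing,
                          "land_fraction": g.land_fraction,
                          "period": atlas.period})
    for j, sp in enumerate(atlas.species):
        frame[sp] = atlas.presence[:, j]
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Exclusion filters and aggregation
# ---------------------------------------------------------------------------

def _subset(atlas: OccurrenceAtlas, keep: np.ndarray) -> OccurrenceAtlas:
    g = atlas.grid
    grid = Grid(tuple(np.asarray(g.cell_ids, dtype=object)[keep]),
                g.easting[keep], g.northing[keep], g.cell_size,
                g.land_fraction[keep])
    return OccurrenceAtlas(grid, atlas.species, atlas.period,
                           atlas.presence[keep])


def apply_exclusions(atlas: OccurrenceAtlas, min_land: float = 0.5) -> OccurrenceAtlas:
    """Drop cells with land fraction below ``min_land``, then iteratively drop
    cells left with no Moore neighbor until the grid is stable.

    The neighbor rule is applied to a fixed point: removing an isolated cell
    can orphan a former neighbor.
    """
    keep = atlas.grid.land_fraction >= min_land
    if not keep.any():
        raise ValueError("no cells pass the land-fraction filter")
    out = _subset(atlas, np.flatnonzero(keep))
    while True:
        pairs = out.grid.adjacency_pairs()
        deg = np.zeros(out.grid.n_cells, dtype=np.int64)
        if len(pairs):
            np.add.at(deg, pairs[:, 0], 1)
        if (deg > 0).all():
            return out
        if not (deg > 0).any():
            raise ValueError("exclusions removed every cell (no neighboring squares)")
        out = _subset(out, np.flatnonzero(deg > 0))


def block_assignment(grid: Grid, factor: int) -> tuple[np.ndarray, np.ndarray]:
    """Block lattice keys and each cell's block index, anchored at the grid's
    minimum easting/northing."""
    size = grid.cell_size * factor
    be = (grid.easting - grid.easting.min()) // size
    bn = (grid.northing - grid.northing.min()) // size
    keys = np.unique(np.column_stack([be, bn]), axis=0)
    key_idx = {tuple(k): i for i, k in enumerate(keys)}
    member = np.array([key_idx[(x, y)] for x, y in zip(be, bn)])
    return keys, member


def block_id(size: int, easting: int, northing: int) -> str:
    return f"b{size}_{easting}_{northing}"


def aggregate(atlas: OccurrenceAtlas, factor: int,
              min_land: float = 0.5) -> OccurrenceAtlas:
    """Aggregate ``factor`` x ``factor`` blocks of cells into coarser squares.

    Blocks are anchored at the minimum easting/northing of the grid.  Block
    presence is the union of member presences; block land fraction is the mean
    over the full block (absent members count as 0 land).  Exclusions are then
    re-applied at the new scale.
    """
    if factor not in (3, 9):
        raise ValueError("aggregation factor must be 3 or 9")
    g = atlas.grid
    size = g.cell_size * factor
    keys, member = block_assignment(g, factor)
    e0 = g.easting.min()
    n0 = g.northing.min()
    n_blocks = len(keys)
    presence = np.zeros((n_blocks, len(atlas.species)), dtype=np.uint8)
    np.maximum.at(presence, member, atlas.presence)
    land = np.zeros(n_blocks)
    np.add.at(land, member, g.land_fraction)
    land /= factor ** 2  # missing members contribute 0 land
    grid = Grid(tuple(block_id(size, x * size + e0, y * size + n0) for x, y in keys),
                keys[:, 0] * size + e0, keys[:, 1] * size + n0, size, land)
    out = OccurrenceAtlas(grid, atlas.species, atlas.period, presence)
    return apply_exclusions(out, min_land=min_land)


def moore_neighbors(grid: Grid, cell_id) -> Neighborhood:
    """The surviving Moore neighbors of ``cell_id`` on ``grid``."""
    i = grid.index_of(cell_id)
    coords = grid.lattice_coords()
    lookup = {tuple(c): k for k, c in enumerate(coords)}
    x, y = coords[i]
    nbrs = tuple(grid.cell_ids[lookup[(x + dx, y + dy)]]
                 for dx, dy in MOORE_OFFSETS if (x + dx, y + dy) in lookup)
    return Neighborhood(focal=cell_id, neighbors=nbrs)
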